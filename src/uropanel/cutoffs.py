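"""Control-quartile cutoffs and dichotomization.

Continuous biomarker concentrations are binarized against the quartiles of
the control group's distribution (CQ1/CQ2/CQ3), computed on the raw
(untransformed) pg/mL scale.  Exceedance is inclusive: a value equal to the
cutoff counts as above it.

The quartile convention is the weighted average at position ``(n + 1) p``
(the default of the mainstream commercial statistics packages this kind of
analysis is usually run in); the ``(n - 1) p`` linear-interpolation
convention is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import BIOMARKERS, CONTROL, Cohort, SplitAssignment, TRAIN

__all__ = [
    "TRAIN_CONTROLS",
    "ALL_CONTROLS",
    "control_quartiles",
    "build_cutoff_table",
    "exceeds",
    "dichotomize",
    "CutoffTable",
]

TRAIN_CONTROLS = "TRAIN_CONTROLS"
ALL_CONTROLS = "ALL_CONTROLS"

_METHODS = {"weibull": "weibull", "linear": "linear"}


def control_quartiles(values, method: str = "weibull") -> tuple[float, float, float]:
    """Empirical quartiles (CQ1, CQ2, CQ3) of a control sample.

    ``method='weibull'`` places quantile ``p`` at position ``(n + 1) p``
    with linear interpolation between order statistics (so for values 1..7
    the quartiles are exactly (2, 4, 6), and for 1..6 they are
    (1.75, 3.5, 5.25)); ``method='linear'`` uses the ``(n - 1) p``
    convention instead.  Requires at least 4 non-missing values.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown quantile method {method!r}; use 'weibull' or 'linear'")
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 4:
        raise ValueError(f"control quartiles require >= 4 non-missing values; got {v.size}")
    q = np.quantile(v, [0.25, 0.50, 0.75], method=_METHODS[method])
    return (float(q[0]), float(q[1]), float(q[2]))


@dataclass
class CutoffTable:
    """Per-biomarker dichotomization thresholds CQ1 <= CQ2 <= CQ3.

    ``table`` is indexed by biomarker with columns ``CQ1, CQ2, CQ3``.
    """

    table: pd.DataFrame
    source: str = TRAIN_CONTROLS
    n_controls: int = 0

    def __post_init__(self):
        t = self.table
        for col in ("CQ1", "CQ2", "CQ3"):
            if col not in t.columns:
                raise ValueError(f"cutoff table is missing column {col!r}")
        bad = t.index[(t["CQ1"] > t["CQ2"]) | (t["CQ2"] > t["CQ3"])]
        if len(bad):
            raise ValueError(f"cutoffs must satisfy CQ1 <= CQ2 <= CQ3; violated for {list(bad)}")

    def cutoff(self, biomarker: str, level: str) -> float:
        if level not in ("CQ1", "CQ2", "CQ3"):
            raise ValueError(f"level must be CQ1, CQ2 or CQ3; got {level!r}")
        try:
            return float(self.table.loc[biomarker, level])
        except KeyError:
            raise KeyError(f"no cutoffs for biomarker {biomarker!r}") from None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="biomarker")

    @classmethod
    def from_csv(cls, path, source: str = "FILE", n_controls: int = 0) -> "CutoffTable":
        t = pd.read_csv(path, index_col="biomarker")
        return cls(table=t[["CQ1", "CQ2", "CQ3"]], source=source, n_controls=n_controls)

    @classmethod
    def from_dict(cls, cutoffs: dict, source: str = "FILE", n_controls: int = 0) -> "CutoffTable":
        """Build from ``{biomarker: (CQ1, CQ2, CQ3)}``."""
        t = pd.DataFrame.from_dict(cutoffs, orient="index", columns=["CQ1", "CQ2", "CQ3"])
        t.index.name = "biomarker"
        return cls(table=t, source=source, n_controls=n_controls)


def build_cutoff_table(
    cohort: Cohort,
    split: SplitAssignment | None = None,
    source: str = TRAIN_CONTROLS,
    method: str = "weibull",
) -> CutoffTable:
    """Quartile cutoffs from the control group.

    ``source=TRAIN_CONTROLS`` (default, prevents test-set leakage) uses only
    controls in the TRAIN arm; ``ALL_CONTROLS`` uses every control.  Raw
    concentrations are assumed (log-transformed cohorts are rejected since
    published-style cutoffs live on the pg/mL scale).
    """
    if cohort.log_scale:
        raise ValueError("cutoffs are computed on raw concentrations, not log-transformed values")
    if source not in (TRAIN_CONTROLS, ALL_CONTROLS):
        raise ValueError(f"source must be {TRAIN_CONTROLS!r} or {ALL_CONTROLS!r}")
    sub = cohort
    if source == TRAIN_CONTROLS:
        if split is None:
            raise ValueError("source=TRAIN_CONTROLS requires a split")
        sub = cohort.subset(split.arm_ids(TRAIN))
    controls = sub.df[sub.groups == CONTROL]
    if len(controls) == 0:
        raise ValueError("no controls available for cutoff computation")
    rows = {}
    for name in BIOMARKERS:
        rows[name] = control_quartiles(
            pd.to_numeric(controls[name], errors="coerce").to_numpy(float), method=method
        )
    t = pd.DataFrame.from_dict(rows, orient="index", columns=["CQ1", "CQ2", "CQ3"])
    t.index.name = "biomarker"
    return CutoffTable(table=t, source=source, n_controls=len(controls))


def exceeds(value: float, cutoff: float) -> int:
    """1 iff ``value >= cutoff`` (inclusive); missing values are an error."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError("exceeds() requires a non-missing value; callers must handle exclusion")
    return int(float(value) >= float(cutoff))


def dichotomize(
    cohort: Cohort, cutoffs: CutoffTable, level: str, biomarkers=None
) -> pd.DataFrame:
    """Binary exceedance matrix (one column per biomarker, one row per subject).

    Cells are 1 when the concentration is at or above the requested cutoff
    level, 0 below it, and NaN when missing.  Index is subject_id.
    """
    names = list(biomarkers) if biomarkers is not None else list(BIOMARKERS)
    out = {}
    for name in names:
        v = pd.to_numeric(cohort.df[name], errors="coerce").to_numpy(float)
        c = cutoffs.cutoff(name, level)
        col = np.where(np.isnan(v), np.nan, (v >= c).astype(float))
        out[f"{name}>={level}"] = col
    return pd.DataFrame(out, index=cohort.subject_ids.to_numpy())
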