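"""Cohort container, delimited-text I/O, log transformation, and train/test splitting.

A cohort is a tidy per-subject table: one row per patient carrying a group
label (``CONTROL`` / ``NHIC`` / ``HIC``), the 13 canonical urinary biomarker
concentrations (pg/mL; TAC in assay units), and optional clinical covariates
(age, symptom scores, uroflowmetry values, maximal bladder capacity under
anesthesia, glomerulation grade).  The in-memory representation is a thin
validated wrapper around a :class:`pandas.DataFrame`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BIOMARKERS",
    "GROUPS",
    "CONTROL",
    "NHIC",
    "HIC",
    "TRAIN",
    "TEST",
    "CLINICAL_COLUMNS",
    "Cohort",
    "SplitAssignment",
    "read_cohort",
    "write_cohort",
    "log_transform",
    "stratified_split",
]

#: Canonical urinary biomarker panel: inflammatory cytokines/chemokines,
#: oxidative stress markers (8-OHdG, 8-isoprostane), nerve growth factor,
#: and total antioxidant capacity.
BIOMARKERS = (
    "eotaxin",
    "IL-2",
    "IL-6",
    "IL-8",
    "IP-10",
    "MCP-1",
    "MIP-1b",
    "RANTES",
    "TNF-a",
    "NGF",
    "8-OHdG",
    "8-isoprostane",
    "TAC",
)

CONTROL = "CONTROL"
NHIC = "NHIC"
HIC = "HIC"
GROUPS = (CONTROL, NHIC, HIC)

TRAIN = "TRAIN"
TEST = "TEST"

#: Optional per-subject clinical covariates (units in parentheses):
#: age (years), ICSI/ICPI/OSS/VAS symptom scores, glomerulation_grade (0-4),
#: Qmax (mL/s), voided_volume (mL), PVR (mL), CBC (mL), MBC (mL).
CLINICAL_COLUMNS = (
    "age",
    "ICSI",
    "ICPI",
    "OSS",
    "VAS",
    "glomerulation_grade",
    "Qmax",
    "voided_volume",
    "PVR",
    "CBC",
    "MBC",
)

_REQUIRED_COLUMNS = ("subject_id", "group") + BIOMARKERS


class Cohort:
    """Validated per-subject table.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain ``subject_id``, ``group``, and the 13 canonical
        biomarker columns; clinical columns are optional.  Unknown columns
        are rejected.
    log_scale : bool
        True when biomarker values are natural-log transformed
        (non-negativity is then not enforced).
    validate : bool
        Skip validation only for internally constructed frames.
    """

    def __init__(self, df: pd.DataFrame, log_scale: bool = False, validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.log_scale = log_scale
        #: per-biomarker epsilon used by :func:`log_transform` (set there)
        self.epsilons: dict[str, float] | None = None
        if validate:
            self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        df = self.df
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table is missing required columns: {missing}")
        unknown = [c for c in df.columns if c not in _REQUIRED_COLUMNS + CLINICAL_COLUMNS]
        if unknown:
            raise ValueError(f"cohort table has unrecognized columns: {unknown}")
        ids = df["subject_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate subject_id: {dup.iloc[0]!r}")
        bad_group = df.loc[~df["group"].isin(GROUPS), "group"]
        if len(bad_group):
            raise ValueError(
                f"unknown group label {bad_group.iloc[0]!r}; allowed labels are {list(GROUPS)}"
            )
        if not self.log_scale:
            for name in BIOMARKERS:
                col = pd.to_numeric(df[name], errors="coerce")
                if ((col < 0) & col.notna()).any():
                    raise ValueError(f"negative concentration in biomarker column {name!r}")
        if "MBC" in df.columns:
            mbc = pd.to_numeric(df["MBC"], errors="coerce")
            if ((mbc <= 0) & mbc.notna()).any():
                raise ValueError("MBC must be > 0 when present")
        if "glomerulation_grade" in df.columns:
            g = pd.to_numeric(df["glomerulation_grade"], errors="coerce")
            ok = g.isna() | ((g >= 0) & (g <= 4) & (g == g.round()))
            if not ok.all():
                raise ValueError("glomerulation_grade must be an integer in 0..4 when present")

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:  # value identity, used by round-trip tests
        if not isinstance(other, Cohort):
            return NotImplemented
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if c in ("subject_id", "group"):
                if not (a[c].astype(str) == b[c].astype(str)).all():
                    return False
            else:
                x = pd.to_numeric(a[c], errors="coerce").to_numpy(float)
                y = pd.to_numeric(b[c], errors="coerce").to_numpy(float)
                same = (x == y) | (np.isnan(x) & np.isnan(y))
                if not same.all():
                    return False
        return True

    @property
    def subject_ids(self) -> pd.Series:
        return self.df["subject_id"].astype(str)

    @property
    def groups(self) -> pd.Series:
        return self.df["group"]

    def group_sizes(self) -> dict[str, int]:
        vc = self.df["group"].value_counts()
        return {g: int(vc.get(g, 0)) for g in GROUPS}

    def subset(self, ids) -> "Cohort":
        """Rows whose subject_id is in ``ids`` (cohort order preserved)."""
        mask = self.subject_ids.isin([str(i) for i in ids])
        sub = Cohort(self.df.loc[mask], log_scale=self.log_scale, validate=False)
        sub.epsilons = self.epsilons
        return sub

    def biomarker_values(self, name: str, dropna: bool = True) -> np.ndarray:
        if name not in BIOMARKERS:
            raise KeyError(f"{name!r} is not a canonical biomarker; panel: {list(BIOMARKERS)}")
        v = pd.to_numeric(self.df[name], errors="coerce").to_numpy(float)
        return v[~np.isnan(v)] if dropna else v

    def copy(self) -> "Cohort":
        c = Cohort(self.df.copy(), log_scale=self.log_scale, validate=False)
        c.epsilons = dict(self.epsilons) if self.epsilons else None
        return c


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_cohort(path, delimiter: str = ",") -> Cohort:
    """Read a cohort from a UTF-8 delimited-text table.

    The header must contain ``subject_id``, ``group`` and the 13 canonical
    biomarker columns; clinical columns are optional.  Empty biomarker cells
    become missing values.  Duplicate subject ids, unknown group labels and
    negative concentrations are hard errors.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"subject_id": str},
                     float_precision="round_trip")
    return Cohort(df)


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write a cohort as delimited text (missing values as empty cells).

    Floats are written with :func:`repr` precision so that a read-back
    round-trips to value-identical data.
    """
    df = cohort.df.copy()
    for col in df.columns:
        if col in ("subject_id", "group"):
            continue
        nums = pd.to_numeric(df[col], errors="coerce")
        df[col] = ["" if np.isnan(v) else repr(float(v)) for v in nums.to_numpy(float)]
    df.to_csv(path, sep=delimiter, index=False)


# ----------------------------------------------------------------------
# Log transformation
# ----------------------------------------------------------------------

def log_transform(cohort: Cohort, epsilon: float | dict | None = None) -> Cohort:
    """Natural-log transform biomarker concentrations to correct right skew.

    Each present concentration ``c`` is replaced by ``ln(c + eps)`` where
    ``eps`` is half the smallest positive value of that biomarker over the
    cohort (``eps = 1`` if the column has no positive value).  Zeros thereby
    stay finite without perturbing ranks.  Missing stays missing; clinical
    fields are untouched.

    Parameters
    ----------
    epsilon : float, dict, or None
        Override the half-minimum-positive rule with a constant (or a
        per-biomarker dict).  ``None`` (default) applies the rule.
    """
    if cohort.log_scale:
        raise ValueError("cohort is already log transformed")
    df = cohort.df.copy()
    eps_used: dict[str, float] = {}
    for name in BIOMARKERS:
        col = pd.to_numeric(df[name], errors="coerce").to_numpy(float)
        if isinstance(epsilon, dict):
            eps = float(epsilon[name])
        elif epsilon is not None:
            eps = float(epsilon)
        else:
            pos = col[(col > 0) & ~np.isnan(col)]
            eps = float(pos.min()) / 2.0 if pos.size else 1.0
        eps_used[name] = eps
        with np.errstate(divide="ignore"):
            out = np.log(col + eps)
        df[name] = out
    result = Cohort(df, log_scale=True, validate=False)
    result.epsilons = eps_used
    return result


# ----------------------------------------------------------------------
# Train/test split
# ----------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """Mapping of every subject to the TRAIN or TEST arm."""

    arms: pd.Series  # index: subject_id (str), values: TRAIN/TEST
    train_fraction: float
    seed: int
    stratified: bool = True

    def arm_ids(self, arm: str) -> list[str]:
        if arm not in (TRAIN, TEST):
            raise ValueError(f"arm must be {TRAIN!r} or {TEST!r}, got {arm!r}")
        return list(self.arms.index[self.arms == arm])

    @property
    def train_ids(self) -> list[str]:
        return self.arm_ids(TRAIN)

    @property
    def test_ids(self) -> list[str]:
        return self.arm_ids(TEST)

    def arm_of(self, subject_id: str) -> str:
        return str(self.arms.loc[str(subject_id)])

    def sizes(self) -> dict[str, int]:
        return {TRAIN: int((self.arms == TRAIN).sum()), TEST: int((self.arms == TEST).sum())}

    def to_json(self, path) -> None:
        payload = {
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "stratified": self.stratified,
            "arms": {str(k): str(v) for k, v in self.arms.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SplitAssignment":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        arms = pd.Series(payload["arms"], dtype=object)
        return cls(
            arms=arms,
            train_fraction=float(payload["train_fraction"]),
            seed=int(payload["seed"]),
            stratified=bool(payload.get("stratified", True)),
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    cohort: Cohort,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify: bool = True,
) -> SplitAssignment:
    """Seeded random split into TRAIN/TEST arms, stratified by group.

    Within each group stratum, ``round(n * train_fraction)`` subjects
    (round-half-up) are assigned to TRAIN by a seeded shuffle; the remainder
    go to TEST.  Identical seed and cohort give an identical assignment.

    A stratum that would leave either arm empty is a hard error: with three
    strata of sizes (46, 334, 42) and fraction 0.70 the TRAIN sizes are
    (32, 234, 29).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    ids = cohort.subject_ids.to_numpy()
    groups = cohort.groups.to_numpy()

    if stratify:
        for g in GROUPS:
            if (groups == g).sum() == 0:
                raise ValueError(f"stratified split requires subjects in group {g!r}; none found")
        strata = [ids[groups == g] for g in GROUPS]
    else:
        strata = [ids]

    assignment: dict[str, str] = {}
    for stratum_ids in strata:
        n = len(stratum_ids)
        n_train = _round_half_up(n * train_fraction)
        if n_train < 1 or n_train > n - 1:
            raise ValueError(
                f"degenerate stratum: {n} subjects with train_fraction {train_fraction} "
                f"leaves an empty arm"
            )
        perm = rng.permutation(n)
        for i, idx in enumerate(perm):
            assignment[str(stratum_ids[idx])] = TRAIN if i < n_train else TEST

    arms = pd.Series({str(i): assignment[str(i)] for i in ids}, dtype=object)
    return SplitAssignment(arms=arms, train_fraction=train_fraction, seed=seed, stratified=stratify)


def check_missing_fraction(values: np.ndarray, what: str, max_fraction: float = 0.5) -> np.ndarray:
    """Drop NaNs; error if more than ``max_fraction`` of ``values`` are missing."""
    values = np.asarray(values, dtype=float)
    n = values.size
    keep = values[~np.isnan(values)]
    if n and (n - keep.size) / n > max_fraction:
        raise ValueError(
            f"more than {max_fraction:.0%} of values are missing for {what} "
            f"({n - keep.size}/{n})"
        )
    return keep
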