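"""Univariate biomarker screening by directional rank AUC.

Each biomarker's ability to discriminate the target outcome is summarised by
the Mann-Whitney probability estimate of the ROC area, with a Hanley-McNeil
confidence interval, and retained for modelling when the AUC reaches the
screening gate (0.6 by default, inclusive).  Two screening tasks exist:

* ``IC_VS_CONTROL`` -- positives are all IC/BPS subjects (NHIC and HIC),
  negatives are controls;
* ``HIC_VS_NHIC`` -- positives are HIC, negatives NHIC, controls excluded.

AUCs are reported directionally (no ``max(a, 1-a)`` flipping): a biomarker
that is *lower* in cases than in controls shows an AUC below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort import BIOMARKERS, CONTROL, HIC, NHIC, Cohort, SplitAssignment, check_missing_fraction

__all__ = [
    "IC_VS_CONTROL",
    "HIC_VS_NHIC",
    "TASKS",
    "rank_auc",
    "auc_ci",
    "screen_biomarkers",
    "roc_points",
    "ScreeningTable",
    "task_labels",
]

IC_VS_CONTROL = "IC_VS_CONTROL"
HIC_VS_NHIC = "HIC_VS_NHIC"
TASKS = (IC_VS_CONTROL, HIC_VS_NHIC)


def task_labels(task: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(positive groups, negative groups) defining a screening task."""
    if task == IC_VS_CONTROL:
        return (NHIC, HIC), (CONTROL,)
    if task == HIC_VS_NHIC:
        return (HIC,), (NHIC,)
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def rank_auc(values_pos, values_neg) -> float:
    """Mann-Whitney probability estimate of the ROC area.

    Over all (positive, negative) pairs: 1 if pos > neg, 0.5 on ties,
    0 otherwise -- identical to the trapezoidal ROC area.  Directional:
    values below 0.5 are returned as-is.
    """
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("rank_auc requires at least one value in each class")
    if np.isnan(pos).any() or np.isnan(neg).any():
        raise ValueError("rank_auc requires missing values to be dropped first")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_ci(auc: float, n_pos: int, n_neg: int, level: float = 0.95) -> tuple[float, float]:
    """Hanley-McNeil confidence interval for a rank AUC, truncated to [0, 1].

    Uses the exponential-distribution approximations
    ``Q1 = A / (2 - A)`` and ``Q2 = 2 A^2 / (1 + A)``.  Degenerate at
    AUC 0 or 1 (SE exactly zero).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class counts must be >= 1")
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    z = norm.ppf(0.5 + level / 2.0)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class ScreeningTable:
    """Per-biomarker screening summary for one task.

    ``table`` is indexed by biomarker with columns
    ``auc, ci_low, ci_high, n_pos, n_neg, retained``.
    """

    task: str
    gate: float
    table: pd.DataFrame
    flipped: bool = False

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="biomarker")

    def __str__(self) -> str:
        lines = [f"Screening ({self.task}), gate AUC >= {self.gate:g}"]
        for name, row in self.table.iterrows():
            mark = "*" if row["retained"] else " "
            lines.append(
                f"  {mark} {name:<14s} AUC {row['auc']:.3f} "
                f"({row['ci_low']:.3f}-{row['ci_high']:.3f})"
            )
        return "\n".join(lines)


def screen_biomarkers(
    cohort: Cohort,
    split: SplitAssignment | None = None,
    task: str = IC_VS_CONTROL,
    gate: float = 0.6,
    arm: str = "TRAIN",
    level: float = 0.95,
    flip: bool = False,
) -> ScreeningTable:
    """Directional AUC screen of every canonical biomarker.

    Evaluated on the given arm of the split (the whole cohort if ``split`` is
    None).  Missing values are dropped pairwise per biomarker; a biomarker
    with more than half of its arm values missing is an error.  ``retained``
    is inclusive at the gate (AUC >= gate).  ``flip`` reports
    ``max(a, 1 - a)`` instead of the directional AUC.
    """
    sub = cohort.subset(split.arm_ids(arm)) if split is not None else cohort
    pos_groups, neg_groups = task_labels(task)
    gmask = sub.groups.to_numpy()
    pos_mask = np.isin(gmask, pos_groups)
    neg_mask = np.isin(gmask, neg_groups)
    if pos_mask.sum() == 0 or neg_mask.sum() == 0:
        raise ValueError(f"task {task} requires both classes in the {arm} arm")

    rows = []
    for name in BIOMARKERS:
        v = pd.to_numeric(sub.df[name], errors="coerce").to_numpy(float)
        pos = check_missing_fraction(v[pos_mask], f"biomarker {name} (positives)")
        neg = check_missing_fraction(v[neg_mask], f"biomarker {name} (negatives)")
        a = rank_auc(pos, neg)
        if flip:
            a = max(a, 1.0 - a)
        lo, hi = auc_ci(a, pos.size, neg.size, level=level)
        rows.append((name, a, lo, hi, pos.size, neg.size, a >= gate))
    table = pd.DataFrame(
        rows, columns=["biomarker", "auc", "ci_low", "ci_high", "n_pos", "n_neg", "retained"]
    ).set_index("biomarker")
    return ScreeningTable(task=task, gate=gate, table=table, flipped=flip)


def roc_points(values_pos, values_neg) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for one biomarker.

    A simple export for plotting; the screening statistic itself is the
    threshold-free rank AUC.
    """
    from sklearn.metrics import roc_curve

    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, thr = roc_curve(y, np.concatenate([pos, neg]))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
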