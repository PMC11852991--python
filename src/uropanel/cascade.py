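"""Two-stage diagnostic cascade and the NHIC severity subgroup analysis.

Stage 1 applies an IC/BPS cluster rule to every subject: rule-negative
subjects are labelled non-IC/BPS.  Stage 2 applies an HIC rule (by default
the single literal IP-10 >= CQ3) to stage-1 positives: rule-positive
subjects are labelled HIC, the rest NHIC.

Stage-wise evaluation follows the tasks the rules were built for: stage 1 is
scored on IC/BPS-vs-control over the whole arm and stage 2 on HIC-vs-NHIC
restricted to true IC/BPS subjects (so each stage's report equals the
standalone rule evaluation for its task).  The joint three-class confusion
matrix of the cascade as actually executed is reported alongside, as is the
stage-2 performance among stage-1 positives only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .cohort import CONTROL, HIC, NHIC, Cohort, SplitAssignment
from .cutoffs import CutoffTable
from .rules import ClusterRule, PerformanceReport, apply_rule_cohort, evaluate_rule
from .screening import HIC_VS_NHIC, IC_VS_CONTROL

__all__ = [
    "NON_IC",
    "NHIC_PRED",
    "HIC_PRED",
    "CascadeModel",
    "CascadeReport",
    "SubgroupReport",
    "classify",
    "classify_cohort",
    "evaluate_cascade",
    "nhic_subgroups",
    "DEFAULT_MODEL1_RULE",
    "DEFAULT_MODEL2_RULE",
]

NON_IC = "NON_IC"
NHIC_PRED = "NHIC_PRED"
HIC_PRED = "HIC_PRED"
_LABELS = (NON_IC, NHIC_PRED, HIC_PRED)

#: Headline rules of the published diagnostic algorithm.
DEFAULT_MODEL1_RULE = "TNF-a>=CQ3|8-OHdG>=CQ3 & 8-isoprostane>=CQ2"
DEFAULT_MODEL2_RULE = "IP-10>=CQ3"


@dataclass
class CascadeModel:
    """IC/BPS gate (stage 1) plus HIC gate (stage 2) with their cutoffs."""

    model1_rule: ClusterRule
    model2_rule: ClusterRule
    cutoffs: CutoffTable

    @classmethod
    def from_strings(
        cls,
        cutoffs: CutoffTable,
        model1_rule: str = DEFAULT_MODEL1_RULE,
        model2_rule: str = DEFAULT_MODEL2_RULE,
    ) -> "CascadeModel":
        return cls(
            model1_rule=ClusterRule.parse(model1_rule),
            model2_rule=ClusterRule.parse(model2_rule),
            cutoffs=cutoffs,
        )


def classify(model: CascadeModel, subject) -> str:
    """Cascade label for one subject (Series/mapping of biomarker values).

    Stage 1 negative -> ``NON_IC``; stage 1 positive and stage 2 negative ->
    ``NHIC_PRED``; both positive -> ``HIC_PRED``.  Raises if a required
    biomarker is missing.
    """
    from .rules import apply_rule

    if apply_rule(model.model1_rule, subject, model.cutoffs) == 0:
        return NON_IC
    if apply_rule(model.model2_rule, subject, model.cutoffs) == 0:
        return NHIC_PRED
    return HIC_PRED


def classify_cohort(model: CascadeModel, cohort: Cohort) -> pd.Series:
    """Vectorized cascade labels; NaN for non-evaluable subjects.

    A subject is non-evaluable if stage 1 cannot be evaluated, or stage 1
    fires and stage 2 cannot be evaluated.
    """
    s1 = apply_rule_cohort(model.model1_rule, cohort, model.cutoffs).to_numpy()
    s2 = apply_rule_cohort(model.model2_rule, cohort, model.cutoffs).to_numpy()
    out = np.full(len(cohort), None, dtype=object)
    out[s1 == 0.0] = NON_IC
    fired = s1 == 1.0
    out[fired & (s2 == 0.0)] = NHIC_PRED
    out[fired & (s2 == 1.0)] = HIC_PRED
    out[np.isnan(s1) | (fired & np.isnan(s2))] = None
    return pd.Series(out, index=cohort.subject_ids.to_numpy(), name="cascade_label")


@dataclass
class CascadeReport:
    """Joint 3x3 confusion matrix plus per-stage performance reports."""

    confusion: pd.DataFrame  # rows: truth CONTROL/NHIC/HIC; cols: predicted label
    stage1: PerformanceReport
    stage2: PerformanceReport
    stage2_screen_positive: PerformanceReport | None
    n_non_evaluable: int
    arm: str

    def summary(self) -> str:
        lines = [f"Diagnostic cascade ({self.arm} arm)"]
        lines.append(self.confusion.to_string())
        if self.n_non_evaluable:
            lines.append(f"  non-evaluable subjects: {self.n_non_evaluable}")
        lines.append(f"  stage 1 (IC/BPS gate): {self.stage1}")
        lines.append(f"  stage 2 (HIC gate):    {self.stage2}")
        if self.stage2_screen_positive is not None:
            lines.append(f"  stage 2 among stage-1 positives: {self.stage2_screen_positive}")
        return "\n".join(lines)


def evaluate_cascade(
    model: CascadeModel,
    cohort: Cohort,
    split: SplitAssignment | None,
    arm: str,
) -> CascadeReport:
    """Run the cascade on one arm and score it jointly and per stage.

    The stage-1 report is the stage-1 rule evaluated on IC/BPS-vs-control;
    the stage-2 report is the stage-2 rule on HIC-vs-NHIC conditional on true
    IC/BPS membership (both therefore match the standalone rule evaluations
    exactly).  The 3x3 matrix reflects the cascade as executed: a true HIC
    subject failing stage 1 lands in the NON_IC column.
    """
    sub = cohort.subset(split.arm_ids(arm)) if split is not None else cohort
    if len(sub) == 0:
        raise ValueError(f"arm {arm!r} is empty")
    labels = classify_cohort(model, sub)
    truth = sub.groups.to_numpy()

    confusion = pd.DataFrame(
        0, index=pd.Index([CONTROL, NHIC, HIC], name="truth"),
        columns=pd.Index(list(_LABELS), name="predicted"),
    )
    for t, p in zip(truth, labels.to_numpy()):
        if p is not None:
            confusion.loc[t, p] += 1

    stage1 = evaluate_rule(model.model1_rule, sub, None, arm, IC_VS_CONTROL, model.cutoffs)
    stage1.arm = arm
    try:
        stage2 = evaluate_rule(model.model2_rule, sub, None, arm, HIC_VS_NHIC, model.cutoffs)
        stage2.arm = arm
    except ValueError:
        stage2 = PerformanceReport(0, 0, 0, 0, arm=arm, task=HIC_VS_NHIC,
                                   rule=str(model.model2_rule))

    # stage 2 restricted to subjects the cascade actually forwards
    fired_ids = labels.index[(labels == NHIC_PRED) | (labels == HIC_PRED)]
    stage2_sp = None
    forwarded = sub.subset(fired_ids)
    if len(forwarded):
        g = forwarded.groups.to_numpy()
        if (g == HIC).sum() and (g == NHIC).sum():
            stage2_sp = evaluate_rule(
                model.model2_rule, forwarded, None, arm, HIC_VS_NHIC, model.cutoffs
            )
            stage2_sp.arm = f"{arm} (stage-1 positives)"

    return CascadeReport(
        confusion=confusion,
        stage1=stage1,
        stage2=stage2,
        stage2_screen_positive=stage2_sp,
        n_non_evaluable=int(labels.isna().sum()),
        arm=arm,
    )


# ----------------------------------------------------------------------
# NHIC severity subgroups
# ----------------------------------------------------------------------

@dataclass
class SubgroupReport:
    """IP-10 exceedance proportions across the four MBC x glomerulation strata.

    ``table`` rows are the subgroups (low MBC = strictly below the threshold;
    high grade = at or above the grade threshold); the association test
    contrasts the combined low-MBC/high-grade subgroup against the rest.
    """

    table: pd.DataFrame
    statistic: float
    pvalue: float
    test: str
    biomarker: str
    level: str
    mbc_threshold: float
    grade_threshold: int
    n_missing_covariates: int

    def summary(self) -> str:
        lines = [
            f"NHIC subgroups: {self.biomarker} >= {self.level}, "
            f"MBC < {self.mbc_threshold:g} mL, grade >= {self.grade_threshold}"
        ]
        lines.append(self.table.to_string())
        lines.append(
            f"  low-MBC/high-grade vs rest: {self.test} statistic "
            f"{self.statistic:.3f}, p = {self.pvalue:.4g}"
        )
        if self.n_missing_covariates:
            lines.append(f"  NHIC subjects lacking MBC or grade: {self.n_missing_covariates}")
        return "\n".join(lines)


def nhic_subgroups(
    cohort: Cohort,
    split: SplitAssignment | None,
    arm: str | None,
    cutoffs: CutoffTable,
    mbc_threshold: float = 750.0,
    grade_threshold: int = 2,
    biomarker: str = "IP-10",
    level: str = "CQ3",
) -> SubgroupReport:
    """Proportion of NHIC subjects exceeding a cutoff, by bladder severity.

    Subjects are NHIC patients with both MBC and glomerulation grade present;
    MBC exactly at the threshold goes to the ">=" stratum.  The 2x2
    association (combined low-MBC & high-grade subgroup vs the rest, against
    exceedance) is tested by Pearson chi-square, or Fisher's exact test when
    any expected cell count is below 5.
    """
    sub = cohort
    if split is not None and arm is not None:
        sub = cohort.subset(split.arm_ids(arm))
    df = sub.df[sub.groups == NHIC]

    def _col(name):
        if name in df.columns:
            return pd.to_numeric(df[name], errors="coerce")
        return pd.Series(np.nan, index=df.index)

    mbc = _col("MBC")
    grade = _col("glomerulation_grade")
    values = pd.to_numeric(df[biomarker], errors="coerce")
    ok = mbc.notna() & grade.notna() & values.notna()
    n_missing = int(len(df) - ok.sum())
    if ok.sum() == 0:
        raise ValueError("no NHIC subjects with MBC, glomerulation grade and "
                         f"{biomarker} all present")
    mbc, grade, values = mbc[ok], grade[ok], values[ok]
    exceed = (values >= cutoffs.cutoff(biomarker, level)).astype(int)
    low_mbc = mbc < mbc_threshold
    high_grade = grade >= grade_threshold

    strata = [
        (f"MBC<{mbc_threshold:g} & grade>={grade_threshold}", low_mbc & high_grade),
        (f"MBC<{mbc_threshold:g} & grade<{grade_threshold}", low_mbc & ~high_grade),
        (f"MBC>={mbc_threshold:g} & grade>={grade_threshold}", ~low_mbc & high_grade),
        (f"MBC>={mbc_threshold:g} & grade<{grade_threshold}", ~low_mbc & ~high_grade),
    ]
    rows = []
    for name, mask in strata:
        n = int(mask.sum())
        k = int(exceed[mask].sum())
        rows.append((name, n, k, k / n if n else float("nan")))
    table = pd.DataFrame(rows, columns=["subgroup", "n", "n_exceed", "proportion"]).set_index(
        "subgroup"
    )

    severe = (low_mbc & high_grade).to_numpy()
    counts = np.array(
        [
            [int(exceed[severe].sum()), int((1 - exceed[severe]).sum())],
            [int(exceed[~severe].sum()), int((1 - exceed[~severe]).sum())],
        ]
    )
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        stat, p, test = float("nan"), float("nan"), "undefined"
    else:
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
        if expected.min() < 5:
            stat, p = fisher_exact(counts)
            test = "fisher"
        else:
            stat, p, _, _ = chi2_contingency(counts, correction=False)
            test = "chi_square"
    return SubgroupReport(
        table=table,
        statistic=float(stat),
        pvalue=float(p),
        test=test,
        biomarker=biomarker,
        level=level,
        mbc_threshold=mbc_threshold,
        grade_threshold=grade_threshold,
        n_missing_covariates=n_missing,
    )
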