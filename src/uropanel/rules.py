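"""Boolean threshold-rule ("cluster") classifiers over dichotomized biomarkers.

A rule is a conjunction of clauses, each clause a disjunction of literals of
the form "biomarker >= CQ-level"; e.g. the headline IC/BPS rule

    TNF-a>=CQ3|8-OHdG>=CQ3 & 8-isoprostane>=CQ2

fires when (TNF-a or 8-OHdG is at/above its control third quartile) AND
(8-isoprostane is at/above its control median).  Rules are evaluated against
a cutoff table, producing confusion counts, sensitivity, specificity,
accuracy, and the balanced AUC (sens + spec) / 2 -- which is exactly the
trapezoidal ROC area of a binary classifier.

Grammar: literals ``NAME>=CQ1|CQ2|CQ3``; ``|`` separates literals within a
clause, ``&`` separates clauses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import BIOMARKERS, Cohort, SplitAssignment
from .cutoffs import CutoffTable, exceeds
from .screening import task_labels

__all__ = [
    "ThresholdLiteral",
    "ClusterRule",
    "PerformanceReport",
    "apply_rule",
    "apply_rule_cohort",
    "evaluate_rule",
    "enumerate_rules",
    "rank_rules",
]

_LEVELS = ("CQ1", "CQ2", "CQ3")


@dataclass(frozen=True, order=True)
class ThresholdLiteral:
    """One predicate: biomarker concentration at or above a CQ level."""

    biomarker: str
    level: str

    def __post_init__(self):
        if self.biomarker not in BIOMARKERS:
            raise ValueError(
                f"{self.biomarker!r} is not a canonical biomarker; panel: {list(BIOMARKERS)}"
            )
        if self.level not in _LEVELS:
            raise ValueError(f"level must be one of {_LEVELS}; got {self.level!r}")

    def __str__(self) -> str:
        return f"{self.biomarker}>={self.level}"

    @classmethod
    def parse(cls, text: str) -> "ThresholdLiteral":
        if ">=" not in text:
            raise ValueError(f"cannot parse literal {text!r}; expected 'NAME>=CQn'")
        name, level = (s.strip() for s in text.split(">=", 1))
        return cls(biomarker=name, level=level)


class ClusterRule:
    """AND-of-ORs rule over threshold literals.

    ``clauses`` is a non-empty sequence of non-empty literal sequences; the
    rule fires for a subject iff every clause contains at least one literal
    whose exceedance is 1.  Clauses and literals are stored in canonical
    (lexicographic) order so equal rules compare and print identically.
    """

    def __init__(self, clauses):
        norm_clauses = []
        for clause in clauses:
            lits = tuple(sorted(set(clause)))
            if not lits:
                raise ValueError("empty clause in rule")
            if len(lits) != len(tuple(clause)):
                raise ValueError("duplicate literal within a clause")
            norm_clauses.append(lits)
        if not norm_clauses:
            raise ValueError("rule must have at least one clause")
        self.clauses: tuple[tuple[ThresholdLiteral, ...], ...] = tuple(sorted(norm_clauses))

    def __eq__(self, other) -> bool:
        return isinstance(other, ClusterRule) and self.clauses == other.clauses

    def __hash__(self) -> int:
        return hash(self.clauses)

    def __str__(self) -> str:
        return " & ".join("|".join(str(l) for l in clause) for clause in self.clauses)

    def __repr__(self) -> str:
        return f"ClusterRule({str(self)!r})"

    @property
    def biomarkers(self) -> list[str]:
        return sorted({l.biomarker for clause in self.clauses for l in clause})

    @classmethod
    def parse(cls, text: str) -> "ClusterRule":
        """Parse ``'A>=CQ3|B>=CQ3 & C>=CQ2'`` (``&`` binds clauses, ``|`` literals)."""
        clauses = []
        for chunk in text.split("&"):
            lits = [ThresholdLiteral.parse(p) for p in chunk.split("|") if p.strip()]
            clauses.append(lits)
        return cls(clauses)


def apply_rule(rule: ClusterRule, subject, cutoffs: CutoffTable) -> int:
    """Evaluate a rule for one subject (a Series or mapping of biomarker values).

    Requires a non-missing value for every biomarker the rule references;
    a missing one raises (callers exclude such subjects as non-evaluable).
    """
    for name in rule.biomarkers:
        v = subject[name]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"subject is non-evaluable: missing biomarker {name!r}")
    result = 1
    for clause in rule.clauses:
        if not any(
            exceeds(float(subject[l.biomarker]), cutoffs.cutoff(l.biomarker, l.level))
            for l in clause
        ):
            result = 0
            break
    return result


def apply_rule_cohort(rule: ClusterRule, cohort: Cohort, cutoffs: CutoffTable) -> pd.Series:
    """Vectorized rule evaluation over a cohort.

    Returns a float Series indexed by subject_id: 1.0/0.0 for evaluable
    subjects, NaN for subjects missing any required biomarker.
    """
    n = len(cohort)
    out = np.ones(n)
    evaluable = np.ones(n, dtype=bool)
    values = {
        name: pd.to_numeric(cohort.df[name], errors="coerce").to_numpy(float)
        for name in rule.biomarkers
    }
    for name in rule.biomarkers:
        evaluable &= ~np.isnan(values[name])
    for clause in rule.clauses:
        clause_hit = np.zeros(n, dtype=bool)
        for l in clause:
            v = values[l.biomarker]
            c = cutoffs.cutoff(l.biomarker, l.level)
            with np.errstate(invalid="ignore"):
                clause_hit |= v >= c
        out = np.where(clause_hit, out, 0.0)
    out = np.where(evaluable, out, np.nan)
    return pd.Series(out, index=cohort.subject_ids.to_numpy(), name=str(rule))


@dataclass
class PerformanceReport:
    """Confusion counts and derived rates of a binary rule on one arm/task."""

    tp: int
    fn: int
    fp: int
    tn: int
    n_excluded: int = 0
    arm: str = ""
    task: str = ""
    rule: str = ""

    @classmethod
    def from_counts(cls, tp, fn, fp, tn, **kw) -> "PerformanceReport":
        return cls(tp=int(tp), fn=int(fn), fp=int(fp), tn=int(tn), **kw)

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_pos if self.n_pos else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / self.n_neg if self.n_neg else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.n_pos + self.n_neg
        return (self.tp + self.tn) / total if total else float("nan")

    @property
    def balanced_auc(self) -> float:
        """(sensitivity + specificity) / 2: the ROC area of a binary classifier."""
        return (self.sensitivity + self.specificity) / 2.0

    def as_dict(self) -> dict:
        return {
            "rule": self.rule,
            "task": self.task,
            "arm": self.arm,
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "n_excluded": self.n_excluded,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_auc": self.balanced_auc,
        }

    def __str__(self) -> str:
        return (
            f"{self.rule or 'rule'} [{self.task} {self.arm}] "
            f"sens {self.sensitivity:.1%} spec {self.specificity:.1%} "
            f"acc {self.accuracy:.1%} AUC {self.balanced_auc:.2f} "
            f"(TP {self.tp} FN {self.fn} FP {self.fp} TN {self.tn}"
            + (f", excluded {self.n_excluded})" if self.n_excluded else ")")
        )


def evaluate_rule(
    rule: ClusterRule,
    cohort: Cohort,
    split: SplitAssignment | None,
    arm: str,
    task: str,
    cutoffs: CutoffTable,
) -> PerformanceReport:
    """Confusion matrix of a rule against the task's truth on one arm.

    Task ``IC_VS_CONTROL`` takes NHIC and HIC as positives and controls as
    negatives; ``HIC_VS_NHIC`` takes HIC as positives and NHIC as negatives
    (controls excluded).  Subjects missing a required biomarker are excluded
    from the counts and tallied in ``n_excluded``.
    """
    sub = cohort.subset(split.arm_ids(arm)) if split is not None else cohort
    pos_groups, neg_groups = task_labels(task)
    g = sub.groups.to_numpy()
    relevant = np.isin(g, pos_groups + neg_groups)
    truth = np.isin(g, pos_groups)
    pred = apply_rule_cohort(rule, sub, cutoffs).to_numpy()

    evaluable = relevant & ~np.isnan(pred)
    if truth[evaluable].sum() == 0 or (~truth[evaluable]).sum() == 0:
        raise ValueError(f"arm {arm!r} lacks one of the classes for task {task!r}")
    p = pred[evaluable] >= 0.5
    t = truth[evaluable]
    return PerformanceReport(
        tp=int((p & t).sum()),
        fn=int((~p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        n_excluded=int((relevant & np.isnan(pred)).sum()),
        arm=arm,
        task=task,
        rule=str(rule),
    )


def _set_partitions_2(items: tuple) -> list[tuple[tuple, tuple]]:
    """All unordered partitions of ``items`` into exactly two non-empty blocks."""
    out = []
    n = len(items)
    for r in range(1, n // 2 + 1):
        for combo in itertools.combinations(range(n), r):
            if r == n - r and 0 not in combo:
                continue  # avoid double-counting equal-size partitions
            block1 = tuple(items[i] for i in combo)
            block2 = tuple(items[i] for i in range(n) if i not in combo)
            out.append((block1, block2))
    return out


def enumerate_rules(literals, max_clauses: int = 2) -> list[ClusterRule]:
    """Systematic rule grid over a literal set (the Table-6-style families).

    Produces the single OR of all literals, the full AND (each literal its
    own clause), and every two-clause partition of the literal set (each
    block an OR clause).  Deduplicated, canonically ordered, deterministic.
    At most 8 literals (beyond that, specify rules explicitly).
    """
    lits = tuple(sorted(set(literals)))
    if not lits:
        raise ValueError("need at least one literal")
    if len(lits) > 8:
        raise ValueError(
            f"{len(lits)} literals is too many for exhaustive enumeration; "
            "specify rules explicitly"
        )
    rules = {ClusterRule([lits])}  # single OR
    rules.add(ClusterRule([[l] for l in lits]))  # full AND
    if max_clauses >= 2:
        for block1, block2 in _set_partitions_2(lits):
            rules.add(ClusterRule([block1, block2]))
    return sorted(rules, key=lambda r: (len(r.clauses), str(r)))


def mixed_level_rules(biomarkers, high: str = "CQ3", low: str = "CQ2") -> list[ClusterRule]:
    """Rules mixing cutoff levels over a biomarker set.

    For every split of the biomarkers into a non-empty ``high``-level subset
    and a non-empty ``low``-level remainder, produce both the single-clause
    OR (any literal fires) and the two-clause AND form (the high-level OR
    clause AND the low-level OR clause) -- the shapes of the published
    mixed-level rules.
    """
    names = tuple(sorted(set(biomarkers)))
    if len(names) < 2:
        return []
    if len(names) > 8:
        raise ValueError("too many biomarkers for exhaustive mixed-level enumeration")
    rules = set()
    n = len(names)
    for mask in range(1, 2 ** n - 1):
        high_lits = tuple(
            ThresholdLiteral(names[i], high) for i in range(n) if mask & (1 << i)
        )
        low_lits = tuple(
            ThresholdLiteral(names[i], low) for i in range(n) if not mask & (1 << i)
        )
        rules.add(ClusterRule([high_lits + low_lits]))
        rules.add(ClusterRule([high_lits, low_lits]))
    return sorted(rules, key=lambda r: (len(r.clauses), str(r)))


def rule_family(lits_cq2, lits_cq3, include_mixed: bool = True) -> list[ClusterRule]:
    """Candidate cluster rules from CQ2- and CQ3-selected literal sets.

    The union of the systematic enumerations over each level's own literals
    plus (optionally) the mixed-level one- and two-clause rules over the
    combined biomarker set.  Deduplicated and canonically ordered.
    """
    rules: set[ClusterRule] = set()
    if lits_cq2:
        rules.update(enumerate_rules(lits_cq2))
    if lits_cq3:
        rules.update(enumerate_rules(lits_cq3))
    if include_mixed:
        names = {l.biomarker for l in tuple(lits_cq2) + tuple(lits_cq3)}
        if 2 <= len(names) <= 8:
            rules.update(mixed_level_rules(names))
    if not rules:
        raise ValueError("no literals supplied")
    return sorted(rules, key=lambda r: (len(r.clauses), str(r)))


def rank_rules(reports, criterion: str = "balanced_auc") -> list[PerformanceReport]:
    """Order performance reports by a criterion (descending).

    Ties break by higher sensitivity, then lexicographic rule string; the
    sort is stable, so fully tied reports keep their input order.
    """
    if criterion not in ("balanced_auc", "accuracy", "sensitivity", "specificity"):
        raise ValueError(f"unknown ranking criterion {criterion!r}")
    reports = list(reports)
    arms = {r.arm for r in reports}
    tasks = {r.task for r in reports}
    if len(arms) > 1 or len(tasks) > 1:
        raise ValueError("rank_rules expects reports from a single arm and task")
    return sorted(
        reports,
        key=lambda r: (-getattr(r, criterion), -r.sensitivity, r.rule),
    )
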