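"""End-to-end study driver: comparability tables, model selection, reporting.

:class:`DiagnosticStudy` is the package's top-level model object.  Built from
a cohort and a :class:`StudyConfig`, its :meth:`~DiagnosticStudy.fit` runs
the full analysis -- train/test split, arm-comparability tests, univariate
AUC screening for both tasks, control-quartile cutoffs, forward stepwise
logistic selection on CQ2- and CQ3-dichotomized candidate pools, systematic
cluster-rule evaluation on both arms, the two-stage diagnostic cascade, and
the NHIC severity subgroup analysis -- and returns a :class:`StudyResults`
carrying every table plus a ``summary()`` and a deterministic on-disk bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import cascade as cascade_mod
from .cohort import (
    BIOMARKERS,
    CLINICAL_COLUMNS,
    GROUPS,
    TEST,
    TRAIN,
    Cohort,
    SplitAssignment,
    log_transform,
    stratified_split,
)
from .cutoffs import TRAIN_CONTROLS, CutoffTable, build_cutoff_table, dichotomize
from .logistic import StepwisePath, forward_stepwise
from .rules import (
    ClusterRule,
    PerformanceReport,
    ThresholdLiteral,
    evaluate_rule,
    rank_rules,
    rule_family,
)
from .screening import HIC_VS_NHIC, IC_VS_CONTROL, ScreeningTable, screen_biomarkers, task_labels

__all__ = ["StudyConfig", "DiagnosticStudy", "StudyResults", "compare_arms", "run_pipeline"]


@dataclass
class StudyConfig:
    """Tunable knobs of the end-to-end analysis (defaults match the study design)."""

    train_fraction: float = 0.7
    seed: int = 0
    stratify: bool = True
    gate: float = 0.6
    entry_alpha: float = 0.05
    cutoff_source: str = TRAIN_CONTROLS
    quantile_method: str = "weibull"
    welch: bool = False
    model2_levels: tuple[str, ...] = ("CQ2", "CQ3")
    mbc_threshold: float = 750.0
    grade_threshold: int = 2
    subgroup_biomarker: str = "IP-10"
    subgroup_level: str = "CQ3"
    log_transform: bool = True

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "model2_levels" in data:
            data["model2_levels"] = tuple(data["model2_levels"])
        return cls(**data)


# ----------------------------------------------------------------------
# Arm comparability
# ----------------------------------------------------------------------

def _t_test(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_arms(
    cohort: Cohort, split: SplitAssignment, welch: bool = False, alpha: float = 0.05
) -> pd.DataFrame:
    """Train-vs-test comparability table.

    Continuous variables (biomarkers and numeric clinical covariates) are
    compared with a two-sample t-test (pooled-variance Student's by default,
    Welch with ``welch=True``); the group composition with a chi-square test
    (Fisher's exact on a 2x2 when any expected count is below 5).  Rows where
    both arms have zero variance carry an undefined statistic and are
    flagged.  Two-tailed throughout; ``flagged`` marks p <= alpha.
    """
    train = cohort.subset(split.train_ids).df
    test = cohort.subset(split.test_ids).df
    if len(train) == 0 or len(test) == 0:
        raise ValueError("both arms must be non-empty")
    rows = []

    # group composition (categorical)
    counts = np.array(
        [
            [int((train["group"] == g).sum()) for g in GROUPS],
            [int((test["group"] == g).sum()) for g in GROUPS],
        ]
    )
    keep = counts.sum(axis=0) > 0
    counts = counts[:, keep]
    if counts.shape[1] >= 2:
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
        if expected.min() < 5 and counts.shape == (2, 2):
            stat, p = stats.fisher_exact(counts)
            test_name = "FISHER"
        else:
            stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
            test_name = "CHI_SQUARE"
        rows.append(
            {
                "variable": "group",
                "train_mean": float("nan"),
                "train_sd": float("nan"),
                "test_mean": float("nan"),
                "test_sd": float("nan"),
                "statistic": float(stat),
                "pvalue": float(p),
                "test": test_name,
                "flagged": bool(p <= alpha),
            }
        )

    continuous = list(BIOMARKERS) + [c for c in CLINICAL_COLUMNS if c in cohort.df.columns]
    for var in continuous:
        a = pd.to_numeric(train[var], errors="coerce").dropna().to_numpy(float)
        b = pd.to_numeric(test[var], errors="coerce").dropna().to_numpy(float)
        row = {
            "variable": var,
            "train_mean": float(a.mean()) if a.size else float("nan"),
            "train_sd": float(a.std(ddof=1)) if a.size > 1 else float("nan"),
            "test_mean": float(b.mean()) if b.size else float("nan"),
            "test_sd": float(b.std(ddof=1)) if b.size > 1 else float("nan"),
            "test": "T_TEST",
        }
        if a.size < 2 or b.size < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
            row.update(statistic=float("nan"), pvalue=float("nan"), flagged=True)
        else:
            stat, p = _t_test(a, b, welch)
            row.update(statistic=stat, pvalue=p, flagged=bool(p <= alpha))
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


# ----------------------------------------------------------------------
# Study model / results
# ----------------------------------------------------------------------

@dataclass
class StudyResults:
    """Everything the fitted study produced, with self-consistent tables."""

    config: StudyConfig
    split: SplitAssignment
    comparability: pd.DataFrame
    screening: dict  # task -> ScreeningTable
    cutoffs: CutoffTable
    stepwise: dict  # model name ("1-1", "1-2", "2-1", "2-2") -> StepwisePath
    rule_reports: dict  # task -> {arm -> list[PerformanceReport]}
    best_rules: dict  # task -> ClusterRule
    cascade_reports: dict  # arm -> CascadeReport
    subgroups: "cascade_mod.SubgroupReport | None"
    group_sizes: dict

    # -- rendering ------------------------------------------------------
    def rule_table(self, task: str) -> pd.DataFrame:
        """Table-6-shaped grid: one row per rule, train and test metrics."""
        train = {r.rule: r for r in self.rule_reports[task][TRAIN]}
        test = {r.rule: r for r in self.rule_reports[task][TEST]}
        rows = []
        for rule, tr in train.items():
            te = test.get(rule)
            row = {"rule": rule}
            for label, rep in (("train", tr), ("test", te)):
                if rep is None:
                    continue
                row[f"{label}_sensitivity"] = rep.sensitivity
                row[f"{label}_specificity"] = rep.specificity
                row[f"{label}_accuracy"] = rep.accuracy
                row[f"{label}_auc"] = rep.balanced_auc
            rows.append(row)
        return pd.DataFrame(rows).set_index("rule")

    def summary(self) -> str:
        lines = [
            "Urinary biomarker cluster diagnostic study",
            f"  seed {self.config.seed}, train fraction {self.config.train_fraction:g}, "
            f"AUC gate {self.config.gate:g}, stepwise entry alpha {self.config.entry_alpha:g}",
            f"  group sizes: {self.group_sizes}; arms: {self.split.sizes()}",
            "",
        ]
        for task in (IC_VS_CONTROL, HIC_VS_NHIC):
            lines.append(str(self.screening[task]))
            lines.append("")
        lines.append("Control-quartile cutoffs "
                     f"({self.cutoffs.source}, n={self.cutoffs.n_controls}):")
        lines.append(self.cutoffs.table.round(3).to_string())
        lines.append("")
        for name, path in self.stepwise.items():
            lines.append(f"Model {name}: " + ", ".join(path.selected) if path.selected
                         else f"Model {name}: (no predictor entered)")
        lines.append("")
        for task in (IC_VS_CONTROL, HIC_VS_NHIC):
            best = self.best_rules.get(task)
            if best is not None:
                lines.append(f"Best {task} rule by training balanced AUC: {best}")
        lines.append("")
        for arm, rep in self.cascade_reports.items():
            lines.append(rep.summary())
            lines.append("")
        if self.subgroups is not None:
            lines.append(self.subgroups.summary())
        return "\n".join(lines)

    # -- bundle ----------------------------------------------------------
    def to_bundle(self, out_dir) -> None:
        """Write a deterministic machine-readable bundle of all tables.

        Delimited-text tables plus a JSON summary; byte-identical across
        reruns with the same cohort, config and seed (no timestamps).
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.comparability.to_csv(out / "comparability.csv")
        for task in self.screening:
            self.screening[task].to_csv(out / f"screening_{task.lower()}.csv")
        self.cutoffs.to_csv(out / "cutoffs.csv")
        for task in self.rule_reports:
            self.rule_table(task).to_csv(out / f"rules_{task.lower()}.csv")
        self.split.to_json(out / "split.json")

        payload = {
            "config": dataclasses.asdict(self.config),
            "group_sizes": self.group_sizes,
            "arm_sizes": self.split.sizes(),
            "stepwise": {
                name: {
                    "selected": path.selected,
                    "steps": [
                        {
                            "predictor": s.predictor,
                            "llf_before": s.llf_before,
                            "llf_after": s.llf_after,
                            "lrt": s.lrt,
                            "pvalue": s.pvalue,
                        }
                        for s in path.steps
                    ],
                    "odds_ratios": (
                        {
                            k: [float(v), float(ci[0]), float(ci[1])]
                            for k, v, ci in zip(
                                path.final_results.model.exog_names,
                                path.final_results.odds_ratios,
                                path.final_results.conf_int().to_numpy(),
                            )
                        }
                        if path.final_results is not None
                        else {}
                    ),
                }
                for name, path in self.stepwise.items()
            },
            "best_rules": {k: str(v) for k, v in self.best_rules.items()},
            "rule_reports": {
                task: {
                    arm: [r.as_dict() for r in reps]
                    for arm, reps in by_arm.items()
                }
                for task, by_arm in self.rule_reports.items()
            },
            "cascade": {
                arm: {
                    "confusion": rep.confusion.to_dict(),
                    "stage1": rep.stage1.as_dict(),
                    "stage2": rep.stage2.as_dict(),
                    "n_non_evaluable": rep.n_non_evaluable,
                }
                for arm, rep in self.cascade_reports.items()
            },
            "subgroups": (
                {
                    "table": self.subgroups.table.to_dict(),
                    "test": self.subgroups.test,
                    "statistic": self.subgroups.statistic,
                    "pvalue": self.subgroups.pvalue,
                }
                if self.subgroups is not None
                else None
            ),
        }
        with open(out / "bundle.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, allow_nan=True)
            fh.write("\n")


class DiagnosticStudy:
    """Top-level model object: the full cluster-diagnostic analysis.

    Parameters
    ----------
    cohort : Cohort
        Raw-concentration cohort (log transformation is applied internally
        for the screening step when configured; quartile cutoffs always use
        the raw scale).
    config : StudyConfig, optional
    """

    def __init__(self, cohort: Cohort, config: StudyConfig | None = None):
        if cohort.log_scale:
            raise ValueError("DiagnosticStudy expects raw concentrations")
        self.cohort = cohort
        self.config = config or StudyConfig()

    def fit(self, seed: int | None = None) -> StudyResults:
        """Run the full pipeline; deterministic given cohort, config and seed."""
        cfg = self.config if seed is None else dataclasses.replace(self.config, seed=seed)
        cohort = self.cohort
        split = stratified_split(
            cohort, train_fraction=cfg.train_fraction, seed=cfg.seed, stratify=cfg.stratify
        )
        comparability = compare_arms(cohort, split, welch=cfg.welch)

        # screening operates on the log scale when configured; the rank AUC
        # is invariant to the monotone transform, so gates agree either way
        screen_source = log_transform(cohort) if cfg.log_transform else cohort
        screening = {
            task: screen_biomarkers(screen_source, split, task=task, gate=cfg.gate)
            for task in (IC_VS_CONTROL, HIC_VS_NHIC)
        }

        cutoffs = build_cutoff_table(
            cohort, split, source=cfg.cutoff_source, method=cfg.quantile_method
        )

        train = cohort.subset(split.train_ids)
        stepwise: dict[str, StepwisePath] = {}
        for model_prefix, task in (("1", IC_VS_CONTROL), ("2", HIC_VS_NHIC)):
            retained = screening[task].retained
            pos_groups, neg_groups = task_labels(task)
            g = train.groups.to_numpy()
            keep = np.isin(g, pos_groups + neg_groups)
            outcome = np.isin(g, pos_groups)[keep].astype(float)
            task_cohort = Cohort(train.df.loc[keep], validate=False)
            for level_idx, level in enumerate(("CQ2", "CQ3"), start=1):
                name = f"{model_prefix}-{level_idx}"
                if not retained:
                    stepwise[name] = StepwisePath(entry_alpha=cfg.entry_alpha)
                    continue
                design = dichotomize(task_cohort, cutoffs, level, biomarkers=retained)
                stepwise[name] = forward_stepwise(
                    design, outcome, entry_alpha=cfg.entry_alpha
                )

        # rule families over the stepwise-selected biomarkers
        rule_reports: dict[str, dict[str, list[PerformanceReport]]] = {}
        best_rules: dict[str, ClusterRule] = {}
        for model_prefix, task in (("1", IC_VS_CONTROL), ("2", HIC_VS_NHIC)):
            lits_by_level = {}
            for level_idx, level in enumerate(("CQ2", "CQ3"), start=1):
                path = stepwise[f"{model_prefix}-{level_idx}"]
                lits_by_level[level] = [ThresholdLiteral.parse(p) for p in path.selected]
            if not (lits_by_level["CQ2"] or lits_by_level["CQ3"]):
                rule_reports[task] = {TRAIN: [], TEST: []}
                continue
            rules = rule_family(lits_by_level["CQ2"], lits_by_level["CQ3"])
            by_arm: dict[str, list[PerformanceReport]] = {}
            for arm in (TRAIN, TEST):
                by_arm[arm] = [
                    evaluate_rule(rule, cohort, split, arm, task, cutoffs) for rule in rules
                ]
            rule_reports[task] = by_arm
            ranked = rank_rules(by_arm[TRAIN])
            best_rules[task] = ClusterRule.parse(ranked[0].rule)

        cascade_reports = {}
        if IC_VS_CONTROL in best_rules and HIC_VS_NHIC in best_rules:
            model = cascade_mod.CascadeModel(
                model1_rule=best_rules[IC_VS_CONTROL],
                model2_rule=best_rules[HIC_VS_NHIC],
                cutoffs=cutoffs,
            )
            for arm in (TRAIN, TEST):
                cascade_reports[arm] = cascade_mod.evaluate_cascade(model, cohort, split, arm)

        subgroups = None
        try:
            subgroups = cascade_mod.nhic_subgroups(
                cohort,
                None,
                None,
                cutoffs,
                mbc_threshold=cfg.mbc_threshold,
                grade_threshold=cfg.grade_threshold,
                biomarker=cfg.subgroup_biomarker,
                level=cfg.subgroup_level,
            )
        except ValueError:
            pass  # covariates absent: subgroup analysis not applicable

        return StudyResults(
            config=cfg,
            split=split,
            comparability=comparability,
            screening=screening,
            cutoffs=cutoffs,
            stepwise=stepwise,
            rule_reports=rule_reports,
            best_rules=best_rules,
            cascade_reports=cascade_reports,
            subgroups=subgroups,
            group_sizes=cohort.group_sizes(),
        )


def run_pipeline(cohort: Cohort, config: StudyConfig | None = None) -> StudyResults:
    """Functional wrapper: ``DiagnosticStudy(cohort, config).fit()``."""
    return DiagnosticStudy(cohort, config).fit()
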