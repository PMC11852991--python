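"""Cluster-rule semantics, enumeration, and performance reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from uropanel import (
    ClusterRule,
    CutoffTable,
    PerformanceReport,
    ThresholdLiteral,
    apply_rule,
    apply_rule_cohort,
    enumerate_rules,
    evaluate_rule,
    rank_auc,
    rank_rules,
)
from uropanel.rules import mixed_level_rules, rule_family

from conftest import make_cohort

HEADLINE = "TNF-a>=CQ3|8-OHdG>=CQ3 & 8-isoprostane>=CQ2"


class TestRuleGrammar:
    def test_parse_and_canonical_string(self):
        rule = ClusterRule.parse(HEADLINE)
        assert len(rule.clauses) == 2
        assert ClusterRule.parse(str(rule)) == rule
        # clause order is canonical, so the reversed text parses equal
        rev = ClusterRule.parse("8-isoprostane>=CQ2 & 8-OHdG>=CQ3|TNF-a>=CQ3")
        assert rev == rule

    def test_unknown_biomarker_rejected(self):
        with pytest.raises(ValueError, match="canonical"):
            ClusterRule.parse("BDNF>=CQ3")

    def test_duplicate_literal_in_clause_rejected(self):
        lit = ThresholdLiteral("TNF-a", "CQ3")
        with pytest.raises(ValueError, match="duplicate"):
            ClusterRule([[lit, lit]])


class TestApplyRule:
    def test_headline_rule_fires(self, reference_cutoffs):
        subject = {"TNF-a": 1.2, "8-OHdG": 3.0, "8-isoprostane": 14.0}
        assert apply_rule(ClusterRule.parse(HEADLINE), subject, reference_cutoffs) == 1

    def test_single_literal_rule_reduces_to_exceeds(self, reference_cutoffs):
        rule = ClusterRule.parse("IP-10>=CQ3")
        assert apply_rule(rule, {"IP-10": 19.94}, reference_cutoffs) == 1
        assert apply_rule(rule, {"IP-10": 19.93}, reference_cutoffs) == 0

    def test_always_false_clause_vetoes(self, reference_cutoffs):
        # second clause cannot be satisfied -> AND semantics give 0
        rule = ClusterRule.parse("TNF-a>=CQ2 & IL-8>=CQ3")
        subject = {"TNF-a": 100.0, "IL-8": 0.0}
        assert apply_rule(rule, subject, reference_cutoffs) == 0

    def test_missing_biomarker_is_non_evaluable(self, reference_cutoffs):
        with pytest.raises(ValueError, match="non-evaluable"):
            apply_rule(
                ClusterRule.parse(HEADLINE),
                {"TNF-a": 1.2, "8-OHdG": np.nan, "8-isoprostane": 14.0},
                reference_cutoffs,
            )

    def test_cohort_vectorization_matches_scalar(self, cohort, reference_cutoffs):
        rule = ClusterRule.parse(HEADLINE)
        vec = apply_rule_cohort(rule, cohort, reference_cutoffs)
        for idx in [0, 50, 200, 421]:
            row = cohort.df.iloc[idx]
            assert vec.iloc[idx] == apply_rule(rule, row, reference_cutoffs)


class TestPerformanceReport:
    def test_rates_from_confusion_counts(self):
        rep = PerformanceReport.from_counts(tp=15, fn=7, fp=32, tn=211)
        assert rep.sensitivity == pytest.approx(0.682, abs=5e-4)
        assert rep.specificity == pytest.approx(0.868, abs=5e-4)
        assert rep.accuracy == pytest.approx(0.853, abs=5e-4)
        assert round(rep.balanced_auc, 2) == 0.78

    def test_always_positive_rule_is_chance(self):
        rep = PerformanceReport.from_counts(tp=50, fn=0, fp=30, tn=0)
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0
        assert rep.balanced_auc == 0.5

    @given(
        tp=st.integers(0, 400), fn=st.integers(0, 400),
        fp=st.integers(0, 400), tn=st.integers(0, 400),
    )
    def test_accuracy_identity(self, tp, fn, fp, tn):
        if tp + fn == 0 or fp + tn == 0:
            return
        rep = PerformanceReport.from_counts(tp, fn, fp, tn)
        want = (rep.sensitivity * rep.n_pos + rep.specificity * rep.n_neg) / (
            rep.n_pos + rep.n_neg
        )
        assert rep.accuracy == pytest.approx(want, abs=1e-12)


class TestEvaluateRule:
    def test_balanced_auc_equals_rank_auc_of_binary_outputs(self, cohort, reference_cutoffs):
        rule = ClusterRule.parse(HEADLINE)
        rep = evaluate_rule(rule, cohort, None, "TRAIN", "IC_VS_CONTROL", reference_cutoffs)
        pred = apply_rule_cohort(rule, cohort, reference_cutoffs).to_numpy()
        g = cohort.df["group"].to_numpy()
        a = rank_auc(pred[g != "CONTROL"], pred[g == "CONTROL"])
        assert rep.balanced_auc == pytest.approx(a, abs=1e-12)

    def test_non_evaluable_subjects_counted(self, reference_cutoffs):
        c = make_cohort(
            ["NHIC", "NHIC", "CONTROL", "CONTROL"],
            **{"IP-10": [25.0, np.nan, 1.0, 2.0]},
        )
        rep = evaluate_rule(
            ClusterRule.parse("IP-10>=CQ3"), c, None, "TRAIN", "IC_VS_CONTROL",
            reference_cutoffs,
        )
        assert rep.n_excluded == 1
        assert rep.tp + rep.fn + rep.fp + rep.tn == 3

    def test_or_literal_never_decreases_sensitivity(self, cohort, reference_cutoffs):
        base = ClusterRule.parse("TNF-a>=CQ3 & 8-isoprostane>=CQ2")
        widened = ClusterRule.parse("TNF-a>=CQ3|8-OHdG>=CQ3 & 8-isoprostane>=CQ2")
        r1 = evaluate_rule(base, cohort, None, "TRAIN", "IC_VS_CONTROL", reference_cutoffs)
        r2 = evaluate_rule(widened, cohort, None, "TRAIN", "IC_VS_CONTROL", reference_cutoffs)
        assert r2.sensitivity >= r1.sensitivity

    def test_extra_clause_never_decreases_specificity(self, cohort, reference_cutoffs):
        base = ClusterRule.parse("TNF-a>=CQ3|8-OHdG>=CQ3")
        narrowed = ClusterRule.parse(HEADLINE)
        r1 = evaluate_rule(base, cohort, None, "TRAIN", "IC_VS_CONTROL", reference_cutoffs)
        r2 = evaluate_rule(narrowed, cohort, None, "TRAIN", "IC_VS_CONTROL", reference_cutoffs)
        assert r2.specificity >= r1.specificity


class TestEnumeration:
    @pytest.mark.parametrize("k,expected", [(1, 1), (2, 2), (3, 5), (4, 9)])
    def test_rule_counts_match_partition_arithmetic(self, k, expected):
        # 1 all-OR + 1 all-AND + (2^(k-1) - 1) two-clause partitions, deduplicated
        names = ["TNF-a", "8-OHdG", "8-isoprostane", "IP-10"][:k]
        lits = [ThresholdLiteral(n, "CQ3") for n in names]
        rules = enumerate_rules(lits)
        assert len(rules) == expected
        assert len(set(rules)) == len(rules)

    def test_too_many_literals_guarded(self):
        names = ["eotaxin", "IL-2", "IL-6", "IL-8", "IP-10", "MCP-1", "MIP-1b",
                 "RANTES", "TNF-a"]
        lits = [ThresholdLiteral(n, "CQ3") for n in names]
        with pytest.raises(ValueError, match="explicit"):
            enumerate_rules(lits)

    def test_mixed_level_rules_cover_headline_shape(self):
        rules = mixed_level_rules(["TNF-a", "8-OHdG", "8-isoprostane"])
        assert ClusterRule.parse(HEADLINE) in rules

    def test_rule_family_union_is_deduplicated(self):
        lits2 = [ThresholdLiteral("TNF-a", "CQ2"), ThresholdLiteral("8-OHdG", "CQ2")]
        lits3 = [ThresholdLiteral("TNF-a", "CQ3"), ThresholdLiteral("8-OHdG", "CQ3")]
        fam = rule_family(lits2, lits3)
        assert len(set(fam)) == len(fam)
        assert ClusterRule([[ThresholdLiteral("TNF-a", "CQ2"),
                             ThresholdLiteral("8-OHdG", "CQ2")]]) in fam


class TestRanking:
    def _report(self, auc, sens, name):
        tp = int(round(sens * 100))
        spec = 2 * auc - sens
        tn = int(round(spec * 100))
        return PerformanceReport(tp=tp, fn=100 - tp, fp=100 - tn, tn=tn, rule=name,
                                 arm="TRAIN", task="IC_VS_CONTROL")

    def test_descending_by_criterion_then_sensitivity(self):
        reports = [
            self._report(0.70, 0.60, "b"),
            self._report(0.75, 0.70, "c"),
            self._report(0.75, 0.80, "a"),
        ]
        ranked = rank_rules(reports)
        assert [r.rule for r in ranked] == ["a", "c", "b"]

    def test_full_ties_preserve_input_order(self):
        reports = [self._report(0.7, 0.6, "same") for _ in range(3)]
        assert rank_rules(reports) == reports

    def test_single_report(self):
        r = self._report(0.7, 0.6, "only")
        assert rank_rules([r]) == [r]

    def test_mixed_arms_rejected(self):
        a = self._report(0.7, 0.6, "x")
        b = self._report(0.7, 0.6, "y")
        b.arm = "TEST"
        with pytest.raises(ValueError):
            rank_rules([a, b])
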