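"""Two-stage cascade classification and the NHIC severity subgroup analysis."""

import dataclasses

import numpy as np
import pytest

from uropanel import (
    CascadeModel,
    ClusterRule,
    classify,
    classify_cohort,
    default_config,
    evaluate_cascade,
    evaluate_rule,
    generate_cohort,
    nhic_subgroups,
    stratified_split,
)
from uropanel.cascade import HIC_PRED, NHIC_PRED, NON_IC

from conftest import make_cohort


@pytest.fixture
def model(reference_cutoffs):
    return CascadeModel.from_strings(reference_cutoffs)


class TestClassify:
    def test_stage1_short_circuit(self, model):
        subject = {"TNF-a": 0.1, "8-OHdG": 1.0, "8-isoprostane": 1.0, "IP-10": 50.0}
        assert classify(model, subject) == NON_IC

    def test_stage2_separates_nhic_from_hic(self, model):
        subject = {"TNF-a": 0.95, "8-OHdG": 1.0, "8-isoprostane": 13.35, "IP-10": 2.0}
        assert classify(model, subject) == NHIC_PRED
        subject["IP-10"] = 25.0
        assert classify(model, subject) == HIC_PRED

    def test_labels_partition_the_arm(self, reference_cutoffs, default_cfg):
        cfg = dataclasses.replace(default_cfg, missing_rate=0.08)
        c = generate_cohort(cfg, seed=99)
        model = CascadeModel.from_strings(reference_cutoffs)
        labels = classify_cohort(model, c)
        n_labelled = labels.isin([NON_IC, NHIC_PRED, HIC_PRED]).sum()
        assert n_labelled + labels.isna().sum() == len(c)


class TestEvaluateCascade:
    def test_stage_reports_equal_standalone_rule_evaluation(self, cohort, model):
        split = stratified_split(cohort, 0.7, seed=6)
        rep = evaluate_cascade(model, cohort, split, "TRAIN")
        s1 = evaluate_rule(model.model1_rule, cohort, split, "TRAIN",
                           "IC_VS_CONTROL", model.cutoffs)
        s2 = evaluate_rule(model.model2_rule, cohort, split, "TRAIN",
                           "HIC_VS_NHIC", model.cutoffs)
        assert (rep.stage1.tp, rep.stage1.fn, rep.stage1.fp, rep.stage1.tn) == (
            s1.tp, s1.fn, s1.fp, s1.tn
        )
        assert (rep.stage2.tp, rep.stage2.fn, rep.stage2.fp, rep.stage2.tn) == (
            s2.tp, s2.fn, s2.fp, s2.tn
        )

    def test_confusion_rows_sum_to_arm_composition(self, cohort, model):
        split = stratified_split(cohort, 0.7, seed=6)
        rep = evaluate_cascade(model, cohort, split, "TEST")
        test_arm = cohort.subset(split.test_ids)
        sizes = test_arm.group_sizes()
        totals = rep.confusion.sum(axis=1)
        assert totals["CONTROL"] + totals["NHIC"] + totals["HIC"] + rep.n_non_evaluable == len(
            test_arm
        )
        assert (totals <= [sizes["CONTROL"], sizes["NHIC"], sizes["HIC"]]).all()

    def test_never_firing_stage2_empties_hic_column(self, cohort, reference_cutoffs):
        # IL-8 cutoff far above any observed value
        cuts = reference_cutoffs.table.copy()
        cuts.loc["IL-8"] = [1e9, 1e9, 1e9]
        from uropanel import CutoffTable

        model = CascadeModel.from_strings(
            CutoffTable(cuts), model2_rule="IL-8>=CQ3"
        )
        rep = evaluate_cascade(model, cohort, None, "TRAIN")
        assert rep.confusion[HIC_PRED].sum() == 0

    def test_relaxing_stage2_only_moves_nhic_pred_to_hic_pred(self, cohort, reference_cutoffs):
        strict = CascadeModel.from_strings(
            reference_cutoffs, model2_rule="IP-10>=CQ3 & IL-6>=CQ3"
        )
        relaxed = CascadeModel.from_strings(reference_cutoffs, model2_rule="IP-10>=CQ3")
        a = classify_cohort(strict, cohort)
        b = classify_cohort(relaxed, cohort)
        changed = a[a != b]
        assert (changed == NHIC_PRED).all()
        assert (b[changed.index] == HIC_PRED).all()

    def test_controls_only_with_never_firing_stage1(self, reference_cutoffs):
        c = make_cohort(["CONTROL"] * 6, fill=0.0)
        model = CascadeModel.from_strings(reference_cutoffs)
        labels = classify_cohort(model, c)
        assert (labels == NON_IC).all()


class TestNhicSubgroups:
    def test_mbc_boundary_goes_to_high_stratum(self, reference_cutoffs):
        c = make_cohort(
            ["NHIC"] * 4,
            **{"IP-10": [30.0, 1.0, 30.0, 1.0]},
            MBC=[750.0, 750.0, 749.0, 749.0],
            glomerulation_grade=[2, 2, 2, 2],
        )
        rep = nhic_subgroups(c, None, None, reference_cutoffs)
        assert rep.table.loc["MBC<750 & grade>=2", "n"] == 2
        assert rep.table.loc["MBC>=750 & grade>=2", "n"] == 2

    def test_subgroup_sizes_partition_complete_cases(self, cohort, reference_cutoffs):
        rep = nhic_subgroups(cohort, None, None, reference_cutoffs)
        nhic = cohort.df[cohort.df["group"] == "NHIC"]
        complete = (
            nhic["MBC"].notna() & nhic["glomerulation_grade"].notna() & nhic["IP-10"].notna()
        ).sum()
        assert rep.table["n"].sum() == complete

    def test_coupling_lifts_severe_subgroup_with_power(self, default_cfg, reference_cutoffs):
        """With the +1.5 log-odds severity coupling on, the low-MBC/high-grade
        subgroup shows the highest IP-10 exceedance and the association test
        rejects in nearly every replicate."""
        cfg = dataclasses.replace(default_cfg, couple_ip10=True)
        cuts = _theoretical_cutoffs(cfg)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            c = generate_cohort(cfg, seed=10_000 + i)
            rep = nhic_subgroups(c, None, None, cuts)
            severe = rep.table["proportion"].iloc[0]
            if severe == rep.table["proportion"].max() and rep.pvalue <= 0.05:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_no_coupling_is_null(self, default_cfg, reference_cutoffs):
        cuts = _theoretical_cutoffs(default_cfg)
        rejections = 0
        n_rep = 100
        for i in range(n_rep):
            c = generate_cohort(default_cfg, seed=20_000 + i)
            rep = nhic_subgroups(c, None, None, cuts)
            rejections += rep.pvalue <= 0.05
        # 95% binomial band around alpha = 0.05 at 100 replicates
        assert rejections <= 10

    def test_all_covariates_missing_rejected(self, reference_cutoffs):
        c = make_cohort(["NHIC"] * 4, **{"IP-10": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            nhic_subgroups(c, None, None, reference_cutoffs)


def _theoretical_cutoffs(cfg):
    """Closed-form control quartiles of the generator's calibration."""
    from scipy.stats import norm

    from uropanel import CutoffTable

    z = norm.ppf([0.25, 0.5, 0.75])
    return CutoffTable.from_dict(
        {
            name: tuple(np.exp(cfg.mu0[name] + cfg.sigma[name] * z))
            for name in cfg.mu0
        },
        source="THEORETICAL",
    )
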