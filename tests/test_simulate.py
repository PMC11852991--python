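"""Synthetic cohort generator: AUC calibration, quantile matching, determinism."""

import dataclasses
import io

import numpy as np
import pytest
from scipy.stats import norm

from uropanel import (
    BIOMARKERS,
    GeneratorConfig,
    auc_to_shift,
    default_config,
    generate_cohort,
    implied_auc,
    rank_auc,
    read_cohort,
    write_cohort,
)
from uropanel.screening import hanley_mcneil_se


class TestAucToShift:
    def test_no_separation_gives_zero_shift(self):
        assert auc_to_shift(0.5, 1.0) == 0.0
        assert auc_to_shift(0.5, 3.7) == 0.0

    def test_closed_form_value(self):
        # auc = Phi(1) -> delta = sigma * sqrt(2) * 1
        assert auc_to_shift(norm.cdf(1.0), 1.0) == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_symmetry_below_half(self):
        assert auc_to_shift(0.2, 1.3) == pytest.approx(-auc_to_shift(0.8, 1.3), rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_degenerate_auc_rejected(self, bad):
        with pytest.raises(ValueError):
            auc_to_shift(bad, 1.0)


class TestDefaultConfig:
    def test_group_sizes_match_study_cohort(self, default_cfg):
        assert default_cfg.group_sizes == (46, 334, 42)

    def test_il2_screened_out_for_ic_task(self, default_cfg):
        assert default_cfg.auc_ic["IL-2"] < 0.6

    def test_control_quartiles_recovered_within_15_percent(self, default_cfg):
        """A large generated control arm reproduces the calibration quartiles."""
        cfg = dataclasses.replace(default_cfg, group_sizes=(20_000, 1, 1))
        c = generate_cohort(cfg, seed=42)
        controls = c.df[c.df["group"] == "CONTROL"]
        v = controls["TNF-a"].to_numpy(float)
        q = np.quantile(v, [0.25, 0.5, 0.75], method="weibull")
        for got, want in zip(q, (0.62, 0.73, 0.95)):
            assert abs(got - want) / want < 0.15

    def test_control_quantiles_match_lognormal_closed_form(self, default_cfg):
        cfg = dataclasses.replace(default_cfg, group_sizes=(20_000, 1, 1))
        c = generate_cohort(cfg, seed=9)
        controls = c.df[c.df["group"] == "CONTROL"]
        for name in ("IP-10", "8-OHdG"):
            mu, s = default_cfg.mu0[name], default_cfg.sigma[name]
            for p in (0.1, 0.5, 0.9):
                want = np.exp(mu + s * norm.ppf(p))
                got = np.quantile(controls[name].to_numpy(float), p)
                assert got == pytest.approx(want, rel=0.1)


class TestGenerateCohort:
    def test_null_generator_groups_exchangeable(self, default_cfg):
        flat = {name: 0.5 for name in BIOMARKERS}
        cfg = dataclasses.replace(
            default_cfg, group_sizes=(300, 600, 100), auc_ic=flat, auc_hic=flat
        )
        c = generate_cohort(cfg, seed=5)
        g = c.df["group"].to_numpy()
        for name in ("TNF-a", "IP-10", "TAC"):
            v = c.df[name].to_numpy(float)
            pos = v[g != "CONTROL"]
            neg = v[g == "CONTROL"]
            a = rank_auc(pos, neg)
            assert abs(a - 0.5) <= 3 * hanley_mcneil_se(0.5, pos.size, neg.size)

    def test_configured_auc_recovered(self, default_cfg):
        """Empirical 8-OHdG AUC at n=(200, 800, 100) sits inside the
        Monte-Carlo band of its configured 0.845 separation."""
        cfg = dataclasses.replace(default_cfg, group_sizes=(200, 800, 100))
        c = generate_cohort(cfg, seed=77)
        g = c.df["group"].to_numpy()
        v = c.df["8-OHdG"].to_numpy(float)
        a = rank_auc(v[g != "CONTROL"], v[g == "CONTROL"])
        target = implied_auc(cfg, "IC_VS_CONTROL", "8-OHdG")
        assert abs(a - target) <= 3 * hanley_mcneil_se(target, 900, 200)

    def test_seed_reproducibility_byte_identical(self, default_cfg):
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_cohort(generate_cohort(default_cfg, seed=31), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_generated_cohort_passes_read_validation(self, tmp_path, default_cfg):
        cfg = dataclasses.replace(default_cfg, missing_rate=0.05)
        c = generate_cohort(cfg, seed=2)
        path = tmp_path / "c.csv"
        write_cohort(c, path)
        assert len(read_cohort(path)) == len(c)

    def test_covariates_only_for_ic_groups(self, cohort):
        df = cohort.df
        assert df.loc[df["group"] == "CONTROL", "MBC"].isna().all()
        assert df.loc[df["group"] != "CONTROL", "MBC"].notna().all()
        grades = df.loc[df["group"] != "CONTROL", "glomerulation_grade"]
        assert grades.between(0, 4).all()

    def test_ip10_coupling_raises_severe_subgroup_exceedance(self, default_cfg):
        cfg = dataclasses.replace(default_cfg, couple_ip10=True, group_sizes=(46, 2000, 42))
        c = generate_cohort(cfg, seed=8)
        df = c.df[c.df["group"] == "NHIC"]
        severe = (df["MBC"] < 750) & (df["glomerulation_grade"] >= 2)
        cq3 = np.exp(cfg.mu0["IP-10"] + norm.ppf(0.75) * cfg.sigma["IP-10"])
        p_severe = (df.loc[severe, "IP-10"] >= cq3).mean()
        p_rest = (df.loc[~severe, "IP-10"] >= cq3).mean()
        assert p_severe > p_rest + 0.1

    def test_invalid_config_rejected(self, default_cfg):
        with pytest.raises(ValueError):
            dataclasses.replace(default_cfg, group_sizes=(0, 10, 10)).validate()
        bad = dict(default_cfg.sigma)
        bad["IL-6"] = 0.0
        with pytest.raises(ValueError):
            dataclasses.replace(default_cfg, sigma=bad).validate()


class TestImpliedAuc:
    def test_hic_task_is_exactly_configured(self, default_cfg):
        assert implied_auc(default_cfg, "HIC_VS_NHIC", "IP-10") == default_cfg.auc_hic["IP-10"]

    def test_ic_task_mixture_formula(self, default_cfg):
        # the HIC fraction of the positive class pulls the induced AUC toward
        # Phi(z_ic + z_hic)
        got = implied_auc(default_cfg, "IC_VS_CONTROL", "IP-10")
        z = norm.ppf(default_cfg.auc_ic["IP-10"]) + norm.ppf(default_cfg.auc_hic["IP-10"])
        w_hic = 42 / 376
        want = (1 - w_hic) * default_cfg.auc_ic["IP-10"] + w_hic * norm.cdf(z)
        assert got == pytest.approx(want, rel=1e-12)
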