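"""Synthetic cohort generator for the urinary biomarker panel.

Emulates the data structure the diagnostic analysis assumes: right-skewed
(log-normal) biomarker concentrations per group, configurable group-separation
strengths expressed directly as target AUCs, group sizes, and the clinical
covariates (MBC, glomerulation grade) used by the NHIC subgroup analysis.

The statistical device is the binormal link between a rank AUC and a
location shift on the log scale: with equal log-sd ``sigma`` in both groups,
a shift ``delta = sigma * sqrt(2) * Phi^{-1}(auc)`` yields exactly the target
AUC for that two-group comparison.  Controls are drawn at ``(mu0, sigma)``;
both IC/BPS groups are shifted by ``delta_ic`` (from the IC-vs-control target)
and the HIC group additionally by ``delta_hic`` (HIC-vs-NHIC target, applied
relative to NHIC).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .cohort import BIOMARKERS, CONTROL, HIC, NHIC, Cohort

__all__ = [
    "GeneratorConfig",
    "auc_to_shift",
    "default_config",
    "generate_cohort",
    "implied_auc",
]

# Published control-group quartiles (CQ1, CQ2, CQ3) used to calibrate the
# control log-normal parameters of the nine biomarkers they cover.
_CONTROL_QUARTILES = {
    "eotaxin": (1.60, 3.41, 6.59),
    "IL-6": (0.60, 0.84, 1.16),
    "IL-8": (1.31, 4.42, 12.63),
    "IP-10": (1.80, 3.74, 19.94),
    "MCP-1": (28.32, 106.16, 230.25),
    "RANTES": (1.97, 3.80, 8.04),
    "TNF-a": (0.62, 0.73, 0.95),
    "8-OHdG": (4.74, 13.90, 22.34),
    "8-isoprostane": (6.94, 13.35, 22.10),
}

# Cohort-level mean +/- SD for the four biomarkers without published control
# quartiles; log-normal parameters are moment-matched from these.
_MEAN_SD = {
    "IL-2": (0.3, 0.2),
    "MIP-1b": (1.9, 4.9),
    "NGF": (0.2, 0.1),
    "TAC": (992.9, 1167.4),
}

# Default group-separation targets: directional screening AUCs, training set.
_AUC_IC = {
    "eotaxin": 0.622, "IL-2": 0.009, "IL-6": 0.505, "IL-8": 0.573,
    "IP-10": 0.376, "MCP-1": 0.681, "MIP-1b": 0.265, "RANTES": 0.402,
    "TNF-a": 0.775, "NGF": 0.210, "8-OHdG": 0.845, "8-isoprostane": 0.717,
    "TAC": 0.488,
}
_AUC_HIC = {
    "eotaxin": 0.586, "IL-2": 0.512, "IL-6": 0.741, "IL-8": 0.736,
    "IP-10": 0.794, "MCP-1": 0.532, "MIP-1b": 0.540, "RANTES": 0.658,
    "TNF-a": 0.535, "NGF": 0.475, "8-OHdG": 0.477, "8-isoprostane": 0.411,
    "TAC": 0.428,
}

_Z75 = norm.ppf(0.75)  # 0.6745: z-score of the 3rd quartile


def auc_to_shift(auc: float, sigma: float) -> float:
    """Log-mean shift producing a target two-group AUC under equal log-sd.

    ``delta = sigma * sqrt(2) * Phi^{-1}(auc)``.  AUC 0.5 maps to zero shift;
    AUC values below 0.5 map to negative shifts (directional, no flipping).
    """
    if not 0.0 < auc < 1.0:
        raise ValueError(f"target AUC must be in (0, 1); got {auc} (infinite shift)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(sigma * math.sqrt(2.0) * norm.ppf(auc))


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    group_sizes : (n_control, n_nhic, n_hic)
    mu0, sigma : dict
        Control-group log-normal parameters per biomarker.
    auc_ic, auc_hic : dict
        Target directional AUCs per biomarker for IC/BPS-vs-control and
        HIC-vs-NHIC.
    mbc_params : dict
        ``{group: (mean, sd)}`` of maximal bladder capacity (mL) for the two
        IC/BPS groups; controls carry no MBC.
    glomerulation_probs : dict
        ``{group: [p0..p4]}`` category probabilities of the glomerulation
        grade for the two IC/BPS groups.
    couple_ip10 : bool
        When True, NHIC subjects in the severe subgroup (MBC below
        ``mbc_threshold`` and grade at or above ``grade_threshold``) have
        their IP-10 drawn from a distribution whose probability of exceeding
        the theoretical control CQ3 is bumped by
        ``ip10_severity_log_odds`` on the log-odds scale.
    missing_rate : float
        Independent per-cell probability of a missing biomarker value.
    """

    group_sizes: tuple[int, int, int] = (46, 334, 42)
    mu0: dict = field(default_factory=dict)
    sigma: dict = field(default_factory=dict)
    auc_ic: dict = field(default_factory=dict)
    auc_hic: dict = field(default_factory=dict)
    age_mean: float = 53.9
    age_sd: float = 13.2
    mbc_params: dict = field(default_factory=lambda: {NHIC: (700.0, 200.0), HIC: (600.0, 180.0)})
    glomerulation_probs: dict = field(
        default_factory=lambda: {
            NHIC: (0.10, 0.30, 0.35, 0.20, 0.05),
            HIC: (0.05, 0.15, 0.30, 0.30, 0.20),
        }
    )
    couple_ip10: bool = False
    ip10_severity_log_odds: float = 1.5
    mbc_threshold: float = 750.0
    grade_threshold: int = 2
    missing_rate: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if len(self.group_sizes) != 3 or any(int(n) < 1 for n in self.group_sizes):
            raise ValueError("group_sizes must be three integers >= 1")
        for name in BIOMARKERS:
            if name not in self.mu0 or name not in self.sigma:
                raise ValueError(f"missing log-normal parameters for biomarker {name!r}")
            if self.sigma[name] <= 0:
                raise ValueError(f"sigma must be > 0 for biomarker {name!r}")
            for d in (self.auc_ic, self.auc_hic):
                a = d.get(name, 0.5)
                if not 0.0 < a < 1.0:
                    raise ValueError(f"target AUC for {name!r} must be in (0, 1); got {a}")
        for g, probs in self.glomerulation_probs.items():
            if len(probs) != 5 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"glomerulation probabilities for {g!r} must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "group_sizes" in d:
            d["group_sizes"] = tuple(int(x) for x in d["group_sizes"])
        base = default_config()
        for key in ("mu0", "sigma", "auc_ic", "auc_hic"):
            merged = dict(getattr(base, key))
            merged.update(d.get(key, {}))
            d[key] = merged
        cfg = dataclasses.replace(base, **d)
        cfg.validate()
        return cfg


def default_config() -> GeneratorConfig:
    """Generator calibrated to the study's published summaries.

    Control log-normal parameters are solved from the published control
    quartiles where available (``mu0`` = mean of ln CQ1 and ln CQ3, ``sigma``
    from their spread over ``2 * Phi^{-1}(0.75)``), and moment-matched from
    the cohort mean +/- SD otherwise.  Target AUCs are the published training
    screening AUCs for both tasks; group sizes are (46 controls, 334 NHIC,
    42 HIC).
    """
    mu0, sigma = {}, {}
    for name, (q1, _q2, q3) in _CONTROL_QUARTILES.items():
        mu0[name] = (math.log(q1) + math.log(q3)) / 2.0
        sigma[name] = (math.log(q3) - math.log(q1)) / (2.0 * _Z75)
    for name, (mean, sd) in _MEAN_SD.items():
        s2 = math.log(1.0 + (sd / mean) ** 2)
        mu0[name] = math.log(mean) - s2 / 2.0
        sigma[name] = math.sqrt(s2)
    cfg = GeneratorConfig(mu0=mu0, sigma=sigma, auc_ic=dict(_AUC_IC), auc_hic=dict(_AUC_HIC))
    cfg.validate()
    return cfg


def implied_auc(config: GeneratorConfig, task: str, biomarker: str) -> float:
    """Closed-form AUC the generator induces for a screening task.

    For ``HIC_VS_NHIC`` this equals the configured ``auc_hic`` exactly.  For
    ``IC_VS_CONTROL`` the positive class is a NHIC/HIC mixture, and because
    HIC carries the additional HIC-vs-NHIC shift the induced AUC is the
    size-weighted mixture ``w_nhic * auc_ic + w_hic * Phi(z_ic + z_hic)``
    with ``z = Phi^{-1}(auc)``.
    """
    a_ic = config.auc_ic.get(biomarker, 0.5)
    a_hic = config.auc_hic.get(biomarker, 0.5)
    if task == "HIC_VS_NHIC":
        return float(a_hic)
    if task != "IC_VS_CONTROL":
        raise ValueError(f"unknown task {task!r}")
    _, n_nhic, n_hic = config.group_sizes
    w_hic = n_hic / (n_nhic + n_hic)
    z_ic, z_hic = norm.ppf(a_ic), norm.ppf(a_hic)
    return float((1.0 - w_hic) * a_ic + w_hic * norm.cdf(z_ic + z_hic))


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Draw a synthetic cohort; fully reproducible from the seed.

    Biomarkers are log-normal per group with the AUC-calibrated shifts; age
    is drawn for all subjects; MBC and glomerulation grade only for the two
    IC/BPS groups.  With ``couple_ip10`` the severe NHIC subgroup's IP-10 is
    drawn from a shifted distribution so that its probability of exceeding
    the theoretical control CQ3 is higher by the configured log-odds bump.
    """
    config.validate()
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)

    n_control, n_nhic, n_hic = (int(n) for n in config.group_sizes)
    n = n_control + n_nhic + n_hic
    groups = np.array([CONTROL] * n_control + [NHIC] * n_nhic + [HIC] * n_hic, dtype=object)
    width = len(str(n))
    ids = [f"S{i + 1:0{width}d}" for i in range(n)]

    df = pd.DataFrame({"subject_id": ids, "group": groups})
    is_control = groups == CONTROL
    is_nhic = groups == NHIC
    is_hic = groups == HIC

    # clinical covariates (drawn before biomarkers so the IP-10 coupling can
    # see the severity subgroup)
    df["age"] = np.round(rng.normal(config.age_mean, config.age_sd, n).clip(18, 90), 1)
    mbc = np.full(n, np.nan)
    grade = np.full(n, np.nan)
    for g, mask in ((NHIC, is_nhic), (HIC, is_hic)):
        mean, sd = config.mbc_params[g]
        k = int(mask.sum())
        mbc[mask] = np.round(rng.normal(mean, sd, k).clip(150, 1500), 0)
        grade[mask] = rng.choice(5, size=k, p=np.asarray(config.glomerulation_probs[g], float))
    df["MBC"] = mbc
    df["glomerulation_grade"] = grade

    severe = is_nhic & (mbc < config.mbc_threshold) & (grade >= config.grade_threshold)

    for name in BIOMARKERS:
        mu0 = config.mu0[name]
        s = config.sigma[name]
        d_ic = auc_to_shift(config.auc_ic.get(name, 0.5), s)
        d_hic = auc_to_shift(config.auc_hic.get(name, 0.5), s)
        mu = np.full(n, mu0)
        mu[is_nhic] = mu0 + d_ic
        mu[is_hic] = mu0 + d_ic + d_hic
        if name == "IP-10" and config.couple_ip10 and severe.any():
            cq3 = math.exp(mu0 + _Z75 * s)  # theoretical control CQ3
            p0 = 1.0 - norm.cdf((math.log(cq3) - (mu0 + d_ic)) / s)
            p1 = float(expit(logit(p0) + config.ip10_severity_log_odds))
            mu[severe] = math.log(cq3) - s * norm.ppf(1.0 - p1)
        values = np.exp(mu + s * rng.standard_normal(n))
        if config.missing_rate > 0:
            values[rng.random(n) < config.missing_rate] = np.nan
        df[name] = values

    cols = ["subject_id", "group"] + list(BIOMARKERS) + ["age", "MBC", "glomerulation_grade"]
    return Cohort(df[cols])
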