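# Methods

This note documents the statistical procedures `uropanel` implements, the
choices made where the published analysis design left the details open, and
what the synthetic-data tests do and do not demonstrate.

## The diagnostic problem

Subjects carry one of three cystoscopically established labels — CONTROL,
NHIC (non-Hunner interstitial cystitis) or HIC (Hunner-lesion disease) —
and a vector of 13 urinary biomarker concentrations (pg/mL; total
antioxidant capacity in assay units). Two binary tasks are modelled:

* **IC/BPS vs control**: positives are NHIC ∪ HIC;
* **HIC vs NHIC**: within the IC/BPS population, controls excluded.

The analysis is deliberately threshold-based rather than score-based:
clinicians receive a Boolean rule over "biomarker ≥ control quartile"
predicates, not a fitted probability.

## Pipeline stages

### Train/test split

A seeded 70/30 split, stratified over the three groups, with
round-half-up training counts per stratum (strata of 46/334/42 at 0.70
give 32/234/29). Stratification is the package default for statistical
hygiene even though a plain random split would also be defensible; a
non-stratified mode exists. A stratum that would leave either arm empty is
an error rather than a silent imbalance.

### Log transformation

Biomarker concentrations are right-skewed; `log_transform` applies
`ln(c + ε)` with ε equal to half the smallest positive value of that
biomarker in the cohort (ε = 1 for an all-zero column). The rule keeps
zeros finite without disturbing ranks; ε is configurable. Because both the
rank AUC and the quartile thresholds are invariant to (or defined on) the
raw scale, the transform affects presentation and any downstream
parametric use, not the screening or dichotomization decisions — the test
suite asserts the retained sets agree with and without it.

### Screening

The rank AUC is the Mann–Whitney probability estimate with half credit for
ties, computed from midranks; it equals the trapezoidal ROC area and is
reported **directionally** (no `max(A, 1−A)` folding), so biomarkers lower
in cases show AUCs below 0.5. The retention gate `A ≥ 0.6` is inclusive.
Confidence intervals use the Hanley–McNeil standard error with the
exponential-model approximations `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`; the
published analysis does not state its interval method, and tests
cross-check this closed form against a 2 000-resample bootstrap. Missing
values are dropped pairwise per biomarker; more than 50 % missing in a
class is an error.

### Control-quartile cutoffs

CQ1/CQ2/CQ3 are empirical quartiles of the control sample on the raw
concentration scale. The quantile convention is the weighted average at
position `(n+1)p` — the default of the mainstream commercial statistics
software this style of analysis is typically run in — with the `(n−1)p`
linear-interpolation convention available by flag, since the published
values cannot adjudicate between the two without raw data. Cutoffs default
to **training-arm controls** (no test-set leakage); an all-controls policy
is provided because a control-group summary table may well have used all
46 controls. Exceedance is inclusive (`x ≥ CQ`).

### Logistic selection

Binary logistic regression is fitted by iteratively reweighted least
squares; convergence when the deviance changes by < 1e−8, cap 100
iterations. Complete/quasi-complete separation (|β| > 15 or exploding
standard errors) is flagged and the odds ratios reported as unavailable —
no Firth-type penalty, matching the plain odds ratios of the source
analysis. For a single binary predictor the MLE equals the 2×2
cross-product ratio and the Wald interval equals
`exp(ln OR ± z√(1/a+1/b+1/c+1/d))`; the tests exploit both identities, and
independently verify the optimum against a BFGS maximization of the
log-likelihood and against `statsmodels.Logit`.

Forward stepwise selection enters, at each step, the candidate with the
largest likelihood-ratio improvement provided its χ²₁ p-value is ≤ the
entry threshold (default 0.05 — the published account says only
"log-likelihood criteria", and 0.05 is its stated significance
convention); there is no removal step, and a zero-improvement candidate
(e.g. a duplicate) never enters. Candidate pools are the retained
biomarkers dichotomized at one level: four models in total
(IC/HIC task × CQ2/CQ3), mirroring the published model structure rather
than mixing levels inside one regression.

### Cluster rules

A rule is an AND of OR-clauses over threshold literals. The systematic
rule family scored for each task is: the all-OR rule, the all-AND rule and
every two-clause partition at each single level, plus mixed-level one- and
two-clause rules in which a subset of the selected biomarkers sits at CQ3
and the remainder at CQ2 (the shape of the published headline rule).
Enumeration is capped at 8 literals. Reports carry the confusion counts;
accuracy ≡ (sens·n₊ + spec·n₋)/(n₊+n₋) and the "AUC" of a binary rule is
its balanced accuracy (sens+spec)/2 — exactly its two-point trapezoidal
ROC area. Rules are ranked by training balanced AUC, ties broken by higher
sensitivity then rule string; the published account does not state how its
headline rule was chosen, so all metrics are retained alongside the
ranking. Subjects missing any biomarker a rule references are excluded
from that rule's confusion matrix and counted.

### Cascade and subgroups

Stage 1 (IC/BPS rule) routes negatives to non-IC/BPS; stage 2 (HIC rule,
default `IP-10>=CQ3`) splits the remainder into NHIC/HIC predictions. At
prediction time stage 2 sees whoever passed stage 1 regardless of truth;
at evaluation time the stage-2 report conditions on true IC/BPS membership
so that it coincides exactly with the standalone HIC-vs-NHIC rule
evaluation, and the performance among actually-forwarded subjects is
reported as a second view. The NHIC subgroup analysis stratifies by
MBC < 750 mL (strict; 750 itself is "large") and glomerulation grade ≥ 2,
and tests the combined severe subgroup against the rest for IP-10 ≥ CQ3
exceedance with Pearson's chi-square, switching to Fisher's exact test
when any expected cell is below 5.

### Comparability table

Train-vs-test comparisons use the pooled-variance Student's t-test by
default (Welch by flag) for continuous variables and chi-square/Fisher for
the group composition, two-tailed at α = 0.05.

## Synthetic cohort generator

Concentrations are log-normal per biomarker: controls at `(μ₀, σ)`, both
IC/BPS groups shifted by `δ_ic`, HIC additionally by `δ_hic`, with equal
log-sd across groups so that the binormal link
`δ = σ√2·Φ⁻¹(AUC)` makes every configured AUC exact and invertible.
Defaults:

* **μ₀, σ** — solved from the published control quartiles
  (`μ₀ = (ln CQ1 + ln CQ3)/2`, `σ = (ln CQ3 − ln CQ1)/(2Φ⁻¹(0.75))`) for
  the nine biomarkers that have them, and moment-matched from the
  cohort-level mean ± SD for IL-2, MIP-1b, NGF and TAC. Quartiles win over
  means where both exist, because quartiles drive every downstream cutoff.
* **Target AUCs** — the published training screening AUCs for both tasks,
  applied directionally.
* **Group sizes** — (46, 334, 42); ages ~N(53.9, 13.2²) for everyone; MBC
  and glomerulation grade only for the IC/BPS groups (controls do not
  undergo hydrodistention), with NHIC grades distributed to match the
  reported mean ± SD of 1.8 ± 1.0.
* **Severity coupling** — optionally, NHIC subjects with MBC < 750 mL and
  grade ≥ 2 have their IP-10 drawn from a location-shifted distribution
  whose probability of exceeding the theoretical control CQ3 is raised by
  +1.5 log-odds. The coupling is off by default: it exists to make the
  severity-subgroup contrast reproducible on demand, and leaving it off
  keeps the IP-10 screening AUCs exactly at their configured targets.
* **Missingness** — independent per-cell, default 0 (the source analysis
  reports none).

Because HIC carries both shifts, the induced IC-vs-control AUC for a
biomarker is the mixture `w·AUC_ic + (1−w)·Φ(z_ic + z_hic)` with
`w = n_NHIC/(n_NHIC+n_HIC)`; `implied_auc` exposes this closed form and
the recovery tests target it.

What the generator does **not** emulate: assay noise floors and
left-censoring, creatinine normalization, batch effects, inter-biomarker
correlation (an option for a shared log-normal factor was considered and
deferred since no correlation structure is reported), or heteroscedastic
group variances. Passing tests therefore demonstrate the pipeline's
statistical machinery — not that real urine panels meet the log-normal,
equal-variance, independence assumptions.

## Problem sizes and numerical choices

Simulation-based tests use 200 replicates at (200, 800, 100) subjects per
group for screening recovery, 200 replicates of 600 subjects for stepwise
calibration, and 100–200 replicates of the default 422-subject cohort for
the subgroup power and null checks; these sizes put Monte-Carlo error well
inside the asserted bands while keeping the suite quick. Ties in the rank
AUC take half credit; quantile ties resolve by the interpolation
convention; stepwise ties (equal LRT) resolve by candidate order;
rule-ranking ties by sensitivity then name. Degenerate inputs error
loudly: empty classes, all-constant predictors, fewer than four control
values, strata that would empty an arm.

## Known limitations

* The published multivariable odds ratios cannot be reproduced without the
  raw cohort; only the single-predictor models whose 2×2 tables are fully
  determined by printed rates are recomputed (see
  `scripts/acceptance.py`).
* With the published effect sizes, biomarkers whose true AUC lies within
  about one Monte-Carlo standard error of the 0.6 gate (eotaxin, IL-8) are
  intrinsically unstable screening decisions at realistic sample sizes —
  exact recovery of the retained set is not achievable with high
  probability at n ≈ 1 100, and the acceptance suite records this
  honestly rather than enlarging the cohort.
* The realized historical 70/30 split of the source cohort (with its
  22/20 HIC imbalance) is not derivable from any stated rule and is
  treated as a fixture, not a contract: printed arm compositions are used
  as inputs where needed.
* Separated logistic fits report no interval; users wanting estimates
  under separation should apply an external penalized method.
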