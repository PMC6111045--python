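# Methods

## Scope and model direction

`methylaccel` implements the analysis chain used in family-based studies of
epigenetic age acceleration: array QC, clock-age prediction, blood-cell
deconvolution, intrinsic/extrinsic acceleration (IEAA/EEAA), pedigree-aware
mixed-model association, and clumping+thresholding polygenic scores. The
association model treats the **risk factor as the outcome** and the
acceleration measure as a fixed effect (alongside chronological age and
sex), with the pedigree as a random effect — the direction used when the
question is whether risk-factor profiles differ across acceleration, while
controlling relatedness. Effects on standardized outcomes are therefore read
as "SD change in risk factor per SD of acceleration".

## Quality control

Four rules, applied in a fixed order with boundary semantics pinned by
tests:

1. sample excluded iff the fraction of probes with detection *p* strictly
   above 0.05 is **at least** 1% (inclusive ≥);
2. probe excluded iff beadcount **strictly below** 3 in **strictly more
   than** 5 samples;
3. probe excluded iff the fraction of samples failing detection is **at
   least** 0.5% (inclusive ≥);
4. sample excluded iff methylation-predicted sex ≠ recorded sex.

Probe-level fractions are computed on the sample set surviving step 1;
whether the reverse order was ever intended is not decidable from the usual
description of the procedure, so the listed order is pinned and a two-pass
oracle test documents the consequence. A missing beadcount matrix skips rule
2 with a logged warning rather than failing, since beadcounts are often
unavailable outside raw exports. `run_qc` is idempotent on its own output.

Sex prediction is deterministic: female iff mean beta over annotated
chrX probes exceeds a threshold (default 0.35, the midpoint between the
synthetic female-like 0.5 and male-like 0.2 archetypes; overridable). This
replaces the visual intensity-plot inspection used in practice, trading a
small amount of realism for reproducibility.

## Clock ages and acceleration

A clock is a linear predictor on beta values with an optional log-linear age
calibration `F(a) = log(a+1) − log(a₀+1)` for `a ≤ a₀`,
`(a − a₀)/(a₀+1)` above; `F` is continuous, strictly increasing, and
inverted exactly. Published clock coefficient sets are deliberately not
bundled (they are licensed artifacts); clocks are pluggable CSV tables, and
the test suite uses toy clocks built by the synthetic module. Up to 20% of
clock probes may be missing, imputed with the cohort mean beta; beyond that
prediction refuses.

Cell proportions are estimated per sample by constrained least squares
against reference beta profiles of the seven blood cell types: minimise
‖Rπ − b‖² subject to π ≥ 0, Σπ = 1. The solver is non-negative least
squares with a sum-to-one row weighted 1000×, followed by exact
renormalisation; on exact mixtures this recovers proportions to machine
precision, and on noisy mixtures (beta noise sd 0.02) per-type RMSE stays
below 0.05. A rank-deficient reference on the shared probes is refused.

**IEAA** is the residual of the Horvath-style clock age on [1,
chronological age, six cell proportions] — granulocytes are dropped as the
reference category to break the simplex sum-to-one collinearity (an
arbitrary but test-pinned choice). Residuals are computed by minimum-norm
least squares, so the exactly collinear zero-noise case (cells affine in
age) is well-defined; coefficient-level inference elsewhere still requires
full-rank designs.

**EEAA** combines the Hannum-style clock age with the naive CD8⁺ T,
exhausted CD8⁺ T, and plasmablast proportions by the Klemera–Doubal
estimator. Each biomarker j is calibrated by OLS on age, `x_j = q_j + k_j a`
with residual sd `s_j`; the combined biological age is

    BA = [ Σ_j (x_j − q_j) k_j / s_j² ] / [ Σ_j k_j² / s_j² ]

the precision-weighted average, without a chronological-age anchor term (a
variant including chronological age as a pseudo-biomarker is available via
the `chronological` argument of `kdm_combine`). EEAA is the residual of BA
on chronological age. Calibration `(k, q, s)` is fitted on the analysis
cohort itself — whether production calculators use fixed external anchors is
not recoverable from their descriptions, so cohort-fitting is the documented
choice. An `s_j` floor of 1e-8 prevents an exact-fit biomarker from carrying
infinite weight; biomarkers with no usable age slope are rejected.

By construction IEAA is orthogonal (|r| < 1e-6) to every cell proportion
used in its regression, while EEAA retains a material correlation with the
age-drifting immune mixture — the defining contrast between the intrinsic
and extrinsic measures.

## Pedigree mixed models

The additive relationship matrix **A** is built by the tabular method
(`A_ii = 1 + A(s,d)/2`, `A_ij = (A(j,s_i) + A(j,d_i))/2`, unknown parents
contributing zero) and equals twice the recursive kinship coefficient to
1e-12 on random pedigrees.

*Gaussian outcomes*: REML for `y = Xβ + a + e`, `a ~ N(0, σ²ₐA)`. A single
eigendecomposition `A = UDUᵀ` (plus a 1e-8 ridge) diagonalises the rotated
covariance, so the restricted likelihood is profiled over the variance
ratio λ = σ²ₐ/σ²ₑ by bounded scalar optimisation on log λ (xatol 1e-8,
bounds e⁻¹² to e⁸, with an explicit boundary check at λ → 0). Fixed effects
come from GLS at the optimum; p-values are two-sided Wald. Supplying
`fixed_ratio` reproduces GLS with known components exactly (and OLS at
ratio 0). The eigendecomposition can be shared across repeated fits on the
same pedigree, which is what makes the 500-cohort calibration experiments
cheap.

*Binary outcomes*: Albert–Chib latent-liability probit Gibbs sampler with
the residual liability variance fixed at 1; the random effect is sampled in
the eigenbasis of A (diagonal conditional precision), the genetic variance
from an inverse-gamma(0.001, 0.001) conditional, and fixed effects from
their conjugate normal under an improper flat prior. Default chain: 2000
iterations, 500 burn-in. Reported: posterior mean, equal-tailed 95%
credible interval, and a two-sided tail probability floored at 1/draws.
Binary effects are on the latent (probit/liability) scale; no numeric
equivalence with odds-ratio-style coefficients is claimed. Flat-prior
probit is separation-prone when a trait has only a handful of cases —
cohorts of a few hundred individuals are the intended regime, and a
heuristic separation warning is attached to the fit. A Gaussian Gibbs
variant (`gaussian_sampler=True` in the suite, or `fit_gaussian_gibbs`)
exists for fidelity runs; the deterministic REML path is the default.

*Suite*: 12 risk factors × 2 exposures = 24 models. Continuous outcomes and
the exposure are z-scored (n−1 denominator); education is ordinal 0–10 and
z-scored by default with a per-unit option (`scale_education=False`);
binary outcomes pass through unscaled. Bonferroni is applied within each
exposure with family size m = 12 regardless of roster subsetting (override
available); the significance threshold α/m is reported to 4 decimals
(0.05/12 → .0042).

*Calibration design*: the global-null experiments (500 cohorts of ~300,
both in the test suite and the acceptance script) draw Gaussian outcomes
and use the REML path for all 12 tests. The REML fit is the shared
inferential target and runs three orders of magnitude faster than the
sampler; per-test rejection sits inside its exact binomial interval around
0.05 and Bonferroni family-wise error is consistent with ≤ 0.05.

## Polygenic scores

Greedy clumping by ascending p (ties broken by position then id): keep the
index SNP, remove unprocessed SNPs on the same chromosome within 250 kb
whose dosage r² strictly exceeds 0.25, repeat. LD comes from the sample
dosages themselves, not an external panel. Region exclusion removes SNPs in
`[start − flank, end + flank)` — closed left, open right, flank default
500 kb; "a 500-kb region" is ambiguous between total span and flank, and
the ±flank reading is the conservative, configurable one. No p-value
threshold is applied by default (all surviving SNPs score); `p_threshold`
exists. Scores are effect-weighted dosage sums, standardized across
samples; dosages counting the summary's other allele are flipped (2 − d)
and unresolvable allele mismatches are dropped with a count.

## Synthetic cohorts

The generator defines the study conditions for every test:

* **Pedigrees** — independent families; a founder couple, 2–3 children per
  couple, spouses marrying in as unrelated founders; parents precede
  offspring. Ages stratified by generation (75/47/19 ± 6 years, clipped to
  18–90) so the cohort spans adulthood with a mean near 48.
* **Latent accelerations** — two Gaussian latents per individual (intrinsic
  and extrinsic), sd 4.5 years, each with additive-genetic fraction 0.4
  transmitted as midparent + Mendelian sampling. The Horvath-style clock is
  steered by the intrinsic latent, the Hannum-style clock by the extrinsic.
* **Phenotypes** — generated conditional on the latents (risk factor as
  outcome), standardized effects per the default table whose magnitudes
  mirror reported blood-cohort associations (e.g. BMI 0.089 SD via the
  intrinsic measure); default per-trait heritability 0.3. Natural scales
  match a middle-aged population cohort (BMI 27 ± 5.4 kg/m², HDL 1.49 ±
  0.42 mmol/L, ...); the cholesterol ratio is **derived** as total/HDL, so
  injecting an independent effect on it is refused — effects reach the
  ratio through its components. Binary traits use a liability threshold at
  realistic prevalences (T2D 3.4%, high blood pressure 13.7%, family
  history 16.7%, ε4 carriage 27.7%). Deprivation is an integer rank
  (1 = most deprived); education is ordinal 0–10.
* **Methylation** — clock probes are steered so that, at noise sd 0 and
  exact construction, each clock returns chronological age plus its latent
  acceleration to machine precision; with the default beta noise (sd 0.01)
  the toy clocks' weight scales are set so clock noise is ~2–3 years,
  giving clock–age correlations around 0.94 — the precision regime of real
  blood clocks. Cell mixtures drift linearly with age (naive CD8⁺ T down,
  exhausted CD8⁺ T and plasmablasts up) around a Dirichlet (concentration
  150), deterministic at noise 0, so the extrinsic measure tracks
  composition and the intrinsic one cannot. A chrX block carries the sex
  signal (mean beta 0.5 female / 0.2 male). QC failures are injected with
  known identities: 3 samples at 2% detection failure, 2 detection-failing
  and 2 low-beadcount background probes, 1 flipped sex pattern (all
  configurable; none at noise 0).
* **Genotypes** — dosage blocks with copy-plus-redraw LD (within-block
  r² ≈ 0.72, between-block ≈ 0), ~1 Mb apart so blocks never share a
  clumping window; a matching summary table and an effect-driven liability
  for monotonicity checks.

Everything is reproducible: one root seed is expanded per stage via
`SeedSequence`, and identical configurations give byte-identical outputs.

What the generator does **not** emulate: probe-level heteroscedasticity and
beta-value boundary inflation, batch/chip effects, genuine genome-wide CpG
correlation structure, assortative mating, age-dependent participation, or
linkage between the toy genotypes and the methylome. Passing tests
demonstrate that the estimators recover what they are defined to recover
under a faithful generating model — not that real-cohort effect sizes would
be reproduced.

## Problem sizes and numerical choices

Test and acceptance experiments use cohorts of ~60–700 individuals (500
probes, two 120-probe clocks), 100-replicate recovery runs at n ≈ 600, and
500-cohort null calibrations at n ≈ 300 — sizes at which every property
being asserted is already stable. Monte-Carlo summaries of the probit
sampler are averaged over 4 chains to keep sampling error well inside the
±0.15 recovery band. Tolerances: exact linear-algebra identities at
1e-10–1e-12, residual orthogonality at 1e-6–1e-8, REML criterion vs a dense
oracle at 1e-6. The relationship-matrix ridge is 1e-8; the KDM `s` floor
1e-8; z-scoring uses the n−1 denominator throughout.

## Known limitations

* The probit sampler's flat fixed-effect prior misbehaves under
  quasi-separation (very rare binary outcomes in small cohorts); effects
  are reported on the liability scale only.
* Mean-imputation of missing clock probes uses the cohort-wide mean beta,
  not clock-specific training means (which are not distributable).
* LD clumping from sample dosages is noisy at small n compared to a
  reference panel.
* IDAT parsing, dye-bias/background normalisation, and the online
  calculators' internal renormalisation are out of scope: inputs are
  already-normalised beta matrices.
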