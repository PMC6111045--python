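# methylaccel

Epigenetic age acceleration analysis on pedigreed cohorts: from raw
methylation beta matrices to risk-factor association estimates.

Large family studies ask whether known dementia and cardiometabolic risk
factors — BMI, smoking, cholesterol, blood pressure, deprivation, education,
diabetes, family history, *APOE* ε4 status, polygenic risk — track with how
much "older" a person's blood methylome looks than their calendar age.
`methylaccel` implements that full analysis chain as a tested, reusable
library and CLI, together with a synthetic family-cohort generator so every
stage can be validated against known ground truth (the cohorts such studies
use are access-controlled).

## What it computes

Given a beta matrix **B** (samples × CpG probes, values in [0, 1]) with
companion detection-p and beadcount matrices:

1. **QC** — exclude samples with ≥1% of probes at detection *p* > 0.05;
   probes with beadcount < 3 in more than 5 samples; probes failing
   detection in ≥0.5% of the surviving samples; samples whose
   methylation-predicted sex (mean chrX beta) contradicts the recorded sex.
2. **Clock ages** — for a clock with weights *w* and intercept *c*,
   `age = F⁻¹(c + Σⱼ wⱼ βⱼ)`, where *F* is the identity or the log-linear
   calibration `F(a) = log(a+1) − log(a₀+1)` below adult age *a₀*, linear
   above. Clock coefficient tables are user-supplied CSVs.
3. **Cell composition** — constrained least squares (non-negative,
   sum-to-one) against reference profiles of the seven blood cell types:
   naive CD8⁺ T, exhausted CD8⁺ T, plasmablast, CD4⁺ T, NK, monocyte,
   granulocyte.
4. **IEAA** — residual of the Horvath-style clock age regressed on
   chronological age and the cell proportions (intrinsic: composition-blind).
5. **EEAA** — Klemera–Doubal weighted average of the Hannum-style clock age
   and the three age-varying immune measures,
   `BA = [Σⱼ (xⱼ−qⱼ)kⱼ/sⱼ²] / [Σⱼ kⱼ²/sⱼ²]`, residualised on chronological
   age (extrinsic: tracks immunosenescence).
6. **Association** — per risk factor, the animal model
   `y = Xβ + a + e`, `a ~ N(0, σ²ₐA)` with **A** the pedigree additive
   relationship matrix; the risk factor is the outcome and chronological
   age, sex, and one acceleration measure are fixed effects. Gaussian
   outcomes are fitted by REML, binary outcomes by a latent-liability
   probit Gibbs sampler. Numeric variables are z-scored; Bonferroni
   correction is applied within each acceleration measure (m = 12,
   threshold 0.05/12 = .0042).
7. **Polygenic scores** (optional stage) — greedy LD clumping of GWAS
   summary statistics (r² > 0.25 within 250 kb), ±500 kb region exclusion
   (e.g. around *APOE*), effect-weighted dosage sums.

## Worked example

```bash
cat > demo.yaml <<'YAML'
seed: 42
output_dir: demo_run
simulate:
  n_families: 65
  generations: 2
  effect_table: {bmi: [0.089, 0.3]}   # SD effect via intrinsic, extrinsic accel
chain: {iterations: 1500, burn_in: 500}
YAML
methylaccel run --config demo.yaml
```

This simulates ~290 individuals in two-generation families, injects a BMI
effect of 0.089 SD per SD of intrinsic acceleration and 0.3 SD per SD of
extrinsic acceleration, and runs QC → clocks → acceleration → association.
The printed report (abridged):

```
QC:
  samples: 290 -> 286 (4 excluded)
  probes:  500 -> 496 (4 excluded)

Clock ages:
  Horvath-style vs chronological r = 0.938
  Hannum-style  vs chronological r = 0.942

Bonferroni threshold: alpha/m = 0.05/12 = .0042

Associations (risk factor x exposure):
  risk_factor       exposure      beta   ci_low  ci_high          p      p_adj  sig
  ...
  bmi               eeaa         0.281    0.168    0.394   1.14e-06   1.36e-05  *
  pack_years        eeaa         0.004   -0.114    0.121      0.948          1
  ...
```

The three injected QC sample failures and one swapped sex label are removed
(4 samples), both toy clocks track chronological age at r ≈ 0.94, and the
injected BMI→EEAA effect of 0.3 SD is recovered at 0.281 SD and is the only
row significant after Bonferroni — null traits stay null. All 24 rows
(12 risk factors × 2 acceleration measures) are written to
`demo_run/associations.tsv`, with every intermediate (filtered matrices,
acceleration table, manifest with checksums) alongside.

The same stages are exposed individually (`methylaccel qc|age|assoc|prs`)
and as library functions (`run_qc`, `predict_age`,
`estimate_cell_proportions`, `compute_acceleration_table`,
`build_relationship_matrix`, `fit_gaussian_lmm`, `fit_binary_mixed`,
`run_association_suite`, `ld_clump`, `compute_prs`, ...).

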