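"""Synthetic family cohorts with known ground truth.

Every downstream stage of the pipeline (QC, clock ages, acceleration,
pedigree mixed models, polygenic scores) is exercised against cohorts built
here, where the generating parameters are known exactly:

* pedigrees of nuclear families over one or more generations;
* two latent age-acceleration variables per individual (an intrinsic one
  driving the Horvath-style clock and an extrinsic one driving the
  Hannum-style clock), Gaussian with sd ~4.5 years and a heritable
  component transmitted along the pedigree;
* risk-factor phenotypes generated conditional on the latent accelerations
  (risk factor as outcome, matching the analysis model direction), with a
  liability-threshold model for binary traits;
* clock-structured methylation: at zero noise the clock probes reproduce
  chronological age plus the latent acceleration exactly; blood cell
  mixtures drift linearly with age so the extrinsic measure (but not the
  intrinsic one) tracks composition; companion detection-p and beadcount
  matrices carry injected QC failures; a chrX probe block carries the sex
  signal;
* toy genotype dosages in LD blocks with a matching summary-statistics table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .age import age_transform
from .containers import (
    CELL_TYPES,
    BetaMatrix,
    CellReference,
    ClockModel,
    MethylAccelError,
    Pedigree,
)

#: Risk-factor roster: trait -> model family.
RISK_FACTORS: Dict[str, str] = {
    "simd_rank": "gaussian",
    "education": "gaussian",
    "bmi": "gaussian",
    "pack_years": "gaussian",
    "hdl": "gaussian",
    "total_cholesterol": "gaussian",
    "chol_ratio": "gaussian",
    "prs": "gaussian",
    "t2d": "binary",
    "hbp": "binary",
    "family_history": "binary",
    "apoe_e4": "binary",
}

#: Default standardized effects (per SD of latent acceleration) on each risk
#: factor, split by the acceleration measure they act through. Magnitudes
#: mirror the association scale seen in large blood-methylation cohorts.
DEFAULT_EFFECT_TABLE: Dict[str, Tuple[float, float]] = {
    "simd_rank": (-0.005, -0.056),
    "education": (0.040, -0.041),
    "bmi": (0.089, 0.061),
    "pack_years": (0.031, 0.059),
    "hdl": (-0.028, -0.022),
    "total_cholesterol": (0.036, -0.027),
    "prs": (-0.002, -0.007),
    "t2d": (0.178, 0.142),
    "hbp": (0.105, 0.177),
    "family_history": (0.060, -0.007),
    "apoe_e4": (-0.107, -0.103),
}

#: Natural-scale locations for the continuous traits: (mean, sd).
TRAIT_SCALES: Dict[str, Tuple[float, float]] = {
    "bmi": (27.0, 5.4),
    "pack_years": (9.1, 17.3),
    "hdl": (1.49, 0.42),
    "total_cholesterol": (5.13, 1.09),
}

#: Case prevalences for the liability-threshold binary traits.
PREVALENCES: Dict[str, float] = {
    "t2d": 0.034,
    "hbp": 0.137,
    "family_history": 0.167,
    "apoe_e4": 0.277,
}

#: Mean cell proportion at age 50 and per-year drift slope. The granulocyte
#: fraction absorbs the remainder so the simplex always sums to one.
CELL_AGE_MODEL: Dict[str, Tuple[float, float]] = {
    "naive CD8+ T": (0.09, -0.0010),
    "exhausted CD8+ T": (0.04, +0.0008),
    "plasmablast": (0.03, +0.0004),
    "CD4+ T": (0.16, -0.0004),
    "NK": (0.07, +0.0004),
    "monocyte": (0.08, 0.0),
}

#: Dirichlet concentration controlling sampling noise around the age-drifting
#: cell means (ignored at noise_sd=0, where the means are used exactly).
CELL_DIRICHLET_CONCENTRATION = 150.0

SEX_CHROMOSOME = "chrX"
FEMALE_CHRX_BETA = 0.5
MALE_CHRX_BETA = 0.2


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_families: int = 60
    generations: int = 2
    age_range: Tuple[float, float] = (18.0, 90.0)
    n_probes: int = 500
    n_clock_probes: int = 120
    cell_types: Sequence[str] = CELL_TYPES
    noise_sd: float = 0.01
    effect_table: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_TABLE))
    heritability: Dict[str, float] = field(default_factory=dict)  # default 0.3 per trait
    accel_sd: float = 4.5
    accel_heritability: float = 0.4
    n_fail_samples: int = 3
    n_fail_probes_detection: int = 2
    n_fail_probes_beadcount: int = 2
    n_sex_mismatch: int = 1
    n_sex_probes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise MethylAccelError("noise_sd must be >= 0")
        for t, h in self.heritability.items():
            if not (0 <= h <= 1):
                raise MethylAccelError(f"heritability for {t!r} must lie in [0,1], got {h}")
        if not (0 <= self.accel_heritability <= 1):
            raise MethylAccelError("accel_heritability must lie in [0,1]")
        for key, (bi, be) in self.effect_table.items():
            if key == "chol_ratio":
                raise MethylAccelError(
                    "chol_ratio is derived as total_cholesterol/hdl; inject effects "
                    "through those components instead")
            if key not in RISK_FACTORS:
                raise MethylAccelError(f"unknown risk factor {key!r} in effect_table")
            if not (np.isfinite(bi) and np.isfinite(be)):
                raise MethylAccelError(f"non-finite effect for {key!r}")
        if tuple(self.cell_types) != CELL_TYPES:
            raise MethylAccelError(f"cell_types must be exactly {CELL_TYPES}")

    def trait_h2(self, trait: str) -> float:
        return self.heritability.get(trait, 0.3)


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

def simulate_pedigrees(n_families: int, generations: int, seed: int,
                       children_per_couple: Tuple[int, int] = (2, 3)) -> Pedigree:
    """Simulate ``n_families`` independent families over ``generations``
    generations (generation 1 = the founder couple). Spouses marrying into
    later generations are unrelated founders."""
    if n_families < 1 or generations < 1:
        raise MethylAccelError("n_families and generations must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = children_per_couple
    rows: List[tuple] = []
    for f in range(n_families):
        sire, dam = f"fam{f}_g1_m", f"fam{f}_g1_f"
        rows.append((sire, None, None, "male"))
        rows.append((dam, None, None, "female"))
        couples = [(sire, dam)]
        for g in range(2, generations + 1):
            next_couples = []
            for ci, (s, d) in enumerate(couples):
                n_children = int(rng.integers(lo, hi + 1))
                for c in range(n_children):
                    sex = "male" if rng.random() < 0.5 else "female"
                    cid = f"fam{f}_g{g}_c{ci}.{c}"
                    rows.append((cid, s, d, sex))
                    if g < generations:
                        spouse_sex = "female" if sex == "male" else "male"
                        sid = f"fam{f}_g{g}_s{ci}.{c}"
                        rows.append((sid, None, None, spouse_sex))
                        pair = (cid, sid) if sex == "male" else (sid, cid)
                        next_couples.append(pair)
            couples = next_couples
    table = pd.DataFrame(rows, columns=["individual_id", "sire_id", "dam_id", "sex"])
    return Pedigree(table)


def _generation_depth(pedigree: Pedigree) -> pd.Series:
    """0 for founders, 1 + max(parent depth) otherwise."""
    depth: Dict[str, int] = {}
    t = pedigree.table
    parents = {r.individual_id: (r.sire_id, r.dam_id) for r in t.itertuples()}
    for ind in t["individual_id"]:
        s, d = parents[ind]
        ds = [depth[p] for p in (s, d) if not pd.isna(p) and p is not None]
        depth[ind] = 1 + max(ds) if ds else 0
    return pd.Series(depth, name="generation")


def _sample_additive(pedigree: Pedigree, var: float, rng: np.random.Generator) -> pd.Series:
    """Additive genetic values: founders ~ N(0, var); offspring = midparent +
    Mendelian-sampling N(0, var/2)."""
    g: Dict[str, float] = {}
    for r in pedigree.table.itertuples():
        s, d = r.sire_id, r.dam_id
        if (pd.isna(s) or s is None) and (pd.isna(d) or d is None):
            g[r.individual_id] = rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0
        else:
            mid = 0.5 * (g.get(s, 0.0) + g.get(d, 0.0))
            g[r.individual_id] = mid + (rng.normal(0.0, np.sqrt(var / 2)) if var > 0 else 0.0)
    return pd.Series(g)


def _heritable_standard_trait(pedigree: Pedigree, h2: float,
                              rng: np.random.Generator) -> pd.Series:
    """Unit-variance trait with additive-genetic fraction ``h2`` shared along
    the pedigree."""
    genetic = _sample_additive(pedigree, h2, rng)
    env = pd.Series(rng.normal(0.0, np.sqrt(1.0 - h2), len(pedigree)),
                    index=pedigree.ids)
    return genetic.loc[pedigree.ids] + env


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(pedigree: Pedigree, config: SimulationConfig,
                        seed: Optional[int] = None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the risk-factor phenotype table plus per-individual truth.

    Returns ``(phenotypes, truth)``; ``truth`` holds the latent intrinsic and
    extrinsic accelerations (years) and the generation index.
    """
    rng = np.random.default_rng(config.seed + 101 if seed is None else seed)
    ids = pedigree.ids
    n = len(ids)
    gen = _generation_depth(pedigree).loc[ids]

    # ages stratified by generation so parents are older than offspring
    lo, hi = config.age_range
    base = 75.0 - 28.0 * gen.to_numpy(dtype=float)
    age = np.clip(base + rng.normal(0.0, 6.0, n), lo, hi)
    sex = pedigree.table.set_index("individual_id")["sex"].loc[ids]

    # latent accelerations (years): heritable Gaussian, sd config.accel_sd
    acc_i = _heritable_standard_trait(pedigree, config.accel_heritability, rng) * config.accel_sd
    acc_e = _heritable_standard_trait(pedigree, config.accel_heritability, rng) * config.accel_sd
    z_i = (acc_i / config.accel_sd).to_numpy()
    z_e = (acc_e / config.accel_sd).to_numpy()

    def standardized_outcome(trait: str) -> np.ndarray:
        bi, be = config.effect_table.get(trait, (0.0, 0.0))
        resid_var = 1.0 - bi**2 - be**2
        if resid_var <= 0:
            raise MethylAccelError(f"effects for {trait!r} leave no residual variance")
        h2 = config.trait_h2(trait)
        shared = _heritable_standard_trait(pedigree, h2, rng).to_numpy()
        return bi * z_i + be * z_e + np.sqrt(resid_var) * shared

    pheno = pd.DataFrame(index=ids)
    pheno["chronological_age"] = age
    pheno["sex"] = sex

    z_cols = {t: standardized_outcome(t) for t in RISK_FACTORS if t != "chol_ratio"}

    for trait, (mean, sd) in TRAIT_SCALES.items():
        vals = mean + sd * z_cols[trait]
        if trait in ("pack_years",):
            vals = np.maximum(vals, 0.0)
        if trait in ("hdl", "total_cholesterol", "bmi"):
            vals = np.maximum(vals, 0.2)
        pheno[trait] = vals
    pheno["chol_ratio"] = pheno["total_cholesterol"] / pheno["hdl"]

    # area-deprivation rank: 1 = most deprived (lowest latent SES score)
    pheno["simd_rank"] = pd.Series(z_cols["simd_rank"], index=ids).rank(method="first").astype(int)
    pheno["education"] = np.clip(np.round(4.5 + 1.8 * z_cols["education"]), 0, 10).astype(int)
    pheno["prs"] = (z_cols["prs"] - z_cols["prs"].mean()) / z_cols["prs"].std(ddof=1)

    for trait, prev in PREVALENCES.items():
        thr = norm.ppf(1.0 - prev)
        pheno[trait] = (z_cols[trait] > thr).astype(int)

    truth = pd.DataFrame({
        "latent_ieaa": acc_i.loc[ids],
        "latent_eeaa": acc_e.loc[ids],
        "generation": gen,
    })
    return pheno, truth


# ---------------------------------------------------------------------------
# Toy clocks and cell reference
# ---------------------------------------------------------------------------

def make_toy_clock(name: str, n_probes: int, rng: np.random.Generator,
                   transform: str = "identity", adult_age: Optional[float] = None,
                   probe_prefix: str = "clk",
                   weight_range: Tuple[float, float] = (1.5, 2.5)) -> ClockModel:
    """A toy linear clock whose probes the methylation simulator can steer.

    Weights are uniform in ``weight_range``; the intercept centres the
    construction so steered betas stay inside [0, 1] over the whole age
    range. The weight scale sets how strongly per-probe beta noise propagates
    into age noise (sd ~ noise_sd * sqrt(sum w^2) on the transformed scale).
    """
    weights = pd.Series(rng.uniform(*weight_range, n_probes),
                        index=[f"{probe_prefix}_{i:05d}" for i in range(n_probes)])
    anchor = 55.0
    f0 = anchor if transform == "identity" else float(age_transform(anchor, adult_age))
    intercept = f0 - 0.5 * float(weights.sum())
    return ClockModel(name=name, intercept=intercept, weights=weights,
                      transform=transform, adult_age=adult_age)


def make_cell_reference(rng: np.random.Generator, probes_per_type: int = 9) -> CellReference:
    """Reference profiles: each cell type hypomethylated on its own probe
    block, plus shared random probes — full rank by construction."""
    k = len(CELL_TYPES)
    n = probes_per_type * k
    ref = rng.uniform(0.55, 0.9, size=(n, k))
    for j in range(k):
        block = slice(j * probes_per_type, (j + 1) * probes_per_type)
        ref[block, j] = rng.uniform(0.05, 0.2, probes_per_type)
    probes = [f"cell_{i:05d}" for i in range(n)]
    return CellReference(pd.DataFrame(ref, index=probes, columns=list(CELL_TYPES)))


def cell_mean_proportions(age) -> pd.DataFrame:
    """Deterministic age-drifting mean cell proportions (rows: samples)."""
    age = np.asarray(age, dtype=float)
    cols = {}
    for ct, (base, slope) in CELL_AGE_MODEL.items():
        cols[ct] = base + slope * (age - 50.0)
    out = pd.DataFrame(cols)
    out["granulocyte"] = 1.0 - out.sum(axis=1)
    out = out[list(CELL_TYPES)]
    if (out.to_numpy() <= 0).any():
        raise MethylAccelError("cell mean proportions left the simplex; narrow the age range")
    return out


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

@dataclass
class MethylationSim:
    """Output bundle of :func:`simulate_methylation`."""

    data: BetaMatrix
    cell_truth: pd.DataFrame                  # true per-sample proportions
    annotation: Dict[str, str]                # probe -> chromosome
    failed_samples: List[str]                 # injected detection failures
    failed_probes_detection: List[str]
    failed_probes_beadcount: List[str]
    sex_mismatch_samples: List[str]           # methylation pattern flipped


def simulate_methylation(phenotypes: pd.DataFrame,
                         clocks: Sequence[ClockModel],
                         cell_reference: CellReference,
                         config: SimulationConfig,
                         accelerations: Optional[pd.DataFrame] = None,
                         seed: Optional[int] = None) -> MethylationSim:
    """Build beta / detection-p / beadcount matrices steered by the clocks.

    ``accelerations`` has one column per clock name (years added to
    chronological age before the clock transform); missing columns mean zero
    acceleration for that clock. At ``noise_sd == 0`` the construction is
    exact: each clock's prediction equals chronological age plus its
    acceleration, cell mixtures equal their age-linear means, and no QC
    failures are injected noise-side.
    """
    rng = np.random.default_rng(config.seed + 202 if seed is None else seed)
    ids = phenotypes.index
    n = len(ids)
    age = phenotypes["chronological_age"].to_numpy(dtype=float)

    probe_blocks: List[pd.DataFrame] = []
    annotation: Dict[str, str] = {}

    # --- clock probes: beta_ij = 0.5 + (F_i - F0) / (n_probes * w_j)
    for clock in clocks:
        acc = np.zeros(n)
        if accelerations is not None and clock.name in accelerations.columns:
            acc = accelerations[clock.name].loc[ids].to_numpy(dtype=float)
        target = age + acc
        if clock.transform == "identity":
            f = target
        else:
            f = age_transform(target, clock.adult_age)
        w = clock.weights.to_numpy()
        npb = len(w)
        # clock.intercept = F0 - 0.5*sum(w), so sum_j w_j beta_ij + intercept = F_i
        f0 = clock.intercept + 0.5 * w.sum()
        dev = (f - f0)[:, None] / (npb * w[None, :])
        if np.abs(dev).max() >= 0.49:
            raise MethylAccelError(
                f"clock {clock.name!r}: steered betas would leave [0,1]; "
                "increase n_clock_probes or narrow the age range")
        block = 0.5 + dev
        if config.noise_sd > 0:
            block = block + rng.normal(0.0, config.noise_sd, block.shape)
        probe_blocks.append(pd.DataFrame(block, index=ids, columns=clock.weights.index))
        annotation.update({p: "chr1" for p in clock.weights.index})

    # --- cell-mixture probes
    means = cell_mean_proportions(age)
    means.index = ids
    if config.noise_sd == 0:
        cell_truth = means
    else:
        conc = CELL_DIRICHLET_CONCENTRATION
        draws = np.vstack([rng.dirichlet(conc * row) for row in means.to_numpy()])
        cell_truth = pd.DataFrame(draws, index=ids, columns=list(CELL_TYPES))
    mix = cell_truth.to_numpy() @ cell_reference.reference_betas.to_numpy().T
    if config.noise_sd > 0:
        mix = mix + rng.normal(0.0, config.noise_sd, mix.shape)
    probe_blocks.append(pd.DataFrame(mix, index=ids, columns=cell_reference.probe_ids))
    annotation.update({p: "chr2" for p in cell_reference.probe_ids})

    # --- sex probes on the designated sex chromosome
    sex = phenotypes["sex"].loc[ids]
    mismatch_pool = [s for s in ids]
    rng.shuffle(mismatch_pool)
    sex_mismatch = sorted(mismatch_pool[:config.n_sex_mismatch]) if config.noise_sd > 0 else []
    effective_sex = sex.copy()
    for s in sex_mismatch:
        effective_sex[s] = "male" if sex[s] == "female" else "female"
    sex_mean = np.where(effective_sex == "female", FEMALE_CHRX_BETA, MALE_CHRX_BETA)
    sex_block = np.repeat(sex_mean[:, None], config.n_sex_probes, axis=1)
    if config.noise_sd > 0:
        sex_block = sex_block + rng.normal(0.0, config.noise_sd, sex_block.shape)
    sex_probes = [f"sex_{i:05d}" for i in range(config.n_sex_probes)]
    probe_blocks.append(pd.DataFrame(sex_block, index=ids, columns=sex_probes))
    annotation.update({p: SEX_CHROMOSOME for p in sex_probes})

    # --- background probes to fill the panel
    n_structured = sum(b.shape[1] for b in probe_blocks)
    n_background = max(config.n_probes - n_structured, 20)
    bg_means = rng.uniform(0.1, 0.9, n_background)
    bg = np.repeat(bg_means[None, :], n, axis=0)
    if config.noise_sd > 0:
        bg = bg + rng.normal(0.0, config.noise_sd, bg.shape)
    bg_probes = [f"bg_{i:05d}" for i in range(n_background)]
    probe_blocks.append(pd.DataFrame(bg, index=ids, columns=bg_probes))
    annotation.update({p: "chr3" for p in bg_probes})

    beta = pd.concat(probe_blocks, axis=1).clip(0.0, 1.0)
    n_probes_total = beta.shape[1]

    # --- companion matrices with injected QC failures (background probes only)
    detp = pd.DataFrame(rng.uniform(0.0, 0.01, beta.shape),
                        index=ids, columns=beta.columns)
    bead = pd.DataFrame(rng.poisson(12.0, beta.shape) + 4,
                        index=ids, columns=beta.columns)

    failed_samples: List[str] = []
    failed_probes_det: List[str] = []
    failed_probes_bead: List[str] = []
    if config.noise_sd > 0:
        sample_pool = [s for s in ids if s not in sex_mismatch]
        rng.shuffle(sample_pool)
        failed_samples = sorted(sample_pool[:config.n_fail_samples])
        n_fail_probes = max(int(np.ceil(0.02 * n_probes_total)), int(np.ceil(0.01 * n_probes_total)) + 1)
        for s in failed_samples:
            bad = rng.choice(n_probes_total, size=n_fail_probes, replace=False)
            detp.iloc[detp.index.get_loc(s), bad] = 0.5

        pool = list(bg_probes)
        rng.shuffle(pool)
        failed_probes_det = sorted(pool[:config.n_fail_probes_detection])
        failed_probes_bead = sorted(
            pool[config.n_fail_probes_detection:
                 config.n_fail_probes_detection + config.n_fail_probes_beadcount])
        # detection-failing probes: fail in >= 0.5% of the surviving samples
        survivors = [s for s in ids if s not in failed_samples]
        n_fail_samples_per_probe = int(np.ceil(0.005 * len(survivors))) + 1
        for p in failed_probes_det:
            chosen = rng.choice(len(survivors), size=n_fail_samples_per_probe, replace=False)
            col = detp.columns.get_loc(p)
            for c in chosen:
                detp.iloc[detp.index.get_loc(survivors[c]), col] = 0.5
        # beadcount-failing probes: beadcount 2 in 6 samples
        for p in failed_probes_bead:
            chosen = rng.choice(len(survivors), size=6, replace=False)
            col = bead.columns.get_loc(p)
            for c in chosen:
                bead.iloc[bead.index.get_loc(survivors[c]), col] = 2

    data = BetaMatrix(beta=beta, detection_p=detp, beadcount=bead)
    return MethylationSim(
        data=data,
        cell_truth=cell_truth,
        annotation=annotation,
        failed_samples=failed_samples,
        failed_probes_detection=failed_probes_det,
        failed_probes_beadcount=failed_probes_bead,
        sex_mismatch_samples=sex_mismatch,
    )


# ---------------------------------------------------------------------------
# Genotypes and GWAS summary statistics
# ---------------------------------------------------------------------------

@dataclass
class GenotypeSim:
    """Output bundle of :func:`simulate_genotypes`."""

    dosages: pd.DataFrame    # samples x SNPs, values in {0,1,2}
    summary: pd.DataFrame    # snp, chr, pos, a1, a2, beta, p
    liability: pd.Series     # latent trait driven by the summary effects


def simulate_genotypes(phenotypes: pd.DataFrame, n_snps: int,
                       ld_block_size: int, seed: int,
                       flip_prob: float = 0.15) -> GenotypeSim:
    """Toy genotypes in LD blocks plus a matching GWAS summary table.

    Within each block the first SNP is drawn fresh per individual and the
    rest are copies with probability ``flip_prob`` of an independent redraw,
    giving within-block dosage r^2 around (1 - flip_prob)^2 and zero
    correlation between blocks. Blocks are separated by ~1 Mb so they never
    share a clumping window.
    """
    if n_snps < 1:
        raise MethylAccelError("n_snps must be >= 1")
    if ld_block_size < 1:
        raise MethylAccelError("ld_block_size must be >= 1")
    rng = np.random.default_rng(seed)
    ids = phenotypes.index
    n = len(ids)

    dosage = np.empty((n, n_snps), dtype=int)
    chrom = np.empty(n_snps, dtype=object)
    pos = np.empty(n_snps, dtype=int)
    block_starts = range(0, n_snps, ld_block_size)
    for bi, start in enumerate(block_starts):
        end = min(start + ld_block_size, n_snps)
        maf = rng.uniform(0.15, 0.85)
        base = rng.binomial(2, maf, n)
        c = str(bi % 22 + 1)
        bstart = 1_000_000 * (bi // 22 + 1) + 10_000_000
        for j_off, j in enumerate(range(start, end)):
            if j == start:
                dosage[:, j] = base
            else:
                redraw = rng.random(n) < flip_prob
                dosage[:, j] = np.where(redraw, rng.binomial(2, maf, n), base)
            chrom[j] = c
            pos[j] = bstart + j_off * 10_000

    effects = rng.normal(0.0, 0.1, n_snps)
    z = effects / 0.03 + rng.normal(0.0, 1.0, n_snps)
    pvals = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
    snp_ids = [f"rs{j:06d}" for j in range(n_snps)]
    summary = pd.DataFrame({
        "snp": snp_ids,
        "chr": chrom,
        "pos": pos,
        "a1": "A",
        "a2": "G",
        "beta": effects,
        "p": pvals,
    })

    raw = dosage @ effects
    liability = raw + rng.normal(0.0, np.std(raw) if np.std(raw) > 0 else 1.0, n)
    return GenotypeSim(
        dosages=pd.DataFrame(dosage, index=ids, columns=snp_ids),
        summary=summary,
        liability=pd.Series(liability, index=ids, name="liability"),
    )


# ---------------------------------------------------------------------------
# Whole-cohort convenience bundle
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    """Everything one synthetic cohort provides to the pipeline."""

    config: SimulationConfig
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    horvath_clock: ClockModel
    hannum_clock: ClockModel
    cell_reference: CellReference
    methylation: MethylationSim
    recorded_sex: Dict[str, str]


def simulate_cohort(config: SimulationConfig) -> CohortSim:
    """Generate pedigree, phenotypes, clocks, and methylation in one pass.

    The Horvath-style clock (log-linear calibration) is steered by the latent
    intrinsic acceleration; the Hannum-style identity clock by the latent
    extrinsic acceleration.
    """
    root = np.random.SeedSequence(config.seed)
    s_ped, s_pheno, s_clock, s_meth = [int(s.generate_state(1)[0] % (2**31))
                                       for s in root.spawn(4)]
    pedigree = simulate_pedigrees(config.n_families, config.generations, s_ped)
    phenotypes, truth = simulate_phenotypes(pedigree, config, seed=s_pheno)

    clock_rng = np.random.default_rng(s_clock)
    # weight scales chosen so default beta noise (sd 0.01) yields ~2-3 years
    # of clock noise, the precision regime of real blood clocks
    horvath = make_toy_clock("horvath_style", config.n_clock_probes, clock_rng,
                             transform="log_linear", adult_age=20.0,
                             probe_prefix="clkH", weight_range=(0.7, 1.1))
    hannum = make_toy_clock("hannum_style", config.n_clock_probes, clock_rng,
                            transform="identity", probe_prefix="clkN",
                            weight_range=(24.0, 30.0))
    cell_ref = make_cell_reference(clock_rng)

    accel = pd.DataFrame({
        "horvath_style": truth["latent_ieaa"],
        "hannum_style": truth["latent_eeaa"],
    })
    meth = simulate_methylation(phenotypes, [horvath, hannum], cell_ref, config,
                                accelerations=accel, seed=s_meth)
    recorded_sex = dict(phenotypes["sex"])
    return CohortSim(
        config=config, pedigree=pedigree, phenotypes=phenotypes, truth=truth,
        horvath_clock=horvath, hannum_clock=hannum, cell_reference=cell_ref,
        methylation=meth, recorded_sex=recorded_sex,
    )
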