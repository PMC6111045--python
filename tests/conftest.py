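import numpy as np
import pandas as pd
import pytest

import methylaccel as ma
from methylaccel.synthetic import make_cell_reference, make_toy_clock


@pytest.fixture(scope="session")
def small_cohort():
    """Default-conditions cohort (~90 individuals) reused across read-only tests."""
    return ma.simulate_cohort(ma.SimulationConfig(n_families=20, generations=2, seed=11))


@pytest.fixture(scope="session")
def noiseless_parts():
    """Zero-noise cohort pieces where the clock construction is exact."""
    cfg = ma.SimulationConfig(n_families=15, generations=2, seed=7, noise_sd=0.0)
    ped = ma.simulate_pedigrees(cfg.n_families, cfg.generations, 1)
    pheno, truth = ma.simulate_phenotypes(ped, cfg)
    rng = np.random.default_rng(5)
    horvath = make_toy_clock("horvath_style", 120, rng, transform="log_linear",
                             adult_age=20.0, probe_prefix="clkH", weight_range=(0.7, 1.1))
    hannum = make_toy_clock("hannum_style", 120, rng, probe_prefix="clkN",
                            weight_range=(24.0, 30.0))
    ref = make_cell_reference(rng)
    return cfg, ped, pheno, truth, horvath, hannum, ref


@pytest.fixture(scope="session")
def family_matrix():
    """Pedigree with parent-offspring, full sibs, and an inbred individual."""
    t = pd.DataFrame({
        "individual_id": ["s", "d", "c1", "c2", "g"],
        "sire_id": [None, None, "s", "s", "c1"],
        "dam_id": [None, None, "d", "d", "c2"],
        "sex": ["male", "female", "male", "female", "male"],
    })
    return ma.build_relationship_matrix(ma.Pedigree(t))


def clump_oracle(summary, dosages, r2_threshold, window):
    """Exhaustive greedy clumping oracle evaluated pair by pair with fresh
    correlations (independent of the implementation's vectorised path)."""
    df = summary.sort_values(["p", "pos", "snp"], kind="mergesort")
    retained, removed = [], set()
    for _, row in df.iterrows():
        if row["snp"] in removed:
            continue
        retained.append(row["snp"])
        for _, other in df.iterrows():
            if other["snp"] in removed or other["snp"] in retained:
                continue
            if other["chr"] != row["chr"] or abs(other["pos"] - row["pos"]) > window:
                continue
            r = np.corrcoef(dosages[row["snp"]], dosages[other["snp"]])[0, 1]
            if r * r > r2_threshold:
                removed.add(other["snp"])
    return retained


def kinship_oracle(pedigree: ma.Pedigree) -> np.ndarray:
    """Brute-force recursive kinship coefficients; A = 2 * kinship."""
    t = pedigree.table
    parents = {r.individual_id: (r.sire_id, r.dam_id) for r in t.itertuples()}
    order = {ind: k for k, ind in enumerate(t["individual_id"])}
    cache = {}

    def phi(i, j):
        if i is None or j is None or pd.isna(i) or pd.isna(j):
            return 0.0
        if order[i] < order[j]:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        si, di = parents[i]
        if i == j:
            val = 0.5 * (1.0 + phi(si, di))
        else:
            val = 0.5 * (phi(si, j) + phi(di, j))
        cache[key] = val
        return val

    ids = list(t["individual_id"])
    n = len(ids)
    K = np.empty((n, n))
    for a in range(n):
        for b in range(a + 1):
            K[a, b] = K[b, a] = phi(ids[a], ids[b])
    return 2.0 * K
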