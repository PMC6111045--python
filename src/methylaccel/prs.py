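"""Clumping + thresholding polygenic scores from GWAS summary statistics.

The score pipeline: (1) optionally exclude SNPs around a named region (e.g. a
+/-500 kb window around APOE), (2) greedily clump by ascending p-value,
removing neighbours within a distance window whose dosage r^2 exceeds the LD
threshold, (3) sum effect-weighted allele dosages over the retained SNPs and
standardize across samples. LD is computed from the sample dosages themselves
rather than an external reference panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import MethylAccelError

R2_THRESHOLD = 0.25
CLUMP_WINDOW = 250_000
REGION_FLANK = 500_000

SUMMARY_COLUMNS = ("snp", "chr", "pos", "a1", "a2", "beta", "p")


def _validate_summary(summary: pd.DataFrame) -> None:
    missing = [c for c in SUMMARY_COLUMNS if c not in summary.columns]
    if missing:
        raise MethylAccelError(f"summary table missing columns: {missing}")
    if summary["snp"].duplicated().any():
        raise MethylAccelError("duplicate SNP ids in summary table")
    if (summary["pos"] <= 0).any():
        raise MethylAccelError("positions must be positive")
    p = summary["p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise MethylAccelError("summary p-values must lie in (0, 1]")


def ld_clump(summary: pd.DataFrame, dosages: pd.DataFrame,
             r2_threshold: float = R2_THRESHOLD,
             window: int = CLUMP_WINDOW,
             p_threshold: Optional[float] = None) -> List[str]:
    """Greedy clumping by ascending p-value.

    Keep the most significant unprocessed SNP; discard unprocessed SNPs on
    the same chromosome within ``window`` bp whose dosage r^2 with it exceeds
    ``r2_threshold`` (strict >); repeat. Ties on p are broken by position
    then id. Monomorphic SNPs are skipped with a warning. ``p_threshold``
    optionally restricts the roster before clumping.
    """
    _validate_summary(summary)
    shared = summary[summary["snp"].isin(dosages.columns)].copy()
    if p_threshold is not None:
        shared = shared[shared["p"] <= p_threshold]
    if dosages.shape[0] < 2:
        raise MethylAccelError("need >= 2 samples to estimate LD")

    D = dosages.loc[:, shared["snp"]].to_numpy(dtype=float)
    sds = D.std(axis=0)
    mono = sds == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic SNPs skipped during clumping")
        shared = shared.loc[~mono.to_numpy() if hasattr(mono, "to_numpy") else ~mono]
        D = D[:, ~mono]

    order = shared.sort_values(["p", "pos", "snp"], kind="mergesort").index
    snp_row = {snp: i for i, snp in enumerate(shared["snp"])}
    Dc = D - D.mean(axis=0)
    norms = np.sqrt((Dc**2).sum(axis=0))

    retained: List[str] = []
    removed = set()
    info = shared.set_index("snp")
    for idx in order:
        snp = shared.at[idx, "snp"]
        if snp in removed:
            continue
        retained.append(snp)
        chrom, pos = info.at[snp, "chr"], info.at[snp, "pos"]
        near = info[(info["chr"] == chrom) & ((info["pos"] - pos).abs() <= window)]
        i = snp_row[snp]
        for other in near.index:
            if other == snp or other in removed or other in retained:
                continue
            j = snp_row[other]
            r = float(Dc[:, i] @ Dc[:, j] / (norms[i] * norms[j]))
            if r * r > r2_threshold:
                removed.add(other)
    return retained


def exclude_region(summary: pd.DataFrame, chrom: str, start: int, end: int,
                   flank: int = REGION_FLANK) -> pd.DataFrame:
    """Drop SNPs on ``chrom`` with position in [start - flank, end + flank).

    Closed on the left edge, open on the right. An unknown chromosome token
    leaves the table untouched with a warning.
    """
    _validate_summary(summary)
    if start > end:
        raise MethylAccelError("region start must be <= end")
    if chrom not in set(summary["chr"]):
        warnings.warn(f"chromosome {chrom!r} absent from summary table; nothing excluded")
        return summary.copy()
    lo, hi = start - flank, end + flank
    in_region = (summary["chr"] == chrom) & (summary["pos"] >= lo) & (summary["pos"] < hi)
    return summary.loc[~in_region].copy()


@dataclass
class PRSResult:
    """Per-sample polygenic score."""

    raw: pd.Series
    standardized: pd.Series
    n_snps_used: int
    n_snps_dropped: int = 0


def compute_prs(dosages: pd.DataFrame, summary: pd.DataFrame,
                retained: Sequence[str],
                dosage_alleles: Optional[Mapping[str, str]] = None) -> PRSResult:
    """Effect-weighted dosage sum over the retained SNPs.

    ``dosage_alleles`` maps SNP id to the allele the dosage counts; when it is
    the summary's other allele the dosage is flipped (2 - d), and SNPs whose
    counted allele matches neither are dropped with a count reported.
    """
    _validate_summary(summary)
    info = summary.set_index("snp")
    unknown = [s for s in retained if s not in info.index or s not in dosages.columns]
    if unknown:
        raise MethylAccelError(f"retained SNPs absent from inputs: {unknown[:5]}")

    raw = np.zeros(dosages.shape[0])
    used, dropped = 0, 0
    for snp in retained:
        d = dosages[snp].to_numpy(dtype=float)
        effect = float(info.at[snp, "beta"])
        if dosage_alleles is not None and snp in dosage_alleles:
            counted = dosage_alleles[snp]
            if counted == info.at[snp, "a1"]:
                pass
            elif counted == info.at[snp, "a2"]:
                d = 2.0 - d
            else:
                dropped += 1
                continue
        raw += effect * d
        used += 1
    raw_s = pd.Series(raw, index=dosages.index, name="prs_raw")
    sd = raw_s.std(ddof=1)
    if sd == 0:
        std = raw_s * 0.0
    else:
        std = (raw_s - raw_s.mean()) / sd
    std.name = "prs_z"
    return PRSResult(raw=raw_s, standardized=std, n_snps_used=used, n_snps_dropped=dropped)
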