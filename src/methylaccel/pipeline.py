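"""End-to-end orchestration: simulate -> qc -> age -> assoc (-> prs).

A single YAML config drives the run; all randomness flows from one root seed
expanded per stage, every intermediate is written as text under the run
directory, and a manifest records the config hash, per-stage counts, and
output checksums so reruns can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age import compute_acceleration_table
from .association import (
    DEFAULT_ALPHA,
    DEFAULT_M_TESTS,
    build_relationship_matrix,
    run_association_suite,
)
from .containers import BetaMatrix, MethylAccelError
from .prs import compute_prs, exclude_region, ld_clump
from .qc import run_qc
from .synthetic import CohortSim, SimulationConfig, simulate_cohort, simulate_genotypes

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """Validated run configuration."""

    seed: int = 0
    output_dir: str = "methylaccel_run"
    alpha: float = DEFAULT_ALPHA
    m_tests: int = DEFAULT_M_TESTS
    simulate: Dict[str, Any] = field(default_factory=dict)
    stages: Dict[str, bool] = field(default_factory=lambda: {
        "qc": True, "age": True, "assoc": True, "prs": False})
    chain: Dict[str, int] = field(default_factory=lambda: {"iterations": 2000, "burn_in": 500})
    prs_params: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise MethylAccelError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical_hash(self) -> str:
        blob = json.dumps({
            "seed": self.seed, "alpha": self.alpha, "m_tests": self.m_tests,
            "simulate": self.simulate, "stages": self.stages, "chain": self.chain,
            "prs_params": self.prs_params,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def run_end_to_end(config: PipelineConfig) -> Dict[str, Any]:
    """Execute the configured stages in order and return the results bundle.

    Bundle keys: ``cohort`` (CohortSim), ``qc_report``, ``acceleration``,
    ``associations``, optional ``prs``, and ``manifest``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, Any] = {
        "config_hash": config.canonical_hash(),
        "package_version": __version__,
        "stages": {},
        "checksums": {},
    }
    bundle: Dict[str, Any] = {"manifest": manifest}
    root = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(("sim", "assoc", "prs"), root.spawn(3))}

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        sim_kwargs = dict(config.simulate)
        sim_kwargs["seed"] = seeds["sim"]
        cohort = simulate_cohort(SimulationConfig(**sim_kwargs))
        bundle["cohort"] = cohort
        cohort.pedigree.write_tsv(out / "pedigree.tsv")
        _write_tsv(cohort.phenotypes, out / "phenotypes.tsv")
        _write_tsv(cohort.truth, out / "latent_truth.tsv")
        cohort.methylation.data.write(out / "beta.csv", out / "detection_p.csv",
                                      out / "beadcount.csv")
        cohort.horvath_clock.write_csv(out / "clock_horvath_style.csv")
        cohort.hannum_clock.write_csv(out / "clock_hannum_style.csv")
        cohort.cell_reference.write_tsv(out / "cell_reference.tsv")
        pd.Series(cohort.methylation.annotation, name="chrom").rename_axis("probe_id") \
            .to_frame().to_csv(out / "annotation.tsv", sep="\t")
        manifest["stages"]["simulate"] = {
            "samples_out": int(cohort.methylation.data.n_samples),
            "probes_out": int(cohort.methylation.data.n_probes),
            "wall_s": round(time.perf_counter() - t0, 3),
        }

        m = cohort.methylation.data
        if config.stages.get("qc", True):
            stage = "qc"
            t0 = time.perf_counter()
            m, report = run_qc(m, cohort.methylation.annotation, cohort.recorded_sex)
            report.write(out / "qc_report.tsv", out / "qc_report.json")
            m.write(out / "beta_filtered.csv", out / "detection_p_filtered.csv",
                    out / "beadcount_filtered.csv")
            bundle["qc_report"] = report
            manifest["stages"]["qc"] = {
                "samples_in": report.n_samples_before, "samples_out": report.n_samples_after,
                "probes_in": report.n_probes_before, "probes_out": report.n_probes_after,
                "wall_s": round(time.perf_counter() - t0, 3),
            }

        accel = None
        if config.stages.get("age", True):
            stage = "age"
            t0 = time.perf_counter()
            chron = cohort.phenotypes["chronological_age"].loc[m.sample_ids]
            accel = compute_acceleration_table(
                m, chron, cohort.horvath_clock, cohort.hannum_clock,
                cohort.cell_reference)
            _write_tsv(accel.rename_axis("sample_id"), out / "acceleration.tsv")
            bundle["acceleration"] = accel
            manifest["stages"]["age"] = {
                "samples_in": int(m.n_samples), "samples_out": int(len(accel)),
                "wall_s": round(time.perf_counter() - t0, 3),
            }

        if config.stages.get("assoc", True):
            stage = "assoc"
            if accel is None:
                raise MethylAccelError("assoc stage requires the age stage")
            t0 = time.perf_counter()
            A = build_relationship_matrix(cohort.pedigree)
            assoc = run_association_suite(
                cohort.phenotypes, accel[["ieaa", "eeaa"]], A,
                m_tests=config.m_tests, alpha=config.alpha,
                seed=seeds["assoc"], chain=config.chain)
            _write_tsv(assoc, out / "associations.tsv", index=False)
            bundle["associations"] = assoc
            manifest["stages"]["assoc"] = {
                "samples_in": int(len(accel)), "rows_out": int(len(assoc)),
                "wall_s": round(time.perf_counter() - t0, 3),
            }

        if config.stages.get("prs", False):
            stage = "prs"
            t0 = time.perf_counter()
            pp = dict(config.prs_params)
            geno = simulate_genotypes(cohort.phenotypes,
                                      n_snps=int(pp.get("n_snps", 200)),
                                      ld_block_size=int(pp.get("ld_block_size", 5)),
                                      seed=seeds["prs"])
            summary = geno.summary
            if "exclude" in pp:
                chrom, start, end = pp["exclude"]["chrom"], pp["exclude"]["start"], pp["exclude"]["end"]
                summary = exclude_region(summary, str(chrom), int(start), int(end),
                                         flank=int(pp.get("flank", 500_000)))
            retained = ld_clump(summary, geno.dosages,
                                r2_threshold=float(pp.get("r2", 0.25)),
                                window=int(pp.get("window", 250_000)),
                                p_threshold=pp.get("p_threshold"))
            prs = compute_prs(geno.dosages, summary, retained)
            prs_df = pd.DataFrame({"prs_raw": prs.raw, "prs_z": prs.standardized})
            _write_tsv(prs_df.rename_axis("sample_id"), out / "prs.tsv")
            _write_tsv(summary, out / "gwas_summary_used.tsv", index=False)
            bundle["prs"] = prs
            manifest["stages"]["prs"] = {
                "snps_in": int(len(geno.summary)), "snps_used": prs.n_snps_used,
                "wall_s": round(time.perf_counter() - t0, 3),
            }
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(_manifest_json(manifest))
        logger.error("pipeline aborted at stage %s", stage)
        raise

    report_text = write_report(bundle, alpha=config.alpha, m_tests=config.m_tests)
    (out / "report.txt").write_text(report_text)
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["checksums"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(_manifest_json(manifest))
    return bundle


def _manifest_json(manifest: Dict[str, Any]) -> str:
    # wall times vary between reruns; keep them out of the stable manifest
    clean = json.loads(json.dumps(manifest))
    for st in clean.get("stages", {}).values():
        st.pop("wall_s", None)
    return json.dumps(clean, indent=2, sort_keys=True) + "\n"


def write_report(bundle: Dict[str, Any], alpha: float = DEFAULT_ALPHA,
                 m_tests: int = DEFAULT_M_TESTS) -> str:
    """Human-readable run summary: QC counts, the association table, and the
    Bonferroni threshold line with significant rows flagged."""
    lines = [f"methylaccel v{__version__} run report", ""]
    report = bundle.get("qc_report")
    if report is not None:
        lines += [
            "QC:",
            f"  samples: {report.n_samples_before} -> {report.n_samples_after} "
            f"({len(report.excluded_samples)} excluded)",
            f"  probes:  {report.n_probes_before} -> {report.n_probes_after} "
            f"({len(report.excluded_probes)} excluded)",
            "",
        ]
    accel = bundle.get("acceleration")
    if accel is not None:
        r_h = accel["horvath_style_age"].corr(accel["chronological_age"])
        r_n = accel["hannum_style_age"].corr(accel["chronological_age"])
        lines += [
            "Clock ages:",
            f"  Horvath-style vs chronological r = {r_h:.3f}",
            f"  Hannum-style  vs chronological r = {r_n:.3f}",
            "",
        ]
    assoc = bundle.get("associations")
    threshold = round(alpha / m_tests, 4)
    lines.append(f"Bonferroni threshold: alpha/m = {alpha}/{m_tests} = "
                 + f"{threshold:.4f}".lstrip("0"))
    if assoc is None or len(assoc) == 0:
        lines.append("Associations: no tests were run.")
    else:
        lines += ["", "Associations (risk factor x exposure):",
                  f"  {'risk_factor':<18}{'exposure':<9}{'beta':>9}{'ci_low':>9}"
                  f"{'ci_high':>9}{'p':>11}{'p_adj':>11}  sig"]
        for _, row in assoc.iterrows():
            flag = "*" if row["p_adjusted"] < alpha else ""
            lines.append(
                f"  {row['risk_factor']:<18}{row['exposure']:<9}"
                f"{row['beta']:>9.3f}{row['ci_low']:>9.3f}{row['ci_high']:>9.3f}"
                f"{row['p']:>11.3g}{row['p_adjusted']:>11.3g}  {flag}")
    return "\n".join(lines) + "\n"
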