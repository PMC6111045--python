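"""Sample and probe quality control for methylation beta matrices.

The exclusion rules, applied in order:

1. samples in which >= 1% of probes have a detection p-value above 0.05;
2. probes with a beadcount below 3 in more than 5 samples;
3. probes in which >= 0.5% of the remaining samples have a detection
   p-value above 0.05;
4. samples whose methylation-predicted sex disagrees with the recorded sex.

Boundary semantics are pinned exactly: the failure fractions are inclusive
(>=), the detection p cut-off is strict (> 0.05), "beadcount below 3" is
strict (< 3), "more than 5 samples" is strict (> 5). Probe-level fractions
are evaluated on the sample set surviving step 1.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from .containers import BetaMatrix, MethylAccelError

logger = logging.getLogger(__name__)

DETECTION_P_THRESHOLD = 0.05
SAMPLE_FAIL_FRACTION = 0.01
PROBE_FAIL_FRACTION = 0.005
BEADCOUNT_MIN = 3
BEADCOUNT_MAX_SAMPLES = 5

#: Default decision threshold for sex prediction: midpoint between the
#: female-like (0.5) and male-like (0.2) mean chrX beta archetypes.
SEX_BETA_THRESHOLD = 0.35


@dataclass
class QCReport:
    """Bookkeeping for one QC pass: what was excluded, why, and the counts."""

    excluded_samples: Dict[str, str] = field(default_factory=dict)  # id -> reason
    excluded_probes: Dict[str, str] = field(default_factory=dict)
    thresholds: Dict[str, float] = field(default_factory=dict)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_probes_before: int = 0
    n_probes_after: int = 0

    def validate(self) -> None:
        if self.n_samples_before - len(self.excluded_samples) != self.n_samples_after:
            raise MethylAccelError("sample counts do not reconcile")
        if self.n_probes_before - len(self.excluded_probes) != self.n_probes_after:
            raise MethylAccelError("probe counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"item": s, "kind": "sample", "reason": r} for s, r in self.excluded_samples.items()]
        rows += [{"item": p, "kind": "probe", "reason": r} for p, r in self.excluded_probes.items()]
        return pd.DataFrame(rows, columns=["item", "kind", "reason"])

    def write(self, tsv_path, json_path) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        payload = {
            "excluded_samples": self.excluded_samples,
            "excluded_probes": self.excluded_probes,
            "thresholds": self.thresholds,
            "counts": {
                "samples_before": self.n_samples_before,
                "samples_after": self.n_samples_after,
                "probes_before": self.n_probes_before,
                "probes_after": self.n_probes_after,
            },
        }
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def filter_samples_by_detection(m: BetaMatrix,
                                p_threshold: float = DETECTION_P_THRESHOLD,
                                fail_fraction: float = SAMPLE_FAIL_FRACTION) -> List[str]:
    """Samples where the fraction of probes with detection p > ``p_threshold``
    is at least ``fail_fraction`` (inclusive)."""
    _check_threshold(p_threshold, "p_threshold")
    _check_threshold(fail_fraction, "fail_fraction")
    failing = (m.detection_p.to_numpy() > p_threshold).mean(axis=1)
    return list(m.sample_ids[failing >= fail_fraction])


def filter_probes(m: BetaMatrix,
                  beadcount_min: int = BEADCOUNT_MIN,
                  beadcount_max_samples: int = BEADCOUNT_MAX_SAMPLES,
                  p_threshold: float = DETECTION_P_THRESHOLD,
                  fail_fraction: float = PROBE_FAIL_FRACTION) -> Dict[str, str]:
    """Probe exclusions with reasons: beadcount < ``beadcount_min`` in more
    than ``beadcount_max_samples`` samples, or detection failure in >=
    ``fail_fraction`` of samples. Beadcount rule is skipped (with a warning)
    when the beadcount matrix is absent."""
    _check_threshold(p_threshold, "p_threshold")
    _check_threshold(fail_fraction, "fail_fraction")
    excluded: Dict[str, str] = {}
    if m.beadcount is not None:
        low = (m.beadcount.to_numpy() < beadcount_min).sum(axis=0)
        for probe in m.probe_ids[low > beadcount_max_samples]:
            excluded[probe] = "beadcount"
    else:
        warnings.warn("beadcount matrix absent; beadcount probe filter skipped")
        logger.warning("beadcount matrix absent; beadcount probe filter skipped")
    failing = (m.detection_p.to_numpy() > p_threshold).mean(axis=0)
    for probe in m.probe_ids[failing >= fail_fraction]:
        excluded.setdefault(probe, "detection")
    return excluded


def predict_sex(m: BetaMatrix, annotation: Mapping[str, str],
                threshold: float = SEX_BETA_THRESHOLD,
                sex_chromosome: str = "chrX") -> pd.Series:
    """Predict sex from mean beta over annotated sex-chromosome probes:
    female iff mean chrX beta exceeds ``threshold``."""
    sex_probes = [p for p in m.probe_ids if annotation.get(p) == sex_chromosome]
    if not sex_probes:
        raise MethylAccelError(f"no probes annotated on {sex_chromosome}")
    mean_beta = m.beta.loc[:, sex_probes].mean(axis=1)
    return pd.Series(np.where(mean_beta > threshold, "female", "male"),
                     index=m.sample_ids, name="predicted_sex")


def check_sex_concordance(m: BetaMatrix, annotation: Mapping[str, str],
                          recorded_sex: Mapping[str, str],
                          threshold: float = SEX_BETA_THRESHOLD) -> List[str]:
    """Samples whose predicted sex differs from the recorded sex."""
    predicted = predict_sex(m, annotation, threshold)
    return [s for s in m.sample_ids if predicted[s] != recorded_sex[s]]


def run_qc(m: BetaMatrix, annotation: Mapping[str, str],
           recorded_sex: Mapping[str, str],
           p_threshold: float = DETECTION_P_THRESHOLD,
           sample_fail_fraction: float = SAMPLE_FAIL_FRACTION,
           probe_fail_fraction: float = PROBE_FAIL_FRACTION,
           beadcount_min: int = BEADCOUNT_MIN,
           beadcount_max_samples: int = BEADCOUNT_MAX_SAMPLES,
           sex_threshold: float = SEX_BETA_THRESHOLD):
    """Apply all QC rules in order and return (filtered BetaMatrix, QCReport)."""
    report = QCReport(
        thresholds={
            "p_threshold": p_threshold,
            "sample_fail_fraction": sample_fail_fraction,
            "probe_fail_fraction": probe_fail_fraction,
            "beadcount_min": beadcount_min,
            "beadcount_max_samples": beadcount_max_samples,
            "sex_threshold": sex_threshold,
        },
        n_samples_before=m.n_samples,
        n_probes_before=m.n_probes,
    )

    bad_samples = filter_samples_by_detection(m, p_threshold, sample_fail_fraction)
    for s in bad_samples:
        report.excluded_samples[s] = "detection"
    kept_samples = m.sample_ids.difference(bad_samples, sort=False)
    if len(kept_samples) == 0:
        raise MethylAccelError("QC excluded every sample at the detection step")
    m1 = m.subset(samples=kept_samples)

    # probe rules evaluated on the surviving sample set
    bad_probes = filter_probes(m1, beadcount_min, beadcount_max_samples,
                               p_threshold, probe_fail_fraction)
    report.excluded_probes.update(bad_probes)
    kept_probes = m1.probe_ids.difference(bad_probes.keys(), sort=False)
    if len(kept_probes) == 0:
        raise MethylAccelError("QC excluded every probe")
    m2 = m1.subset(probes=kept_probes)

    mismatched = check_sex_concordance(m2, annotation, recorded_sex, sex_threshold)
    for s in mismatched:
        report.excluded_samples[s] = "sex_mismatch"
    final_samples = m2.sample_ids.difference(mismatched, sort=False)
    if len(final_samples) == 0:
        raise MethylAccelError("QC excluded every sample at the sex-concordance step")
    out = m2.subset(samples=final_samples)

    report.n_samples_after = out.n_samples
    report.n_probes_after = out.n_probes
    report.validate()
    logger.info("QC: samples %d -> %d, probes %d -> %d",
                report.n_samples_before, report.n_samples_after,
                report.n_probes_before, report.n_probes_after)
    return out, report


def _check_threshold(x: float, name: str) -> None:
    if not (0 < x <= 1):
        raise MethylAccelError(f"{name} must lie in (0, 1], got {x}")
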