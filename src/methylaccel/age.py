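"""Epigenetic age prediction, cell deconvolution, and age-acceleration measures.

Intrinsic epigenetic age acceleration (IEAA) is the residual of a
Horvath-style clock age regressed on chronological age plus the seven
estimated blood cell proportions, so it is insensitive to composition shifts.
Extrinsic acceleration (EEAA) first combines a Hannum-style clock age with
the three age-varying immune measures (naive cytotoxic T, exhausted cytotoxic
T, plasmablast proportions) by the Klemera-Doubal weighting, then takes the
residual of that weighted biological age on chronological age; it tracks
immunosenescence as well as intrinsic drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import (
    CELL_TYPES,
    EEAA_CELL_TYPES,
    BetaMatrix,
    CellReference,
    ClockModel,
    MethylAccelError,
)

# Fraction of clock probes that may be mean-imputed before prediction refuses.
MAX_MISSING_CLOCK_FRACTION = 0.20


# ---------------------------------------------------------------------------
# Age calibration transform
# ---------------------------------------------------------------------------

def age_transform(age, adult_age: float):
    """Log-linear age calibration: logarithmic below ``adult_age``, linear above.

    F(age) = log(age + 1) - log(adult_age + 1)        for age <= adult_age
    F(age) = (age - adult_age) / (adult_age + 1)      otherwise

    F is continuous, strictly increasing, and F(adult_age) = 0.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1):
        raise MethylAccelError("age_transform requires age > -1")
    lo = np.log1p(age) - np.log1p(adult_age)
    hi = (age - adult_age) / (adult_age + 1.0)
    return np.where(age <= adult_age, lo, hi)


def inverse_age_transform(t, adult_age: float):
    """Exact inverse of :func:`age_transform`."""
    t = np.asarray(t, dtype=float)
    lo = np.expm1(t + np.log1p(adult_age))
    hi = t * (adult_age + 1.0) + adult_age
    return np.where(t <= 0, lo, hi)


def _to_years(transformed, clock: ClockModel):
    if clock.transform == "identity":
        return np.asarray(transformed, dtype=float)
    return inverse_age_transform(transformed, clock.adult_age)


def _from_years(years, clock: ClockModel):
    if clock.transform == "identity":
        return np.asarray(years, dtype=float)
    return age_transform(years, clock.adult_age)


# ---------------------------------------------------------------------------
# Clock prediction
# ---------------------------------------------------------------------------

def predict_age(m: BetaMatrix, clock: ClockModel,
                missing_policy: str = "mean-impute") -> pd.Series:
    """Predict per-sample epigenetic age (years) from a clock table.

    Missing clock probes are mean-imputed from the cohort (policy
    ``"mean-impute"``) up to ``MAX_MISSING_CLOCK_FRACTION``; more than that, or
    policy ``"strict"`` with any probe missing, raises.
    """
    probes = clock.weights.index
    present = probes.intersection(m.probe_ids)
    missing = probes.difference(m.probe_ids)
    frac_missing = len(missing) / len(probes)
    if frac_missing > 0 and missing_policy == "strict":
        raise MethylAccelError(f"{len(missing)} clock probes missing under strict policy")
    if frac_missing > MAX_MISSING_CLOCK_FRACTION:
        raise MethylAccelError(
            f"{frac_missing:.1%} of clock probes missing exceeds the "
            f"{MAX_MISSING_CLOCK_FRACTION:.0%} imputation limit")

    betas = m.beta.loc[:, present]
    linear = clock.intercept + betas.to_numpy() @ clock.weights.loc[present].to_numpy()
    if len(missing):
        # cohort-mean imputation: absent probes contribute the mean of the
        # observed probes (the only cohort information available for them)
        impute_value = float(np.nanmean(m.beta.to_numpy()))
        linear = linear + impute_value * clock.weights.loc[missing].sum()
    return pd.Series(_to_years(linear, clock), index=m.sample_ids, name=clock.name)


# ---------------------------------------------------------------------------
# Reference-based cell deconvolution
# ---------------------------------------------------------------------------

#: Weight on the sum-to-one augmentation row in the NNLS system.
_SUM_CONSTRAINT_WEIGHT = 1000.0


def estimate_cell_proportions(m: BetaMatrix, ref: CellReference) -> pd.DataFrame:
    """Estimate the seven cell-type proportions per sample.

    Constrained least squares: per sample, minimise the squared deviation of
    the observed betas from the reference mixture subject to non-negativity
    and sum-to-one. Solved by non-negative least squares with a heavily
    weighted sum-to-one row, then exact renormalisation.
    """
    shared = ref.probe_ids.intersection(m.probe_ids)
    if len(shared) < len(CELL_TYPES):
        raise MethylAccelError(
            f"only {len(shared)} probes shared with the cell reference; need >= {len(CELL_TYPES)}")
    R = ref.reference_betas.loc[shared].to_numpy()  # probes x 7
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise MethylAccelError("cell reference is rank-deficient on the shared probes")

    A = np.vstack([R, _SUM_CONSTRAINT_WEIGHT * np.ones((1, R.shape[1]))])
    props = np.empty((m.n_samples, R.shape[1]))
    B = m.beta.loc[:, shared].to_numpy()
    for i in range(m.n_samples):
        b = np.concatenate([B[i], [_SUM_CONSTRAINT_WEIGHT]])
        x, _ = nnls(A, b)
        total = x.sum()
        if total <= 0:
            raise MethylAccelError("degenerate deconvolution: all-zero solution")
        props[i] = x / total
    return pd.DataFrame(props, index=m.sample_ids, columns=list(CELL_TYPES))


# ---------------------------------------------------------------------------
# Least-squares residual helpers
# ---------------------------------------------------------------------------

def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    # residuals (the projection complement) are unique even when X is
    # rank-deficient, e.g. noise-free cell mixtures exactly affine in age,
    # so lstsq's minimum-norm solution is used rather than refusing
    if X.shape[0] <= X.shape[1]:
        raise MethylAccelError(f"need more samples ({X.shape[0]}) than covariates ({X.shape[1]})")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def compute_ieaa(clock_ages: pd.Series, chronological: pd.Series,
                 cells: pd.DataFrame, reference_cell: str = "granulocyte") -> pd.Series:
    """Intrinsic acceleration: residual of clock age on chronological age and
    six free cell proportions (``reference_cell`` dropped to break the
    sum-to-one collinearity of the simplex)."""
    idx = clock_ages.index
    free = [c for c in CELL_TYPES if c != reference_cell]
    X = np.column_stack([
        np.ones(len(idx)),
        chronological.loc[idx].to_numpy(dtype=float),
        cells.loc[idx, free].to_numpy(dtype=float),
    ])
    resid = _ols_residuals(clock_ages.to_numpy(dtype=float), X)
    return pd.Series(resid, index=idx, name="ieaa")


def compute_eeaa(weighted_age: pd.Series, chronological: pd.Series) -> pd.Series:
    """Extrinsic acceleration: residual of the weighted biological age on
    chronological age (simple least squares)."""
    if len(weighted_age) < 3:
        raise MethylAccelError("need at least 3 samples")
    chron = chronological.loc[weighted_age.index].to_numpy(dtype=float)
    if np.var(chron) == 0:
        raise MethylAccelError("chronological age has zero variance")
    X = np.column_stack([np.ones(len(chron)), chron])
    resid = _ols_residuals(weighted_age.to_numpy(dtype=float), X)
    return pd.Series(resid, index=weighted_age.index, name="eeaa")


# ---------------------------------------------------------------------------
# Klemera-Doubal biological-age combination
# ---------------------------------------------------------------------------

@dataclass
class KDMWeights:
    """Per-biomarker calibration against chronological age.

    For each biomarker j: x_j = q_j + k_j * age + noise(sd s_j), fitted by
    ordinary least squares on the cohort.
    """

    biomarkers: list
    k: np.ndarray  # slopes, biomarker units / year
    q: np.ndarray  # intercepts, biomarker units
    s: np.ndarray  # residual standard deviations

    def __post_init__(self) -> None:
        if np.any(self.k == 0):
            raise MethylAccelError("KDM slopes must be nonzero")
        if np.any(self.s < 0):
            raise MethylAccelError("KDM residual sds must be non-negative")


#: Minimum slope magnitude (per year, relative to biomarker scale) below which
#: a biomarker is rejected as uninformative about age.
_KDM_SLOPE_TOL = 1e-10

#: Floor applied to s_j inside the combination so an exact-fit biomarker
#: cannot carry infinite weight.
_KDM_S_FLOOR = 1e-8


def fit_kdm_weights(biomarkers: pd.DataFrame, chronological: pd.Series) -> KDMWeights:
    """Fit per-biomarker (k, q, s) by OLS of each biomarker on age."""
    age = chronological.loc[biomarkers.index].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(age)), age])
    ks, qs, ss, names = [], [], [], []
    for col in biomarkers.columns:
        y = biomarkers[col].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        q, k = coef
        if abs(k) <= _KDM_SLOPE_TOL * max(1.0, float(np.std(y))):
            raise MethylAccelError(
                f"biomarker {col!r} has no usable age slope (k={k:.3g}); rejected")
        resid = y - X @ coef
        dof = max(len(age) - 2, 1)
        ks.append(k)
        qs.append(q)
        ss.append(float(np.sqrt(resid @ resid / dof)))
        names.append(col)
    return KDMWeights(biomarkers=names, k=np.array(ks), q=np.array(qs), s=np.array(ss))


def kdm_combine(biomarkers: pd.DataFrame, w: KDMWeights,
                chronological: Optional[pd.Series] = None) -> pd.Series:
    """Klemera-Doubal weighted biological age.

    BA_i = [ sum_j (x_ij - q_j) k_j / s_j^2 ] / [ sum_j k_j^2 / s_j^2 ]

    With ``chronological`` supplied, chronological age enters as an extra
    pseudo-biomarker with unit slope, zero intercept, and the characteristic
    residual sd of the roster (the anchored variant).
    """
    if list(biomarkers.columns) != list(w.biomarkers):
        raise MethylAccelError("biomarker roster does not match the fitted weights")
    X = biomarkers.to_numpy(dtype=float)
    s = np.maximum(w.s, _KDM_S_FLOOR)
    num = (X - w.q) @ (w.k / s**2)
    den = float(np.sum(w.k**2 / s**2))
    if chronological is not None:
        s_ba = float(np.sqrt(len(w.k) / den))  # characteristic roster sd
        num = num + chronological.loc[biomarkers.index].to_numpy(dtype=float) / s_ba**2
        den = den + 1.0 / s_ba**2
    return pd.Series(num / den, index=biomarkers.index, name="kdm_age")


# ---------------------------------------------------------------------------
# Full acceleration table
# ---------------------------------------------------------------------------

def compute_acceleration_table(
    m: BetaMatrix,
    chronological: pd.Series,
    horvath_clock: ClockModel,
    hannum_clock: ClockModel,
    cell_ref: CellReference,
    cells: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Run the whole acceleration stage: clock ages, cells, IEAA, EEAA.

    Returns a DataFrame indexed by sample with columns ``chronological_age``,
    ``horvath_style_age``, ``hannum_style_age``, ``ieaa``, ``eeaa``.
    """
    chron = chronological.loc[m.sample_ids].astype(float)
    horvath_age = predict_age(m, horvath_clock)
    hannum_age = predict_age(m, hannum_clock)
    if cells is None:
        cells = estimate_cell_proportions(m, cell_ref)

    ieaa = compute_ieaa(horvath_age, chron, cells)

    roster = pd.DataFrame({"hannum_style_age": hannum_age})
    for ct in EEAA_CELL_TYPES:
        roster[ct] = cells[ct]
    weights = fit_kdm_weights(roster, chron)
    weighted = kdm_combine(roster, weights)
    eeaa = compute_eeaa(weighted, chron)

    return pd.DataFrame({
        "chronological_age": chron,
        "horvath_style_age": horvath_age,
        "hannum_style_age": hannum_age,
        "ieaa": ieaa,
        "eeaa": eeaa,
    })
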