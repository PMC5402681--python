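"""Covariate-only null model and score-vector machinery.

Every test in this package is a score test against the same null: the
outcome depends on the covariates only.  For a continuous trait the null is
an ordinary least-squares fit of Y on (1, X); for a binary trait a logistic
fit.  The fit yields per-sample fitted values mu0, residuals r = Y - mu0 and
a dispersion Phi (residual variance for continuous traits, 1 for binary).

OTU abundances enter as standardized compositions: per-sample proportions,
column-centred and scaled to unit sample standard deviation.  The score for
OTU j is then U_j = sum_i r_i * Zstd_ij, whose sign is the per-OTU effect
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import InputError, OtuTable, StudyDesign


@dataclass(frozen=True)
class NullFit:
    """Fitted covariate-only null model shared by every test."""

    mu0: np.ndarray
    residuals: np.ndarray
    phi: float
    trait: str

    @property
    def n_samples(self) -> int:
        return self.residuals.shape[0]


@dataclass(frozen=True)
class StandardizedComposition:
    """Column-wise z-scored proportion matrix.

    ``zero_variance`` flags columns that were constant across samples; those
    columns are set to all zeros so they contribute nothing to any score.
    """

    values: np.ndarray
    zero_variance: np.ndarray

    @property
    def n_otus(self) -> int:
        return self.values.shape[1]


def to_composition(otu) -> np.ndarray:
    """Convert counts to per-sample proportions (rows sum to 1)."""
    counts = otu.counts if isinstance(otu, OtuTable) else np.asarray(otu, dtype=float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise InputError("zero-total sample; drop it before computing proportions")
    return counts / totals[:, None]


def scale_columns(M: np.ndarray) -> tuple:
    """Z-score columns with the sample (n-1) standard deviation.

    Returns (scaled, zero_variance_mask); constant columns become zeros.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 2:
        raise InputError("need at least 2 samples to standardize")
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    zero = sd == 0
    sd_safe = np.where(zero, 1.0, sd)
    Z = (M - mu) / sd_safe
    Z[:, zero] = 0.0
    return Z, zero


def standardize_composition(P: np.ndarray) -> StandardizedComposition:
    """Standardize a proportion matrix column-wise (mean 0, sample SD 1)."""
    Z, zero = scale_columns(P)
    return StandardizedComposition(Z, zero)


def fit_null(design: StudyDesign) -> NullFit:
    """Fit the covariate-only null model for either trait type.

    Continuous: OLS of Y on (intercept, X); phi = RSS / (n - q - 1).
    Binary: logistic MLE; mu0 are fitted probabilities and phi = 1.
    """
    y = design.y
    X = design.covariates
    n, q = X.shape
    D = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise InputError(
            "covariate matrix is rank-deficient after adding an intercept; "
            "remove collinear columns"
        )
    if design.trait == "continuous":
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        mu0 = D @ beta
        r = y - mu0
        dof = n - q - 1
        if dof <= 0:
            raise InputError("not enough samples for the covariate count")
        phi = float(r @ r / dof)
        if phi <= 0:
            raise InputError("null model fits the outcome exactly; no residual variance")
        return NullFit(mu0, r, phi, "continuous")
    # binary
    import statsmodels.api as sm

    try:
        res = sm.GLM(y, D, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception as exc:  # pragma: no cover - statsmodels raises rarely
        raise InputError(f"logistic null fit failed ({exc}); reduce covariates")
    if not res.converged:
        raise InputError("logistic null fit did not converge; reduce covariates")
    mu0 = np.asarray(res.fittedvalues)
    if mu0.min() < 1e-10 or mu0.max() > 1 - 1e-10:
        raise InputError("logistic null shows quasi-separation; reduce covariates")
    return NullFit(mu0, y - mu0, 1.0, "binary")


def score_vector(fit: NullFit, Z) -> np.ndarray:
    """Per-OTU score U_j = sum_i (Y_i - mu0_i) * Z_ij."""
    M = Z.values if isinstance(Z, StandardizedComposition) else np.asarray(Z, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.shape[0] != fit.n_samples:
        raise InputError("score_vector: sample dimension mismatch")
    return fit.residuals @ M


def effect_sign(u) -> str:
    """Effect direction label for a score component: '+' iff U_j >= 0."""
    return "+" if float(u) >= 0 else "-"
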