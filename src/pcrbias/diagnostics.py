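"""Posterior diagnostics: multivariate R^2, batch-effect norms, credible sets.

The multivariate R^2 is computed per posterior draw in the fit's log-ratio
coordinates as one minus the ratio of Frobenius norms of the regression
residual and the row-centered total variation:

    R^2(s) = 1 - ||eta(s) - Lambda(s) X||_F^2
               / ||eta(s) - rowmean(eta(s))||_F^2

so a draw whose latent coordinates are exactly linear in X scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import BiasEstimate
from .mlnl import DesignMatrix, PosteriorFit

__all__ = ["posterior_r2", "batch_effect_norms", "credible_summary", "CredibleSummary"]


def posterior_r2(fit: PosteriorFit, design: DesignMatrix | None = None) -> np.ndarray:
    """Per-draw multivariate R^2 of the log-ratio linear model.

    Returns an array of length S; values are at most 1 and can be negative
    for draws fit worse than the per-coordinate mean.
    """
    if design is None:
        design = fit.design
    if design is None:
        raise ValueError("a design matrix is required")
    eta = fit.eta_draws  # (S, P, N)
    pred = fit.lambda_draws @ design.x  # (S, P, N)
    resid = ((eta - pred) ** 2).sum(axis=(1, 2))
    centered = eta - eta.mean(axis=2, keepdims=True)
    total = (centered**2).sum(axis=(1, 2))
    if np.any(total == 0):
        raise ValueError("total variation is zero; R^2 undefined")
    return 1.0 - resid / total


def batch_effect_norms(bias: BiasEstimate) -> dict[str, np.ndarray]:
    """Per-draw Euclidean norm of each batch term, in the fit's coordinates.

    A batch whose norm distribution stochastically dominates the others is a
    candidate processing outlier (e.g. a miscalibrated PCR machine) and can
    be excluded before re-estimating bias.
    """
    if bias.gamma_draws.shape[-1] == 0:
        raise ValueError("no batch columns in this design")
    return {
        name: np.linalg.norm(bias.gamma_draws[:, :, b], axis=1)
        for b, name in enumerate(bias.batch_names)
    }


@dataclass(frozen=True)
class CredibleSummary:
    mean: float
    lower: float
    upper: float
    excludes_zero: bool
    level: float


def credible_summary(draws: np.ndarray, level: float = 0.95) -> CredibleSummary:
    """Equal-tailed credible interval with a zero-exclusion flag.

    Quantiles use linear interpolation of order statistics (numpy's default
    rule), stated here for reproducibility.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 2:
        raise ValueError("need at least two draws")
    if not np.all(np.isfinite(draws)):
        raise ValueError("draws must be finite")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lower, upper = np.quantile(draws, [tail, 1.0 - tail])
    return CredibleSummary(
        mean=float(draws.mean()),
        lower=float(lower),
        upper=float(upper),
        excludes_zero=bool(lower > 0 or upper < 0),
        level=level,
    )
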