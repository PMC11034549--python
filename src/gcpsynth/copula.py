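"""Gaussian-copula synthesis of the latent patient table.

The three copula steps:

1. draw t_1..t_R from MVN(0, P) where P is the Pearson correlation matrix
   of the observed latent columns;
2. push through the standard normal CDF, u_r = Phi(t_r);
3. invert each column's marginal, a_r = F_r^{-1}(u_r).

Because latent-space sampling is inexact, a draw is accepted only when the
Frobenius distance between the synthetic and original correlation matrices
is below a threshold epsilon; up to ``max_tries`` draws are attempted and
the best (smallest-distance) draw is returned with ``accepted=False`` if
none passes.

Marginal estimators: midpoint-rank empirical CDF with linear interpolation
between order statistics (default), Gaussian-kernel smoothed CDF, or
maximum-likelihood parametric fits (gamma, beta, truncated Gaussian with
truncation at the observed min/max).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .latent import LatentTable

__all__ = ["CopulaSpec", "CopulaResult", "copula_sample"]

log = logging.getLogger(__name__)

MARGINAL_KINDS = (
    "empirical_cdf",
    "kernel_smoothed",
    "parametric_gamma",
    "parametric_beta",
    "parametric_truncated_gaussian",
)


@dataclass(frozen=True)
class CopulaSpec:
    """Copula sampler configuration (marginals, acceptance threshold, seed)."""

    marginal_kind: str = "empirical_cdf"
    epsilon: float = 0.5
    max_tries: int = 50
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.marginal_kind not in MARGINAL_KINDS:
            raise ValueError(
                f"unknown marginal kind {self.marginal_kind!r}; "
                f"choose from {MARGINAL_KINDS}"
            )
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_tries < 1:
            raise ValueError("max_tries must be >= 1")


@dataclass
class CopulaResult:
    """Accepted/best synthetic table plus the acceptance trace."""

    table: LatentTable
    accepted: bool
    tries: int
    frobenius_distance: float


def _empirical_inverse(u: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Midpoint-rank empirical quantile with linear interpolation.

    Plotting positions p_i = (i - 0.5)/n; u outside [p_1, p_n] clamps to the
    observed extremes, so inversion never extrapolates.
    """
    xs = np.sort(data)
    n = xs.size
    p = (np.arange(1, n + 1) - 0.5) / n
    return np.interp(u, p, xs)


def _kde_inverse(u: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Inverse of a Gaussian-KDE-smoothed CDF, tabulated on a fine grid."""
    if np.std(data) == 0:
        return np.full_like(u, data[0])
    kde = stats.gaussian_kde(data)
    bw = np.sqrt(kde.covariance[0, 0])
    lo, hi = data.min() - 4 * bw, data.max() + 4 * bw
    grid = np.linspace(lo, hi, 1024)
    cdf = np.array([kde.integrate_box_1d(-np.inf, g) for g in grid])
    cdf = np.clip(cdf, 0.0, 1.0)
    cdf[0], cdf[-1] = 0.0, 1.0
    cdf = np.maximum.accumulate(cdf)
    return np.interp(u, cdf, grid)


def _parametric_inverse(u: np.ndarray, data: np.ndarray, kind: str) -> np.ndarray:
    if kind == "parametric_gamma":
        a, loc, scale = stats.gamma.fit(data)
        return stats.gamma.ppf(u, a, loc=loc, scale=scale)
    if kind == "parametric_beta":
        lo, hi = data.min(), data.max()
        span = max(hi - lo, 1e-12)
        scaled = np.clip((data - lo) / span, 1e-6, 1 - 1e-6)
        a, b, floc, fscale = stats.beta.fit(scaled, floc=0.0, fscale=1.0)
        return stats.beta.ppf(u, a, b) * span + lo
    # truncated Gaussian: truncation bounds = observed min/max, moment-based
    # loc/scale from the sample
    lo, hi = data.min(), data.max()
    mu, sd = data.mean(), max(data.std(ddof=1), 1e-12)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sd)


def _inverse_marginal(u: np.ndarray, data: np.ndarray, kind: str) -> np.ndarray:
    if kind == "empirical_cdf":
        return _empirical_inverse(u, data)
    if kind == "kernel_smoothed":
        return _kde_inverse(u, data)
    return _parametric_inverse(u, data, kind)


def _correlation(values: np.ndarray) -> np.ndarray:
    """Pearson correlation over columns; constant columns get 0 off-diagonal."""
    sd = values.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    z = (values - values.mean(axis=0)) / safe
    corr = z.T @ z / len(values)
    np.fill_diagonal(corr, 1.0)
    return corr


def nearest_positive_definite(corr: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Repair a non-PD correlation matrix by eigenvalue clipping."""
    w, v = np.linalg.eigh(corr)
    if w.min() > floor:
        return corr
    warnings.warn("correlation matrix not positive definite; clipping eigenvalues")
    w = np.clip(w, floor, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def copula_sample(latent: LatentTable, n_out: int, spec: CopulaSpec | None = None) -> CopulaResult:
    """Draw ``n_out`` synthetic latent rows through a Gaussian copula."""
    spec = spec or CopulaSpec()
    if latent.n_rows < 3:
        raise ValueError("copula sampling needs at least 3 latent rows")
    if n_out < 1:
        raise ValueError("n_out must be >= 1")

    x = latent.values()
    corr0 = _correlation(x)
    corr = nearest_positive_definite(corr0)
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(spec.random_seed)

    best: np.ndarray | None = None
    best_dist = np.inf
    tries = 0
    for tries in range(1, spec.max_tries + 1):
        t = rng.standard_normal((n_out, corr.shape[0])) @ chol.T
        u = stats.norm.cdf(t)
        syn = np.column_stack(
            [
                _inverse_marginal(u[:, r], x[:, r], spec.marginal_kind)
                for r in range(x.shape[1])
            ]
        )
        dist = float(np.linalg.norm(_correlation(syn) - corr0))
        if dist < best_dist:
            best_dist, best = dist, syn
        if dist < spec.epsilon:
            return CopulaResult(latent.like(syn), True, tries, dist)
    log.warning(
        "copula: no draw met epsilon=%.3g in %d tries (best %.3g); returning best",
        spec.epsilon,
        tries,
        best_dist,
    )
    return CopulaResult(latent.like(best), False, tries, best_dist)
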