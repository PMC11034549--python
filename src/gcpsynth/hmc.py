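"""Hamiltonian Monte Carlo over the covariance of the latent patient table.

Model: latent rows x_i are i.i.d. MVN(0, Sigma) with the mean pinned at
zero and Sigma unknown.  Sigma is separated into standard deviations and a
correlation matrix, Sigma = diag(sigma) * Omega * diag(sigma), with
half-Cauchy(scale) priors on each sigma_r and an LKJ(eta) prior on Omega
(eta = 1 is flat over valid correlation matrices).  Because the latent
factors of a Gaussian-loss GCP fit are approximately Gaussian, the sampler
refuses tables whose provenance loss is not Gaussian unless overridden.

Sampling runs in the unconstrained space z = (log-diagonal and strict lower
triangle of the Cholesky factor L of Sigma), with the exact log-Jacobian
corrections for z -> L -> Sigma -> (sigma, Omega).  The chain is plain HMC:
leapfrog integration with a diagonal mass matrix estimated during warmup
and dual-averaging step-size adaptation targeting 80% acceptance.
Split-Rhat and effective sample size come from arviz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .latent import LatentTable

__all__ = ["HmcSpec", "CovariancePosterior", "hmc_fit", "hmc_sample"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HmcSpec:
    """HMC configuration: chains, iterations, priors, integrator settings."""

    chains: int = 4
    warmup: int = 500
    samples: int = 500
    random_seed: int = 0
    cauchy_scale: float = 2.5
    lkj_concentration: float = 1.0
    leapfrog_steps: int = 24
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.warmup < 10 or self.samples < 1:
            raise ValueError("iteration counts must be positive (warmup >= 10)")
        if self.cauchy_scale <= 0:
            raise ValueError("cauchy_scale must be > 0")


@dataclass
class CovariancePosterior:
    """Posterior draws of Sigma plus convergence diagnostics."""

    sigma_draws: np.ndarray  # (chains, draws, R, R)
    accept_rate: np.ndarray  # per chain
    rhat: np.ndarray  # per unique Sigma entry (upper triangle incl. diagonal)
    ess: np.ndarray
    warnings: list[str] = field(default_factory=list)
    template: LatentTable | None = field(repr=False, default=None)

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.sigma_draws.mean(axis=(0, 1))

    def flattened(self) -> np.ndarray:
        """All retained draws of Sigma, stacked over chains: (T, R, R)."""
        c, d, r, _ = self.sigma_draws.shape
        return self.sigma_draws.reshape(c * d, r, r)

    def save_draws(self, path) -> None:
        """Persist draws as a delimited table: one row per draw, columns the
        upper triangle of Sigma (sigma_i_j, i <= j) plus the chain index."""
        c, d, r, _ = self.sigma_draws.shape
        iu = np.triu_indices(r)
        cols = [f"sigma_{i + 1}_{j + 1}" for i, j in zip(*iu)]
        df = pd.DataFrame(self.flattened()[:, iu[0], iu[1]], columns=cols)
        df.insert(0, "chain", np.repeat(np.arange(c), d))
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")


class _LogPosterior:
    """Unnormalized log posterior and gradient in the unconstrained space z."""

    def __init__(self, x: np.ndarray, cauchy_scale: float, eta: float) -> None:
        self.n, self.r = x.shape
        self.s = x.T @ x  # sufficient statistic
        self.scale2 = cauchy_scale**2
        self.eta = eta
        tril = np.tril_indices(self.r)
        self.rows, self.cols = tril
        self.dim = self.rows.size

    def _to_chol(self, z: np.ndarray) -> np.ndarray:
        L = np.zeros((self.r, self.r))
        L[self.rows, self.cols] = z
        d = np.arange(self.r)
        L[d, d] = np.exp(z[self.rows == self.cols])
        return L

    def chol_to_z(self, L: np.ndarray) -> np.ndarray:
        z = L[self.rows, self.cols].copy()
        diag_pos = self.rows == self.cols
        z[diag_pos] = np.log(np.diag(L))
        return z

    def value_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            return self._value_and_grad(z)

    def _value_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        r, n = self.r, self.n
        L = self._to_chol(z)
        ldiag = np.diag(L)
        sigma = L @ L.T
        sinv = np.linalg.inv(sigma)
        dvar = np.diag(sigma)  # sigma_r^2
        logdet = 2.0 * np.log(ldiag).sum()

        # log likelihood
        f = -0.5 * n * logdet - 0.5 * float(np.sum(sinv * self.s))
        # half-Cauchy prior on sigma_r (as a density in sigma_r)
        f += -np.log(self.scale2 + dvar).sum()
        # LKJ(eta) prior on the correlation matrix
        f += (self.eta - 1.0) * (logdet - np.log(dvar).sum())
        # Jacobians: L->Sigma, (sigma,Omega)->Sigma inverse, z->L (log-diag)
        i1 = np.arange(1, r + 1)
        f += float(((r + 2.0 - i1) * np.log(ldiag)).sum())
        f += -0.5 * r * np.log(dvar).sum()

        # assemble dF/dSigma (entries treated as independent)
        p = -0.5 * n * sinv + 0.5 * sinv @ self.s @ sinv
        dd = np.zeros(r)
        dd += -1.0 / (self.scale2 + dvar)
        dd += -(self.eta - 1.0) / dvar
        dd += -0.5 * r / dvar
        p = p + np.diag(dd) + (self.eta - 1.0) * sinv

        g_l = 2.0 * p @ L
        d = np.arange(r)
        g_l[d, d] += (r + 2.0 - i1) / ldiag
        g_l[d, d] *= ldiag  # chain rule for the log-diagonal
        grad = g_l[self.rows, self.cols]
        return f, grad


def _dual_averaging_state(eps0: float):
    return {
        "mu": np.log(10.0 * eps0),
        "log_eps_bar": 0.0,
        "h_bar": 0.0,
        "t": 0,
        "gamma": 0.05,
        "t0": 10.0,
        "kappa": 0.75,
    }


def _dual_averaging_update(state: dict, accept_prob: float, target: float) -> float:
    state["t"] += 1
    t = state["t"]
    eta = 1.0 / (t + state["t0"])
    state["h_bar"] = (1 - eta) * state["h_bar"] + eta * (target - accept_prob)
    log_eps = state["mu"] - np.sqrt(t) / state["gamma"] * state["h_bar"]
    w = t ** (-state["kappa"])
    state["log_eps_bar"] = w * log_eps + (1 - w) * state["log_eps_bar"]
    return float(np.exp(log_eps))


def _run_chain(
    post: _LogPosterior, z0: np.ndarray, spec: HmcSpec, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    dim = post.dim
    mass = np.ones(dim)
    eps = 0.1 / post.r

    def leapfrog(z, p, step):
        f, g = post.value_and_grad(z)
        p = p + 0.5 * step * g
        for _ in range(spec.leapfrog_steps - 1):
            z = z + step * p / mass
            _, g = post.value_and_grad(z)
            p = p + step * g
        z = z + step * p / mass
        f, g = post.value_and_grad(z)
        p = p + 0.5 * step * g
        return z, p, f

    def hmc_step(z, f, step):
        p = rng.normal(0.0, np.sqrt(mass))
        h0 = f - 0.5 * float(np.sum(p * p / mass))
        jitter = rng.uniform(0.9, 1.1)
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                z_new, p_new, f_new = leapfrog(z, p, step * jitter)
            h1 = f_new - 0.5 * float(np.sum(p_new * p_new / mass))
            delta = h1 - h0
        except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
            return z, f, 0.0
        if not np.isfinite(delta):  # divergent trajectory: reject
            return z, f, 0.0
        log_alpha = min(0.0, delta)
        if np.log(rng.uniform()) < log_alpha:
            return z_new, f_new, float(np.exp(log_alpha))
        return z, f, float(np.exp(log_alpha))

    z = z0.copy()
    f, _ = post.value_and_grad(z)

    # warmup phase 1: step-size adaptation with unit mass
    half = spec.warmup // 2
    da = _dual_averaging_state(eps)
    window: list[np.ndarray] = []
    for it in range(half):
        z, f, a = hmc_step(z, f, eps)
        eps = _dual_averaging_update(da, a, spec.target_accept)
        if it >= half // 2:
            window.append(z.copy())
    # estimate a diagonal mass matrix (inverse posterior variances)
    if len(window) >= 10:
        var = np.var(np.asarray(window), axis=0)
        var = np.clip(var, 1e-8, None)
        mass = 1.0 / var
    # warmup phase 2: re-adapt the step size under the new metric
    eps = float(np.exp(da["log_eps_bar"]))
    da = _dual_averaging_state(eps)
    for _ in range(spec.warmup - half):
        z, f, a = hmc_step(z, f, eps)
        eps = _dual_averaging_update(da, a, spec.target_accept)
    eps = float(np.exp(da["log_eps_bar"]))

    draws = np.empty((spec.samples, dim))
    accepts = 0.0
    for it in range(spec.samples):
        z, f, a = hmc_step(z, f, eps)
        draws[it] = z
        accepts += a
    return draws, accepts / spec.samples


def hmc_fit(
    latent: LatentTable,
    spec: HmcSpec | None = None,
    allow_non_gaussian: bool = False,
) -> CovariancePosterior:
    """Posterior over the latent covariance via HMC.

    Raises unless the latent table's provenance loss is Gaussian (the MVN
    model is only sensible there) or ``allow_non_gaussian`` is set.
    """
    spec = spec or HmcSpec()
    if latent.n_rows < 10:
        raise ValueError("HMC covariance inference needs at least 10 rows")
    if (
        latent.provenance_loss is not None
        and latent.provenance_loss != "gaussian"
        and not allow_non_gaussian
    ):
        raise ValueError(
            f"latent table was produced by a {latent.provenance_loss!r}-loss fit; "
            "the multivariate-Gaussian model assumes Gaussian loss "
            "(pass allow_non_gaussian=True to override)"
        )

    x = latent.values()  # model mean is pinned at zero; no centering
    post = _LogPosterior(x, spec.cauchy_scale, spec.lkj_concentration)
    r = post.r

    # initialize chains near the Cholesky of the sample covariance, jittered
    samp_cov = x.T @ x / len(x)
    samp_cov = samp_cov + 1e-8 * np.eye(r)
    z_hat = post.chol_to_z(np.linalg.cholesky(samp_cov))

    all_draws = np.empty((spec.chains, spec.samples, post.dim))
    accept = np.empty(spec.chains)
    for c in range(spec.chains):
        rng = np.random.default_rng((spec.random_seed, c))
        z0 = z_hat + rng.normal(0.0, 0.1, size=post.dim)
        all_draws[c], accept[c] = _run_chain(post, z0, spec, rng)

    # map draws back to Sigma
    sigma_draws = np.empty((spec.chains, spec.samples, r, r))
    for c in range(spec.chains):
        for t in range(spec.samples):
            L = post._to_chol(all_draws[c, t])
            sigma_draws[c, t] = L @ L.T

    iu = np.triu_indices(r)
    flat = sigma_draws[:, :, iu[0], iu[1]]
    ds = az.convert_to_dataset({"sigma": flat})
    rhat = az.rhat(ds)["sigma"].to_numpy()
    ess = az.ess(ds)["sigma"].to_numpy()

    warn: list[str] = []
    if np.any(rhat > 1.1):
        warn.append(f"convergence warning: max split-Rhat {float(np.max(rhat)):.3f} > 1.1")
    for w in warn:
        log.warning(w)
    return CovariancePosterior(sigma_draws, accept, rhat, ess, warn, latent)


def hmc_sample(
    posterior: CovariancePosterior, n_out: int, seed: int = 0
) -> LatentTable:
    """Draw ``n_out`` synthetic latent rows, one per retained posterior draw.

    Cycles through the retained Sigma draws in order, sampling a fresh
    MVN(0, Sigma) row from each, until ``n_out`` rows are produced.
    """
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    draws = posterior.flattened()
    rng = np.random.default_rng(seed)
    r = draws.shape[1]
    rows = np.empty((n_out, r))
    chols = {}
    for i in range(n_out):
        t = i % len(draws)
        if t not in chols:
            chols[t] = np.linalg.cholesky(draws[t] + 1e-12 * np.eye(r))
        rows[i] = chols[t] @ rng.standard_normal(r)
    if posterior.template is not None:
        return posterior.template.like(rows)
    return LatentTable(pd.DataFrame(rows, columns=[f"a{j + 1}" for j in range(r)]))
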