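"""Fitting the generalized CP decomposition.

The decomposition minimizes the mask-weighted elementwise loss

    F(A, B, C) = sum_{ijk} w[ijk] * l(x[ijk], m[ijk]),
    m[ijk] = sum_r A[i,r] B[j,r] C[k,r]

over the three factor matrices, where w is the binary observation mask.
The gradient has the classical unfolded form: with Y[ijk] = w * dl/dm,

    dF/dA = unfold(Y, 1) @ khatri_rao(C, B)

and cyclically for B and C.  Optimization uses deterministic full-gradient
L-BFGS-B (the tensors here are small); nonnegativity, when requested, is
enforced through bound constraints, i.e. projection onto the nonnegative
orthant inside the quasi-Newton iteration.  Multiple seeded restarts guard
against bad local minima; the best final objective wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import DomainError, GcpsynthError
from .losses import LossSpec
from .tensor import KruskalModel, Tensor3, fit_score, khatri_rao, reconstruct, unfold

__all__ = ["FitOptions", "RankDiagnostics", "objective", "gradient", "fit_gcp", "select_rank"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :func:`fit_gcp`.

    ``optimizer`` may be "lbfgs" (default, scipy L-BFGS-B) or "adam" (plain
    first-order loop with projection; mostly useful as a cross-check).
    """

    max_iterations: int = 2000
    gradient_tolerance: float = 1e-10
    random_seed: int = 0
    init_scale: float = 0.5
    nonnegative: bool = False
    optimizer: str = "lbfgs"
    restarts: int = 2
    adam_learning_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.gradient_tolerance <= 0:
            raise ValueError("gradient_tolerance must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.optimizer not in ("lbfgs", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class RankDiagnostics:
    """Per-candidate-rank fit diagnostics (the elbow-rule inputs)."""

    ranks: list[int] = field(default_factory=list)
    objectives: list[float] = field(default_factory=list)
    fit_scores: list[float] = field(default_factory=list)
    mses: list[float] = field(default_factory=list)

    def append(self, rank: int, obj: float, score: float, mse: float) -> None:
        if self.ranks and rank <= self.ranks[-1]:
            raise ValueError("candidate ranks must be strictly increasing")
        self.ranks.append(rank)
        self.objectives.append(obj)
        self.fit_scores.append(score)
        self.mses.append(mse)


def _model_values(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.einsum("ir,jr,kr->ijk", a, b, c)


def objective(x: Tensor3, model: KruskalModel, spec: LossSpec) -> float:
    """Mask-weighted sum of elementwise losses; masked cells contribute 0."""
    if model.shape != x.shape:
        raise ValueError(f"model shape {model.shape} != tensor shape {x.shape}")
    spec.check_domain(x.filled(1.0), x.observed)
    m = reconstruct(model)
    _check_model_domain(m, spec, x.observed)
    vals, _ = spec.value_and_deriv(x.filled(1.0), m)
    return float((x.mask * vals).sum())


def gradient(
    x: Tensor3, model: KruskalModel, spec: LossSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`objective` with respect to (A, B, C)."""
    if model.shape != x.shape:
        raise ValueError(f"model shape {model.shape} != tensor shape {x.shape}")
    a, b, c = model.factors
    lam = model.weights
    m = reconstruct(model)
    _check_model_domain(m, spec, x.observed)
    _, d = spec.value_and_deriv(x.filled(1.0), m)
    y = x.mask * d
    ga = unfold(y, 1) @ khatri_rao(c, b) * lam
    gb = unfold(y, 2) @ khatri_rao(c, a) * lam
    gc = unfold(y, 3) @ khatri_rao(b, a) * lam
    return ga, gb, gc


def _check_model_domain(m: np.ndarray, spec: LossSpec, observed: np.ndarray) -> None:
    lb = spec.lower_bound
    if lb > -np.inf and (m[observed] < lb).any():
        idx = np.argwhere(observed & (m < lb))[0]
        raise DomainError(
            f"model value below {lb} at observed cell {tuple(int(v) for v in idx)} "
            f"for loss {spec.name!r}"
        )


def _init_factors(
    shape: tuple[int, int, int], rank: int, options: FitOptions, rng: np.random.Generator
) -> list[np.ndarray]:
    if options.nonnegative:
        return [rng.uniform(0.0, options.init_scale, (n, rank)) for n in shape]
    return [rng.standard_normal((n, rank)) * options.init_scale for n in shape]


def _pack(factors: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([f.ravel() for f in factors])


def _unpack(z: np.ndarray, shape: tuple[int, int, int], rank: int) -> list[np.ndarray]:
    out, pos = [], 0
    for n in shape:
        out.append(z[pos : pos + n * rank].reshape(n, rank))
        pos += n * rank
    return out


def fit_gcp(
    x: Tensor3,
    rank: int,
    spec: LossSpec | None = None,
    options: FitOptions | None = None,
    _warm_start: list[np.ndarray] | None = None,
) -> KruskalModel:
    """Fit a rank-R generalized CP model to the observed cells of ``x``.

    Returns the best model over ``options.restarts`` seeded initializations
    (plus an optional warm start).  Deterministic given the seed.
    """
    spec = spec or LossSpec()
    options = options or FitOptions()
    if rank < 1:
        raise ValueError("rank must be >= 1")
    spec.check_domain(x.filled(1.0), x.observed)
    nonneg = options.nonnegative or spec.lower_bound >= 0.0

    shape = x.shape
    mask = x.mask
    xfill = x.filled(1.0)
    lam = np.ones(rank)

    def fun_grad(z: np.ndarray) -> tuple[float, np.ndarray]:
        a, b, c = _unpack(z, shape, rank)
        m = _model_values(a, b, c)
        if spec.lower_bound >= 0.0:
            # projected iterates keep factors >= 0 so m >= 0 already; clip for safety
            m = np.maximum(m, 0.0)
        vals, d = spec.value_and_deriv(xfill, m)
        y = mask * d
        ga = unfold(y, 1) @ khatri_rao(c, b)
        gb = unfold(y, 2) @ khatri_rao(c, a)
        gc = unfold(y, 3) @ khatri_rao(b, a)
        f = float((mask * vals).sum())
        if not np.isfinite(f):
            raise GcpsynthError(
                f"non-finite objective during optimization (loss={spec.name}, rank={rank})"
            )
        return f, _pack([ga, gb, gc])

    starts: list[list[np.ndarray]] = []
    if _warm_start is not None:
        starts.append([np.asarray(f, dtype=float) for f in _warm_start])
    for t in range(options.restarts):
        rng = np.random.default_rng((options.random_seed, rank, t))
        starts.append(_init_factors(shape, rank, options, rng))

    best_z, best_f = None, np.inf
    bounds = [(0.0, None)] * (sum(shape) * rank) if nonneg else None
    for factors0 in starts:
        z0 = _pack(factors0)
        if nonneg:
            z0 = np.maximum(z0, 0.0)
        if options.optimizer == "lbfgs":
            res = minimize(
                fun_grad,
                z0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": options.max_iterations,
                    "gtol": options.gradient_tolerance,
                    "ftol": 1e-15,
                    "maxls": 50,
                },
            )
            z, f = res.x, float(res.fun)
        else:
            z, f = _adam(fun_grad, z0, options, nonneg)
        if f < best_f:
            best_f, best_z = f, z

    a, b, c = _unpack(best_z, shape, rank)
    if nonneg:
        a, b, c = np.maximum(a, 0.0), np.maximum(b, 0.0), np.maximum(c, 0.0)
    return KruskalModel(
        factors=(a, b, c), weights=lam, loss_name=spec.name, nonnegative=nonneg
    )


def _adam(fun_grad, z0: np.ndarray, options: FitOptions, nonneg: bool):
    """Plain Adam with orthant projection; cross-check optimizer."""
    z = z0.copy()
    m = np.zeros_like(z)
    v = np.zeros_like(z)
    lr, b1, b2, eps = options.adam_learning_rate, 0.9, 0.999, 1e-8
    f = np.inf
    for t in range(1, options.max_iterations + 1):
        f, g = fun_grad(z)
        if np.linalg.norm(g, np.inf) < options.gradient_tolerance:
            break
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mh = m / (1 - b1**t)
        vh = v / (1 - b2**t)
        z = z - lr * mh / (np.sqrt(vh) + eps)
        if nonneg:
            z = np.maximum(z, 0.0)
    return z, fun_grad(z)[0]


def _observed_mse(x: Tensor3, m: np.ndarray) -> float:
    obs = x.observed
    return float(np.mean((x.values[obs] - m[obs]) ** 2))


def select_rank(
    x: Tensor3,
    candidates: list[int],
    spec: LossSpec | None = None,
    options: FitOptions | None = None,
    plateau: float = 0.01,
) -> tuple[int, RankDiagnostics]:
    """Elbow-rule rank selection.

    Fits every candidate rank (ascending, warm-starting each fit from the
    previous rank's factors padded with a fresh column) and returns the
    smallest rank beyond which neither the objective (relative to the
    first candidate's) nor the fit score improves by more than ``plateau``.
    """
    if not candidates:
        raise ValueError("candidate rank list is empty")
    candidates = sorted(set(int(r) for r in candidates))
    if candidates[0] < 1:
        raise ValueError("ranks must be >= 1")
    I, J, K = x.shape
    bound = min(I * J, I * K, J * K)
    if candidates[-1] > bound:
        raise ValueError(f"max candidate rank {candidates[-1]} exceeds bound {bound}")
    spec = spec or LossSpec()
    options = options or FitOptions()

    diag = RankDiagnostics()
    models: list[KruskalModel] = []
    prev: KruskalModel | None = None
    for r in candidates:
        warm = None
        if prev is not None:
            rng = np.random.default_rng((options.random_seed, r, 999))
            pad = r - prev.rank
            warm = []
            for f in prev.factors:
                extra = (
                    rng.uniform(0, options.init_scale, (f.shape[0], pad))
                    if (options.nonnegative or spec.lower_bound >= 0)
                    else rng.standard_normal((f.shape[0], pad)) * options.init_scale
                )
                warm.append(np.hstack([f, extra]))
        model = fit_gcp(x, r, spec, options, _warm_start=warm)
        m = reconstruct(model)
        diag.append(r, objective(x, model, spec), fit_score(x, m), _observed_mse(x, m))
        models.append(model)
        prev = model

    f0 = max(abs(diag.objectives[0]), 1e-12)
    chosen = candidates[-1]
    for t in range(len(candidates) - 1):
        flat = all(
            (diag.objectives[u] - diag.objectives[u + 1]) / f0 < plateau
            and (diag.fit_scores[u + 1] - diag.fit_scores[u]) < plateau
            for u in range(t, len(candidates) - 1)
        )
        if flat:
            chosen = candidates[t]
            break
    log.info("select_rank: chose R=%d from candidates %s", chosen, candidates)
    return chosen, diag
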