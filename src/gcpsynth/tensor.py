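"""Dense 3-way tensor algebra for patients x variables x visits data.

The central objects are :class:`Tensor3`, a dense array paired with a binary
observation mask and axis labels, and :class:`KruskalModel`, a rank-R CP
(Kruskal) factorization ``m[i,j,k] = sum_r lambda_r A[i,r] B[j,r] C[k,r]``
with the loss it was fitted under.  Unobserved cells carry NaN and are never
read by any objective, transform or metric.

Unfolding convention: ``unfold(x, mode)`` puts the selected axis on the rows
and flattens the remaining axes in their original order with the *earlier*
axis varying fastest (Fortran order).  Under this convention the mode-1
unfolding of a Kruskal tensor is ``A @ diag(lam) @ khatri_rao(C, B).T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateVariableError,
    InvalidModelError,
    UndefinedScoreError,
)

__all__ = [
    "Tensor3",
    "KruskalModel",
    "StandardizationTransform",
    "khatri_rao",
    "unfold",
    "fold",
    "reconstruct",
    "fit_score",
    "standardize",
    "destandardize",
]

LOSS_NAMES = ("gaussian", "gamma", "beta_divergence", "poisson_log")


def _default_labels(n: int, prefix: str) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


@dataclass
class Tensor3:
    """Dense 3-way data tensor with a paired binary observation mask.

    Parameters
    ----------
    values
        Array of shape (I, J, K): patients x variables x visits.  Cells with
        ``mask == 0`` hold NaN as a sentinel and are behaviourally undefined.
    mask
        {0,1} array of the same shape; 1 marks an observed cell.
    patient_ids, variable_names, visit_indices
        Axis labels.  Visit indices are 1-based integers.
    """

    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    patient_ids: list[str] = None  # type: ignore[assignment]
    variable_names: list[str] = None  # type: ignore[assignment]
    visit_indices: list[int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-way, got ndim={self.values.ndim}")
        if self.mask is None:
            self.mask = np.ones(self.values.shape)
        self.mask = np.asarray(self.mask, dtype=float)
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        if not np.isin(self.mask, (0.0, 1.0)).all():
            raise ValueError("mask entries must be exactly 0 or 1")
        I, J, K = self.values.shape
        if self.patient_ids is None:
            self.patient_ids = _default_labels(I, "p")
        if self.variable_names is None:
            self.variable_names = _default_labels(J, "var")
        if self.visit_indices is None:
            self.visit_indices = list(range(1, K + 1))
        if (len(self.patient_ids), len(self.variable_names), len(self.visit_indices)) != (
            I,
            J,
            K,
        ):
            raise ValueError("axis label counts must match tensor dimensions")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def observed(self) -> np.ndarray:
        """Boolean observation mask."""
        return self.mask > 0.5

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with masked cells replaced by ``fill`` (safe for arithmetic)."""
        return np.where(self.observed, self.values, fill)

    def copy(self) -> "Tensor3":
        return Tensor3(
            self.values.copy(),
            self.mask.copy(),
            list(self.patient_ids),
            list(self.variable_names),
            list(self.visit_indices),
        )

    def missing_fraction(self) -> float:
        return float(1.0 - self.mask.mean())


@dataclass
class KruskalModel:
    """Rank-R Kruskal (CP) factorization with positive weights.

    ``weights`` defaults to the all-ones vector: scale is absorbed into the
    patient factors so that B and C used at reconstruction are exactly the
    fitted ones.
    """

    factors: tuple[np.ndarray, np.ndarray, np.ndarray]
    weights: np.ndarray = None  # type: ignore[assignment]
    loss_name: str = "gaussian"
    nonnegative: bool = False

    def __post_init__(self) -> None:
        self.factors = tuple(np.asarray(f, dtype=float) for f in self.factors)  # type: ignore[assignment]
        if len(self.factors) != 3:
            raise InvalidModelError("exactly three factor matrices required")
        ranks = {f.shape[1] for f in self.factors if f.ndim == 2}
        if any(f.ndim != 2 for f in self.factors) or len(ranks) != 1:
            raise InvalidModelError("factors must be matrices sharing one column count")
        r = ranks.pop()
        if r < 1:
            raise InvalidModelError("rank must be >= 1")
        if self.weights is None:
            self.weights = np.ones(r)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (r,):
            raise InvalidModelError(
                f"weights length {self.weights.shape} does not match rank {r}"
            )
        if self.loss_name not in LOSS_NAMES:
            raise InvalidModelError(f"unknown loss {self.loss_name!r}")
        if self.nonnegative and any((f < 0).any() for f in self.factors):
            raise InvalidModelError("nonnegative flag set but factors have negatives")

    @property
    def rank(self) -> int:
        return self.factors[0].shape[1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(f.shape[0] for f in self.factors)  # type: ignore[return-value]

    def with_absorbed_weights(self) -> "KruskalModel":
        """Fold the weight vector into the patient factors (lambda -> 1)."""
        a, b, c = self.factors
        return replace(
            self,
            factors=(a * self.weights, b.copy(), c.copy()),
            weights=np.ones(self.rank),
        )


def khatri_rao(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product.

    Row ``(i1, i2)`` of the result maps to index ``i1 * rows(m2) + i2``, the
    ordering that pairs with the Fortran-order unfolding used here.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.ndim != 2 or m2.ndim != 2 or m1.shape[1] != m2.shape[1]:
        raise ValueError("khatri_rao requires matrices with equal column counts")
    r = m1.shape[1]
    return np.einsum("ir,jr->ijr", m1, m2).reshape(-1, r)


def unfold(values: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n matricization, ``mode`` in {1, 2, 3} (1-based)."""
    values = np.asarray(values)
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    ax = mode - 1
    return np.moveaxis(values, ax, 0).reshape(values.shape[ax], -1, order="F")


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold`: ``fold(unfold(x, m), m, x.shape) == x``."""
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    ax = mode - 1
    rest = tuple(s for i, s in enumerate(shape) if i != ax)
    arr = np.asarray(matrix).reshape((shape[ax],) + rest, order="F")
    return np.moveaxis(arr, 0, ax)


def reconstruct(model: KruskalModel) -> np.ndarray:
    """Full tensor of the Kruskal model: sum of R weighted rank-1 tensors."""
    a, b, c = model.factors
    return np.einsum("r,ir,jr,kr->ijk", model.weights, a, b, c)


def fit_score(x: Tensor3, m: np.ndarray) -> float:
    """1 - relative Frobenius residual over observed cells (1 = perfect fit)."""
    m = np.asarray(m, dtype=float)
    if m.shape != x.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {x.shape}")
    obs = x.observed
    xnorm = np.linalg.norm(x.values[obs])
    if xnorm == 0.0:
        raise UndefinedScoreError("fit score undefined: observed tensor is all zero")
    resid = np.linalg.norm(x.values[obs] - m[obs])
    return float(1.0 - resid / xnorm)


@dataclass
class StandardizationTransform:
    """Per-variable location/scale computed over observed entries only.

    ``scale`` uses the sample standard deviation (n-1 denominator).
    """

    location: np.ndarray
    scale: np.ndarray
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if (self.scale <= 0).any():
            raise DegenerateVariableError("all standardization scales must be > 0")


def standardize(t: Tensor3) -> tuple[Tensor3, StandardizationTransform]:
    """Center/scale each variable slice to observed mean 0 and sd 1."""
    J = t.shape[1]
    loc = np.empty(J)
    scale = np.empty(J)
    for j in range(J):
        vals = t.values[:, j, :][t.observed[:, j, :]]
        if vals.size < 2:
            raise DegenerateVariableError(
                f"variable {t.variable_names[j]!r} has < 2 observed entries"
            )
        loc[j] = vals.mean()
        scale[j] = vals.std(ddof=1)
        if scale[j] <= 0 or not np.isfinite(scale[j]):
            raise DegenerateVariableError(
                f"variable {t.variable_names[j]!r} is constant; cannot standardize"
            )
    out = t.copy()
    out.values = (t.values - loc[None, :, None]) / scale[None, :, None]
    out.values[~t.observed] = np.nan
    tf = StandardizationTransform(loc, scale, list(t.variable_names))
    return out, tf


def destandardize(t: Tensor3, transform: StandardizationTransform) -> Tensor3:
    """Invert :func:`standardize` on observed entries; mask passes through."""
    out = t.copy()
    out.values = t.values * transform.scale[None, :, None] + transform.location[
        None, :, None
    ]
    out.values[~t.observed] = np.nan
    return out
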