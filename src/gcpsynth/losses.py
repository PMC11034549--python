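"""Elementwise loss catalog for generalized CP fitting.

Each loss is a function l(x, m) of a data value x and a model value m,
with an analytic partial derivative dl/dm.  The catalog covers the losses
used for continuous and categorical EHR tensors:

- ``gaussian``       l = (x - m)^2                    (any x, m)
- ``poisson_log``    l = exp(m) - x*m                 (x >= 0; m is the log-rate)
- ``gamma``          l = x/(m+eps) + log(m+eps)       (x >= 0, m >= 0)
- ``beta_divergence``
    l = x^beta / (beta (beta-1)) + m^beta / beta
        - x * m^(beta-1) / (beta-1)                   (x >= 0, m >= 0;
    beta not in {0, 1}; evaluated at m + eps)

For losses with log/division terms a small positive ``offset`` (eps)
stabilizes the boundary m = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .tensor import LOSS_NAMES

__all__ = ["LossSpec", "loss_eval"]


@dataclass(frozen=True)
class LossSpec:
    """Loss choice plus its hyperparameters.

    ``beta`` only applies to ``beta_divergence``; ``offset`` only to losses
    with log/division terms.  ``lower_bound`` is the model-value domain
    constraint implied by the loss (0.0 for gamma/beta, -inf otherwise).
    """

    name: str = "gaussian"
    beta: float = 1.5
    offset: float = 1e-10

    def __post_init__(self) -> None:
        if self.name not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.name!r}; choose from {LOSS_NAMES}")
        if self.name == "beta_divergence" and self.beta in (0.0, 1.0):
            raise ValueError("beta_divergence requires beta not in {0, 1}")
        if self.offset <= 0:
            object.__setattr__(self, "offset", 1e-10)

    @property
    def lower_bound(self) -> float:
        """Lower bound on admissible model values m."""
        return 0.0 if self.name in ("gamma", "beta_divergence") else -np.inf

    @property
    def requires_nonnegative_data(self) -> bool:
        return self.name in ("gamma", "beta_divergence", "poisson_log")

    def check_domain(self, x: np.ndarray, where: np.ndarray | None = None) -> None:
        """Raise :class:`DomainError` if observed data violate the domain."""
        if not self.requires_nonnegative_data:
            return
        x = np.asarray(x, dtype=float)
        bad = x < 0
        if where is not None:
            bad = bad & where
        if bad.any():
            idx = tuple(int(v) for v in np.argwhere(bad)[0])
            raise DomainError(
                f"loss {self.name!r} requires nonnegative data; "
                f"negative value at cell {idx}"
            )

    def value_and_deriv(self, x: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized (l(x, m), dl/dm); broadcasts like numpy."""
        x = np.asarray(x, dtype=float)
        m = np.asarray(m, dtype=float)
        if self.name == "gaussian":
            r = m - x
            return r * r, 2.0 * r
        if self.name == "poisson_log":
            em = np.exp(m)
            return em - x * m, em - x
        if (m < self.lower_bound).any():
            raise DomainError(f"loss {self.name!r} requires model values >= 0")
        ms = m + self.offset
        if self.name == "gamma":
            return x / ms + np.log(ms), (1.0 - x / ms) / ms
        # beta-divergence, beta not in {0, 1}
        b = self.beta
        val = x**b / (b * (b - 1.0)) + ms**b / b - x * ms ** (b - 1.0) / (b - 1.0)
        dval = ms ** (b - 1.0) - x * ms ** (b - 2.0)
        return val, dval


def loss_eval(spec: LossSpec, x: float, m: float) -> tuple[float, float]:
    """Scalar loss value and derivative dl/dm at a single (x, m) pair."""
    spec.check_domain(np.asarray([x]))
    v, d = spec.value_and_deriv(np.asarray(x), np.asarray(m))
    return float(v), float(d)
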