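"""Seeded generators for longitudinal test data with known ground truth.

Two generators:

- :func:`make_lowrank` draws a random Kruskal model and returns the noisy
  tensor together with the true model — the oracle for fitting tests.
- :func:`make_ehr_like` emulates a hospital lab-panel extract: a patients x
  variables x visits tensor with cross-variable correlation, temporal
  autocorrelation, MCAR missingness, irregular visit counts and optional
  categorical features, emitted as a tidy long table.

Generative equations for the continuous EHR-like data (so tests can compute
closed-form targets):  with patient effects g_i ~ MVN(0, P) over the J
variables, P exchangeable with off-diagonal rho_g, and AR(1) visit noise
e_ijk = phi * e_ij,k-1 + sqrt(1 - phi^2) * eps (unit marginal sd),

    x[i,j,k] = mu_j + s_j * ( sqrt(tau) * g_ij + sqrt(1 - tau) * e_ijk )

where tau is the patient-effect variance share.  The cross-variable
correlation of x is tau * rho_g, so a requested correlation rho is realized
by setting rho_g = rho / tau (requires rho <= tau).  Categorical variables
draw a per-patient "home" level from the requested marginals and repeat it
at each visit with the persistence probability, otherwise redrawing.

Defaults mirror the regimes of a critical-care lab extract: a 226-patient x
4-variable dense panel, a 36-visit panel with 21% of cells missing
completely at random, and a 246-patient x 2-variable categorical panel.
All values are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .longio import LongTable
from .tensor import KruskalModel, Tensor3, reconstruct

__all__ = [
    "SimSpec",
    "CategoricalSpec",
    "make_lowrank",
    "make_ehr_like",
    "dense_lab_profile",
    "sparse_lab_profile",
    "irregular_lab_profile",
    "categorical_admissions_profile",
]


@dataclass(frozen=True)
class CategoricalSpec:
    """One categorical variable: level count, marginals, visit persistence."""

    name: str
    n_levels: int
    probabilities: tuple[float, ...] | None = None
    persistence: float = 0.8

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("categorical variables need >= 2 levels")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if len(p) != self.n_levels or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
                raise ValueError(
                    f"probabilities for {self.name!r} must be {self.n_levels} "
                    "nonnegative values summing to 1"
                )
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")

    def marginals(self) -> np.ndarray:
        if self.probabilities is not None:
            return np.asarray(self.probabilities, dtype=float)
        return np.ones(self.n_levels) / self.n_levels


@dataclass(frozen=True)
class SimSpec:
    """Shape and distributional knobs of a simulated longitudinal extract."""

    n_patients: int = 226
    n_variables: int = 4
    n_visits: int = 5
    rank: int = 3
    noise_sd: float = 0.1
    cross_correlation: float = 0.5
    ar_coefficient: float = 0.6
    patient_effect_share: float = 0.7
    mcar_rate: float = 0.0
    visit_range: tuple[int, int] | None = None  # irregular visits when set
    variable_means: tuple[float, ...] | None = None
    variable_sds: tuple[float, ...] | None = None
    categoricals: tuple[CategoricalSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("AR coefficient must lie in (-1, 1)")
        if not 0.0 <= self.mcar_rate < 1.0:
            raise ValueError("MCAR rate must lie in [0, 1)")
        if not 0.0 < self.patient_effect_share <= 1.0:
            raise ValueError("patient_effect_share must lie in (0, 1]")
        if abs(self.cross_correlation) > self.patient_effect_share:
            raise ValueError(
                "requested |cross_correlation| cannot exceed patient_effect_share"
            )
        if self.visit_range is not None:
            lo, hi = self.visit_range
            if not 1 <= lo <= hi:
                raise ValueError("visit_range must satisfy 1 <= lo <= hi")
        for tpl, label in ((self.variable_means, "means"), (self.variable_sds, "sds")):
            if tpl is not None and len(tpl) != self.n_variables:
                raise ValueError(f"variable_{label} must have n_variables entries")


def make_lowrank(spec: SimSpec) -> tuple[Tensor3, KruskalModel]:
    """Random Kruskal tensor plus additive Gaussian noise; returns the truth."""
    I, J, K, R = spec.n_patients, spec.n_variables, spec.n_visits, spec.rank
    if R > min(I * J, I * K, J * K):
        raise ValueError(f"rank {R} exceeds min(IJ, IK, JK)")
    rng = np.random.default_rng(spec.seed)
    factors = tuple(rng.standard_normal((n, R)) for n in (I, J, K))
    truth = KruskalModel(factors=factors, loss_name="gaussian")
    values = reconstruct(truth) + rng.normal(0.0, spec.noise_sd, (I, J, K))
    mask = np.ones((I, J, K))
    if spec.mcar_rate > 0:
        mask = (rng.uniform(size=(I, J, K)) >= spec.mcar_rate).astype(float)
        values = np.where(mask > 0, values, np.nan)
    return Tensor3(values, mask), truth


def _exchangeable_chol(J: int, rho: float) -> np.ndarray:
    if J == 0:
        return np.zeros((0, 0))
    corr = np.full((J, J), rho)
    np.fill_diagonal(corr, 1.0)
    return np.linalg.cholesky(corr)


def make_ehr_like(spec: SimSpec) -> LongTable:
    """Longitudinal lab-panel-like long table per the module equations."""
    rng = np.random.default_rng(spec.seed)
    I, J, K = spec.n_patients, spec.n_variables, spec.n_visits
    tau = spec.patient_effect_share
    rho_g = spec.cross_correlation / tau

    mu = np.asarray(spec.variable_means if spec.variable_means else np.zeros(J), float)
    sd = np.asarray(spec.variable_sds if spec.variable_sds else np.ones(J), float)

    g = rng.standard_normal((I, J)) @ _exchangeable_chol(J, rho_g).T
    e = np.empty((I, J, K))
    e[:, :, 0] = rng.standard_normal((I, J))
    phi = spec.ar_coefficient
    for k in range(1, K):
        e[:, :, k] = phi * e[:, :, k - 1] + np.sqrt(1 - phi**2) * rng.standard_normal(
            (I, J)
        )
    z = np.sqrt(tau) * g[:, :, None] + np.sqrt(1 - tau) * e
    values = mu[None, :, None] + sd[None, :, None] * z
    mask = np.ones((I, J, K))

    # irregular visit counts: pad cells beyond each patient's v_i with mask 0
    if spec.visit_range is not None:
        lo, hi = spec.visit_range
        v = rng.integers(lo, hi + 1, size=I)
        for i in range(I):
            mask[i, :, v[i] :] = 0.0
    # MCAR on the remaining observed cells
    if spec.mcar_rate > 0:
        mask *= (rng.uniform(size=(I, J, K)) >= spec.mcar_rate).astype(float)

    patients = [f"p{i + 1:04d}" for i in range(I)]
    variables = [f"lab{j + 1}" for j in range(J)]
    frames = []
    obs = mask > 0.5
    ii, jj, kk = np.where(obs)
    frames.append(
        pd.DataFrame(
            {
                "patient_id": np.asarray(patients)[ii],
                "variable": np.asarray(variables)[jj],
                "visit": kk + 1,
                "value": values[ii, jj, kk],
            }
        )
    )
    # missing continuous cells kept as empty-value records so the
    # missingness pattern survives the CSV round trip
    mi, mj, mk = np.where(~obs)
    if mi.size:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.asarray(patients)[mi],
                    "variable": np.asarray(variables)[mj],
                    "visit": mk + 1,
                    "value": np.nan,
                }
            )
        )

    for cat in spec.categoricals:
        p = cat.marginals()
        home = rng.choice(cat.n_levels, size=I, p=p)
        codes = np.empty((I, K), dtype=int)
        for k in range(K):
            stay = rng.uniform(size=I) < cat.persistence
            redraw = rng.choice(cat.n_levels, size=I, p=p)
            codes[:, k] = np.where(stay, home, redraw)
        ii, kk = np.meshgrid(range(I), range(K), indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.asarray(patients)[ii.ravel()],
                    "variable": cat.name,
                    "visit": kk.ravel() + 1,
                    "value": codes.ravel() + 1.0,  # 1-based level codes
                }
            )
        )

    return LongTable(pd.concat(frames, ignore_index=True))


def dense_lab_profile(seed: int = 0) -> SimSpec:
    """226 patients x 4 lab-like variables x 5 visits, fully observed."""
    return SimSpec(
        n_patients=226,
        n_variables=4,
        n_visits=5,
        cross_correlation=0.5,
        ar_coefficient=0.6,
        variable_means=(1.6, 4.2, 138.0, 32.0),
        variable_sds=(1.6, 0.6, 6.5, 5.8),
        seed=seed,
    )


def sparse_lab_profile(seed: int = 0) -> SimSpec:
    """226 x 4 x 36 panel with 21% of the cells missing completely at random."""
    return SimSpec(
        n_patients=226,
        n_variables=4,
        n_visits=36,
        cross_correlation=0.5,
        ar_coefficient=0.6,
        mcar_rate=0.21,
        variable_means=(1.6, 4.2, 138.0, 32.0),
        variable_sds=(1.6, 0.6, 6.5, 5.8),
        seed=seed,
    )


def irregular_lab_profile(seed: int = 0) -> SimSpec:
    """226 x 4 panel with per-patient visit counts uniform on {3..10}."""
    return SimSpec(
        n_patients=226,
        n_variables=4,
        n_visits=10,
        cross_correlation=0.5,
        ar_coefficient=0.6,
        visit_range=(3, 10),
        variable_means=(1.6, 4.2, 138.0, 32.0),
        variable_sds=(1.6, 0.6, 6.5, 5.8),
        seed=seed,
    )


def categorical_admissions_profile(seed: int = 0) -> SimSpec:
    """246 patients x 2 categorical admission-style features x 5 visits."""
    return SimSpec(
        n_patients=246,
        n_variables=0,
        n_visits=5,
        cross_correlation=0.0,
        patient_effect_share=0.7,
        categoricals=(
            CategoricalSpec("admission_type", 4, (0.45, 0.3, 0.2, 0.05)),
            CategoricalSpec("admission_location", 6, (0.3, 0.25, 0.2, 0.1, 0.1, 0.05)),
        ),
        seed=seed,
    )
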