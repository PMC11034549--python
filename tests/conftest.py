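import numpy as np
import pandas as pd
import pytest

from gcpsynth import (
    FitOptions,
    KruskalModel,
    LatentTable,
    LongTable,
    SimSpec,
    Tensor3,
    make_lowrank,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tensor(rng):
    """Random dense 3x4x2 tensor."""
    return Tensor3(rng.standard_normal((3, 4, 2)))


@pytest.fixture
def masked_tensor(rng):
    """4x3x2 tensor with ~30% of cells masked out."""
    values = rng.standard_normal((4, 3, 2))
    mask = (rng.uniform(size=values.shape) >= 0.3).astype(float)
    values = np.where(mask > 0, values, np.nan)
    return Tensor3(values, mask)


@pytest.fixture
def random_model(rng):
    """Random rank-2 Kruskal model on a 4x3x2 grid."""
    return KruskalModel(
        factors=tuple(rng.standard_normal((n, 2)) * 0.6 for n in (4, 3, 2))
    )


@pytest.fixture
def rank2_tensor():
    """Noiseless rank-2 ground-truth tensor (20x5x6) plus its true model."""
    return make_lowrank(
        SimSpec(n_patients=20, n_variables=5, n_visits=6, rank=2, noise_sd=0.0, seed=7)
    )


@pytest.fixture
def fast_fit_options():
    return FitOptions(max_iterations=800, random_seed=0, restarts=2)


@pytest.fixture
def bivariate_latent(rng):
    """Latent table with two columns at Pearson correlation ~0.8."""
    n = 400
    z = rng.standard_normal((n, 2))
    a1 = z[:, 0]
    a2 = 0.8 * z[:, 0] + np.sqrt(1 - 0.8**2) * z[:, 1]
    return LatentTable(
        pd.DataFrame({"a1": a1, "a2": a2}), provenance_loss="gaussian"
    )


@pytest.fixture
def toy_long_table():
    """Fully observed 2 patients x 2 variables x 2 visits long table."""
    rows = []
    for p in ("pA", "pB"):
        for v in ("creat", "sodium"):
            for k in (1, 2):
                rows.append((p, v, k, float(len(rows) + 1)))
    return LongTable(
        pd.DataFrame(rows, columns=["patient_id", "variable", "visit", "value"])
    )
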