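"""GCP fitting: masked objective, gradients, recovery, rank selection."""

import numpy as np
import pytest

from gcpsynth import (
    FitOptions,
    KruskalModel,
    LossSpec,
    SimSpec,
    Tensor3,
    fit_gcp,
    fit_score,
    gradient,
    loss_eval,
    make_lowrank,
    objective,
    reconstruct,
    select_rank,
)


def brute_force_objective(x: Tensor3, model: KruskalModel, spec: LossSpec) -> float:
    m = reconstruct(model)
    total = 0.0
    for idx in np.ndindex(*x.shape):
        if x.mask[idx] > 0:
            total += loss_eval(spec, float(x.values[idx]), float(m[idx]))[0]
    return total


class TestObjective:
    def test_exact_reconstruction_scores_zero(self, rank2_tensor):
        t, truth = rank2_tensor
        assert objective(t, truth, LossSpec("gaussian")) == pytest.approx(0.0, abs=1e-18)

    def test_masked_cells_contribute_nothing(self, masked_tensor, random_model):
        spec = LossSpec("gaussian")
        f1 = objective(masked_tensor, random_model, spec)
        other = masked_tensor.copy()
        other.values = np.where(other.observed, other.values, -123.0)
        assert objective(other, random_model, spec) == pytest.approx(f1, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        values = rng.standard_normal((3, 3, 2))
        mask = (rng.uniform(size=values.shape) >= 0.3).astype(float)
        t = Tensor3(np.where(mask > 0, values, np.nan), mask)
        model = KruskalModel(
            factors=tuple(rng.standard_normal((n, 2)) * 0.5 for n in (3, 3, 2))
        )
        spec = LossSpec("gaussian")
        assert objective(t, model, spec) == pytest.approx(
            brute_force_objective(t, model, spec), rel=1e-12
        )


class TestGradient:
    def test_zero_at_exact_gaussian_optimum(self, rank2_tensor):
        t, truth = rank2_tensor
        grads = gradient(t, truth, LossSpec("gaussian"))
        assert max(np.abs(g).max() for g in grads) <= 1e-10

    def test_all_zero_mask_gives_zero_gradient(self, rng, random_model):
        values = np.full((4, 3, 2), np.nan)
        t = Tensor3(values, np.zeros((4, 3, 2)))
        grads = gradient(t, random_model, LossSpec("gaussian"))
        assert all(np.array_equal(g, np.zeros_like(g)) for g in grads)

    @pytest.mark.parametrize(
        "name", ["gaussian", "poisson_log", "gamma", "beta_divergence"]
    )
    def test_matches_finite_differences_all_losses(self, name, rng):
        spec = LossSpec(name, offset=1e-8)
        values = rng.standard_normal((4, 3, 2))
        if spec.requires_nonnegative_data:
            values = np.abs(values) + 0.1
        mask = (rng.uniform(size=values.shape) >= 0.3).astype(float)
        t = Tensor3(np.where(mask > 0, values, np.nan), mask)
        factors = tuple(rng.uniform(0.2, 0.8, (n, 2)) for n in (4, 3, 2))
        model = KruskalModel(factors=factors)
        grads = gradient(t, model, spec)
        h = 1e-6
        for fi in range(3):
            for pos in np.ndindex(*factors[fi].shape):
                pert = [f.copy() for f in factors]
                pert[fi][pos] += h
                fp = objective(t, KruskalModel(factors=tuple(pert)), spec)
                pert[fi][pos] -= 2 * h
                fm = objective(t, KruskalModel(factors=tuple(pert)), spec)
                fd = (fp - fm) / (2 * h)
                assert grads[fi][pos] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestFitGcp:
    def test_noiseless_rank2_recovery(self, rank2_tensor, fast_fit_options):
        t, _ = rank2_tensor
        model = fit_gcp(t, 2, LossSpec("gaussian"), fast_fit_options)
        assert fit_score(t, reconstruct(model)) >= 0.999

    def test_masked_fit_imputes_heldout_cells(self, fast_fit_options):
        t, truth = make_lowrank(
            SimSpec(n_patients=20, n_variables=5, n_visits=6, rank=2, noise_sd=0.0, seed=11)
        )
        rng = np.random.default_rng(4)
        mask = (rng.uniform(size=t.shape) >= 0.2).astype(float)
        masked = Tensor3(np.where(mask > 0, t.values, np.nan), mask)
        model = fit_gcp(masked, 2, LossSpec("gaussian"), fast_fit_options)
        m = reconstruct(model)
        assert fit_score(masked, m) >= 0.995
        held = mask == 0
        rmse = np.sqrt(np.mean((m[held] - t.values[held]) ** 2))
        assert rmse <= 0.05 * t.values.std()

    def test_rank1_tensor_recovered_by_rank1_fit(self, rng, fast_fit_options):
        t, _ = make_lowrank(
            SimSpec(n_patients=10, n_variables=4, n_visits=5, rank=1, noise_sd=0.0, seed=3)
        )
        model = fit_gcp(t, 1, LossSpec("gaussian"), fast_fit_options)
        assert fit_score(t, reconstruct(model)) >= 0.9999

    def test_deterministic_given_seed(self, rank2_tensor):
        t, _ = rank2_tensor
        opts = FitOptions(max_iterations=150, random_seed=5, restarts=1)
        m1 = fit_gcp(t, 2, LossSpec("gaussian"), opts)
        m2 = fit_gcp(t, 2, LossSpec("gaussian"), opts)
        for f1, f2 in zip(m1.factors, m2.factors):
            assert np.array_equal(f1, f2)

    def test_fitted_model_unchanged_by_masked_cell_values(self, fast_fit_options):
        t, _ = make_lowrank(
            SimSpec(n_patients=8, n_variables=4, n_visits=5, rank=2, noise_sd=0.05,
                    mcar_rate=0.25, seed=9)
        )
        m1 = fit_gcp(t, 2, LossSpec("gaussian"), fast_fit_options)
        polluted = t.copy()
        polluted.values = np.where(polluted.observed, polluted.values, 777.0)
        m2 = fit_gcp(polluted, 2, LossSpec("gaussian"), fast_fit_options)
        for f1, f2 in zip(m1.factors, m2.factors):
            assert np.array_equal(f1, f2)

    def test_nonnegative_fit_yields_nonnegative_factors(self, fast_fit_options):
        rng = np.random.default_rng(2)
        factors = tuple(rng.uniform(0.2, 1.0, (n, 2)) for n in (10, 4, 5))
        t = Tensor3(np.einsum("ir,jr,kr->ijk", *factors))
        opts = FitOptions(max_iterations=800, random_seed=0, nonnegative=True)
        model = fit_gcp(t, 2, LossSpec("gaussian"), opts)
        assert all((f >= 0).all() for f in model.factors)
        assert fit_score(t, reconstruct(model)) >= 0.99

    def test_adam_optimizer_reaches_reasonable_fit(self, rank2_tensor):
        t, _ = rank2_tensor
        opts = FitOptions(
            max_iterations=2000, random_seed=0, restarts=1, optimizer="adam",
            adam_learning_rate=0.05,
        )
        model = fit_gcp(t, 2, LossSpec("gaussian"), opts)
        assert fit_score(t, reconstruct(model)) >= 0.95


class TestSelectRank:
    def test_recovers_true_rank_three(self, fast_fit_options):
        t, _ = make_lowrank(
            SimSpec(n_patients=20, n_variables=6, n_visits=10, rank=3, noise_sd=0.0, seed=3)
        )
        r, diag = select_rank(t, [1, 2, 3, 4, 5, 6], LossSpec("gaussian"), fast_fit_options)
        assert r == 3
        assert diag.ranks == [1, 2, 3, 4, 5, 6]

    def test_single_candidate_returned(self, rank2_tensor, fast_fit_options):
        t, _ = rank2_tensor
        r, diag = select_rank(t, [1], LossSpec("gaussian"), fast_fit_options)
        assert r == 1
        assert len(diag.objectives) == 1

    def test_objectives_nonincreasing_in_rank(self, fast_fit_options):
        t, _ = make_lowrank(
            SimSpec(n_patients=12, n_variables=5, n_visits=6, rank=2, noise_sd=0.2, seed=5)
        )
        _, diag = select_rank(t, [1, 2, 3, 4], LossSpec("gaussian"), fast_fit_options)
        tol = 1e-6 * abs(diag.objectives[0])
        assert all(
            diag.objectives[i + 1] <= diag.objectives[i] + tol
            for i in range(len(diag.objectives) - 1)
        )

    def test_empty_candidates_rejected(self, rank2_tensor):
        with pytest.raises(ValueError):
            select_rank(rank2_tensor[0], [])

    def test_rank_beyond_bound_rejected(self, rng):
        t = Tensor3(rng.standard_normal((2, 2, 2)))
        with pytest.raises(ValueError):
            select_rank(t, [1, 5])
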