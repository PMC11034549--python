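"""Tensor algebra: Kruskal reconstruction, unfolding, standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcpsynth import (
    DegenerateVariableError,
    KruskalModel,
    InvalidModelError,
    StandardizationTransform,
    Tensor3,
    UndefinedScoreError,
    destandardize,
    fit_score,
    fold,
    khatri_rao,
    reconstruct,
    standardize,
    unfold,
)


def brute_force_reconstruct(weights, a, b, c):
    """Triple-nested-loop oracle for the Kruskal full tensor."""
    I, R = a.shape
    J, K = b.shape[0], c.shape[0]
    out = np.zeros((I, J, K))
    for i in range(I):
        for j in range(J):
            for k in range(K):
                for r in range(R):
                    out[i, j, k] += weights[r] * a[i, r] * b[j, r] * c[k, r]
    return out


class TestReconstruct:
    def test_all_ones_factors_give_all_ones_tensor(self):
        ones = np.ones((2, 1))
        m = KruskalModel(factors=(ones, ones, ones))
        assert np.array_equal(reconstruct(m), np.ones((2, 2, 2)))

    def test_zero_weight_gives_zero_tensor(self, rng):
        m = KruskalModel(
            factors=tuple(rng.standard_normal((n, 1)) for n in (3, 2, 2)),
            weights=np.array([0.0]),
        )
        assert np.array_equal(reconstruct(m), np.zeros((3, 2, 2)))

    def test_matches_triple_loop_oracle_exactly(self, rng):
        a, b, c = (rng.integers(-3, 4, (n, 2)).astype(float) for n in (3, 4, 2))
        lam = np.array([1.0, 2.0])
        m = KruskalModel(factors=(a, b, c), weights=lam)
        assert np.array_equal(reconstruct(m), brute_force_reconstruct(lam, a, b, c))

    def test_oracle_agreement_on_random_instances(self, rng):
        for _ in range(5):
            shape = rng.integers(2, 7, size=3)
            r = int(rng.integers(1, 5))
            factors = tuple(rng.standard_normal((n, r)) for n in shape)
            lam = rng.uniform(0.5, 2.0, r)
            m = KruskalModel(factors=factors, weights=lam)
            expected = brute_force_reconstruct(lam, *factors)
            assert np.allclose(reconstruct(m), expected, rtol=1e-12, atol=1e-12)

    def test_factor_shape_mismatch_rejected(self, rng):
        with pytest.raises(InvalidModelError):
            KruskalModel(
                factors=(
                    rng.standard_normal((3, 2)),
                    rng.standard_normal((4, 3)),
                    rng.standard_normal((2, 2)),
                )
            )


class TestUnfold:
    def test_mode1_of_ones(self):
        assert np.array_equal(unfold(np.ones((2, 2, 2)), 1), np.ones((2, 4)))

    @pytest.mark.parametrize("mode", [1, 2, 3])
    def test_fold_unfold_roundtrip(self, rng, mode):
        t = rng.standard_normal((3, 4, 5))
        assert np.array_equal(fold(unfold(t, mode), mode, t.shape), t)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            unfold(np.ones((2, 2, 2)), 4)

    def test_kruskal_unfolding_identity_all_modes(self, rng):
        a, b, c = (rng.standard_normal((n, 3)) for n in (3, 4, 2))
        lam = rng.uniform(0.5, 2.0, 3)
        t = reconstruct(KruskalModel(factors=(a, b, c), weights=lam))
        assert np.allclose(unfold(t, 1), (a * lam) @ khatri_rao(c, b).T, atol=1e-12)
        assert np.allclose(unfold(t, 2), (b * lam) @ khatri_rao(c, a).T, atol=1e-12)
        assert np.allclose(unfold(t, 3), (c * lam) @ khatri_rao(b, a).T, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        shape=st.tuples(*[st.integers(2, 5)] * 3),
        mode=st.integers(1, 3),
        seed=st.integers(0, 10_000),
    )
    def test_fold_unfold_roundtrip_property(self, shape, mode, seed):
        t = np.random.default_rng(seed).standard_normal(shape)
        assert np.array_equal(fold(unfold(t, mode), mode, shape), t)


class TestKhatriRao:
    def test_row_vectors_give_elementwise_product(self):
        a = np.array([[1.0, 2.0, 3.0]])
        b = np.array([[4.0, 5.0, 6.0]])
        assert np.array_equal(khatri_rao(a, b), np.array([[4.0, 10.0, 18.0]]))

    def test_identity_with_identity(self):
        eye = np.eye(2)
        expected = np.zeros((4, 2))
        # column r is the Kronecker product of the r-th columns
        for r in range(2):
            expected[:, r] = np.kron(eye[:, r], eye[:, r])
        assert np.array_equal(khatri_rao(eye, eye), expected)

    def test_all_ones(self):
        assert np.array_equal(khatri_rao(np.ones((2, 3)), np.ones((2, 3))), np.ones((4, 3)))

    def test_column_mismatch_rejected(self):
        with pytest.raises(ValueError):
            khatri_rao(np.ones((2, 3)), np.ones((2, 2)))


class TestFitScore:
    def test_perfect_fit_is_one(self, small_tensor):
        assert fit_score(small_tensor, small_tensor.values) == pytest.approx(1.0)

    def test_zero_model_scores_zero(self, small_tensor):
        m = np.zeros(small_tensor.shape)
        assert fit_score(small_tensor, m) == pytest.approx(0.0)

    def test_matches_loop_oracle_under_mask(self, masked_tensor, rng):
        m = rng.standard_normal(masked_tensor.shape)
        num = den = 0.0
        for idx in np.ndindex(*masked_tensor.shape):
            if masked_tensor.mask[idx] > 0:
                num += (masked_tensor.values[idx] - m[idx]) ** 2
                den += masked_tensor.values[idx] ** 2
        expected = 1.0 - np.sqrt(num) / np.sqrt(den)
        assert fit_score(masked_tensor, m) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_masked_cell_values(self, masked_tensor, rng):
        m = rng.standard_normal(masked_tensor.shape)
        s1 = fit_score(masked_tensor, m)
        other = masked_tensor.copy()
        other.values = np.where(other.observed, other.values, 1e6)
        assert fit_score(other, m) == pytest.approx(s1, abs=1e-12)

    def test_all_zero_observed_raises(self):
        t = Tensor3(np.zeros((2, 2, 2)))
        with pytest.raises(UndefinedScoreError):
            fit_score(t, np.ones((2, 2, 2)))


class TestStandardization:
    def test_roundtrip_on_observed_entries(self, masked_tensor):
        std, tf = standardize(masked_tensor)
        back = destandardize(std, tf)
        obs = masked_tensor.observed
        assert np.allclose(back.values[obs], masked_tensor.values[obs], atol=1e-12)
        assert np.array_equal(back.mask, masked_tensor.mask)

    def test_standardized_slices_have_zero_mean_unit_sd(self, masked_tensor):
        std, _ = standardize(masked_tensor)
        for j in range(masked_tensor.shape[1]):
            vals = std.values[:, j, :][std.observed[:, j, :]]
            assert vals.mean() == pytest.approx(0.0, abs=1e-12)
            assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_on_standardized_input(self, small_tensor):
        std, _ = standardize(small_tensor)
        std2, _ = standardize(std)
        assert np.allclose(std2.values, std.values, atol=1e-12)

    def test_two_value_variable_hand_oracle(self):
        # variable with observed values {2, 4}: mean 3, sample sd sqrt(2)
        values = np.array([[[2.0]], [[4.0]]])
        t = Tensor3(values)
        _, tf = standardize(t)
        assert tf.location[0] == pytest.approx(3.0)
        assert tf.scale[0] == pytest.approx(np.sqrt(2.0))

    def test_masked_entries_do_not_influence_statistics(self, rng):
        values = rng.standard_normal((5, 2, 3))
        mask = np.ones_like(values)
        mask[0, 0, 0] = 0.0
        polluted = np.where(mask > 0, values, 1e9)
        _, tf1 = standardize(Tensor3(polluted, mask))
        clean = np.where(mask > 0, values, np.nan)
        _, tf2 = standardize(Tensor3(clean, mask))
        assert np.allclose(tf1.location, tf2.location)
        assert np.allclose(tf1.scale, tf2.scale)

    def test_constant_variable_named_in_error(self):
        values = np.ones((3, 2, 2))
        values[:, 1, :] = np.arange(6).reshape(3, 2)
        t = Tensor3(values, variable_names=["flat", "ok"])
        with pytest.raises(DegenerateVariableError, match="flat"):
            standardize(t)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(DegenerateVariableError):
            StandardizationTransform(np.zeros(2), np.array([1.0, 0.0]))


class TestTensor3Validation:
    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Tensor3(np.ones((2, 2, 2)), np.ones((2, 2, 3)))

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError):
            Tensor3(np.ones((2, 2, 2)), np.full((2, 2, 2), 0.5))

    def test_label_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Tensor3(np.ones((2, 2, 2)), patient_ids=["only-one"])
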