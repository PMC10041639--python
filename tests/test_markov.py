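"""Kernel construction and Markov transition matrix tests.

The independent oracle used throughout is a separately coded standard
anisotropic diffusion map (plain Gaussian kernel, plain density
normalisation, row normalisation) that never touches the reweighting code
path.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rwdiffmap import (
    DegenerateSubspaceError,
    KernelMatrix,
    ValidationError,
    WeightedDataset,
    density_estimate,
    estimate_scale,
    gaussian_kernel,
    reweighted_kernel,
    reweighting_factor,
    transition_matrix,
)
from conftest import random_weighted_dataset


def anisotropic_diffusion_map_oracle(x: np.ndarray, epsilon: float) -> np.ndarray:
    """Standard (unweighted) anisotropic diffusion map, coded independently."""
    n = x.shape[0]
    g = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            g[i, j] = np.exp(-np.sum((x[i] - x[j]) ** 2) / (2 * epsilon**2))
    rho = g.sum(axis=1)
    k = g / np.sqrt(np.outer(rho, rho))
    return k / k.sum(axis=1)[:, None]


class TestEstimateScale:
    def test_median_of_collinear_points(self):
        ds = WeightedDataset(np.array([[0.0], [2.0], [4.0]]))
        # pairwise distances {2, 2, 4}: median 2
        assert estimate_scale(ds) == 2.0

    def test_identical_samples_rejected(self):
        ds = WeightedDataset(np.ones((5, 2)))
        with pytest.raises(DegenerateSubspaceError):
            estimate_scale(ds)

    def test_degenerate_subspace_named(self):
        samples = np.column_stack([np.zeros(4), np.arange(4.0)])
        ds = WeightedDataset(samples)
        with pytest.raises(DegenerateSubspaceError) as exc:
            estimate_scale(ds, [0])
        assert exc.value.subset == (0,)
        assert estimate_scale(ds, [1]) > 0  # other column is fine

    def test_matches_brute_force_enumeration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, -1.0], [0.5, 3.0], [-1.0, 1.0]])
        dists = [
            np.linalg.norm(pts[i] - pts[j])
            for i, j in itertools.combinations(range(5), 2)
        ]
        assert estimate_scale(WeightedDataset(pts)) == pytest.approx(
            np.median(dists), abs=0
        )

    def test_subsampled_median_is_seeded_and_close(self, rng):
        ds = WeightedDataset(rng.normal(size=(200, 3)))
        full = estimate_scale(ds)
        sub1 = estimate_scale(ds, max_pairs=5000, seed=0)
        sub2 = estimate_scale(ds, max_pairs=5000, seed=0)
        assert sub1 == sub2
        assert sub1 == pytest.approx(full, rel=0.1)


class TestGaussianKernel:
    def test_zero_distance_is_one(self):
        assert gaussian_kernel([1.0, 2.0], [1.0, 2.0], 0.5) == 1.0

    def test_distance_eps_sqrt2_gives_inverse_e(self):
        eps = 0.7
        xk = np.zeros(3)
        xl = np.array([eps * np.sqrt(2.0), 0.0, 0.0])
        assert gaussian_kernel(xk, xl, eps) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_matches_direct_formula(self, rng):
        xk, xl = rng.normal(size=(2, 3))
        eps = 0.9
        expected = np.exp(-np.sum((xk - xl) ** 2) / (2 * eps**2))
        assert gaussian_kernel(xk, xl, eps) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_epsilon_rejected(self, bad):
        with pytest.raises(ValidationError):
            gaussian_kernel([0.0], [1.0], bad)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_kernel([np.nan], [1.0], 1.0)


class TestDensityEstimate:
    def test_far_apart_samples_have_unit_density(self):
        ds = WeightedDataset(np.array([[0.0], [1e6], [2e6]]))
        rho = density_estimate(ds, epsilon=1.0)
        np.testing.assert_allclose(rho, 1.0, atol=1e-12)

    def test_matches_kernel_row_sums(self, rng):
        pts = rng.normal(size=(4, 2))
        eps = 1.3
        expected = [
            sum(gaussian_kernel(pts[k], pts[l], eps) for l in range(4))
            for k in range(4)
        ]
        rho = density_estimate(WeightedDataset(pts), epsilon=eps)
        np.testing.assert_allclose(rho, expected, rtol=1e-12)

    def test_self_term_bounds_density_below(self, rng):
        ds = WeightedDataset(rng.normal(size=(30, 3)))
        assert np.all(density_estimate(ds) >= 1.0)


class TestReweightingFactor:
    def test_unit_weights_give_one(self):
        assert reweighting_factor(1.0, 1.0) == 1.0

    @given(
        wk=st.floats(0.01, 100.0),
        wl=st.floats(0.01, 100.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetric(self, wk, wl):
        assert reweighting_factor(wk, wl) == reweighting_factor(wl, wk)

    @pytest.mark.parametrize("bad", [0.0, -2.0, np.inf])
    def test_invalid_weight_rejected(self, bad):
        with pytest.raises(ValidationError):
            reweighting_factor(bad, 1.0)


class TestReweightedKernel:
    def test_unit_weights_reduce_to_standard_anisotropic_map(self, rng):
        """At unit weights the full pipeline equals the independent oracle."""
        for _ in range(10):
            x = rng.normal(size=(rng.integers(5, 25), rng.integers(1, 5)))
            ds = WeightedDataset(x)
            eps = estimate_scale(ds)
            m = transition_matrix(reweighted_kernel(ds, epsilon=eps))
            oracle = anisotropic_diffusion_map_oracle(x, eps)
            np.testing.assert_allclose(m.values, oracle, atol=1e-12)

    def test_kernel_is_symmetric_positive(self, weighted_dataset):
        k = reweighted_kernel(weighted_dataset)
        np.testing.assert_allclose(k.values, k.values.T, atol=1e-15)
        assert np.all(k.values > 0)
        assert np.all(np.diag(k.values) > 0)

    def test_global_weight_scaling_cancels_in_m(self, weighted_dataset):
        eps = estimate_scale(weighted_dataset)
        m1 = transition_matrix(reweighted_kernel(weighted_dataset, epsilon=eps))
        for c in (10.0, 1e-3, 7.5):
            scaled = weighted_dataset.with_weights(c * weighted_dataset.weights)
            m2 = transition_matrix(reweighted_kernel(scaled, epsilon=eps))
            np.testing.assert_allclose(m1.values, m2.values, atol=1e-10)


class TestTransitionMatrix:
    def test_hand_written_kernel_rows(self):
        k = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.1], [0.25, 0.1, 1.0]])
        km = KernelMatrix(values=k, epsilon=1.0, density=k.sum(1))
        m = transition_matrix(km).values
        expected = k / k.sum(axis=1)[:, None]
        np.testing.assert_allclose(m, expected, atol=0)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_kernel_scale_invariance(self):
        k = np.array([[1.0, 0.3], [0.3, 1.0]])
        km1 = KernelMatrix(k, 1.0, k.sum(1))
        km2 = KernelMatrix(5.0 * k, 1.0, 5.0 * k.sum(1))
        np.testing.assert_allclose(
            transition_matrix(km1).values, transition_matrix(km2).values, atol=1e-15
        )

    def test_zero_row_rejected(self):
        k = np.array([[0.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValidationError):
            transition_matrix(KernelMatrix(k, 1.0, k.sum(1)))

    def test_permutation_equivariance(self, rng):
        ds = random_weighted_dataset(rng, n_samples=15, n_variables=3)
        eps = estimate_scale(ds)
        m = transition_matrix(reweighted_kernel(ds, epsilon=eps)).values
        perm = rng.permutation(15)
        ds_p = WeightedDataset(ds.samples[perm], ds.weights[perm], ds.names)
        m_p = transition_matrix(reweighted_kernel(ds_p, epsilon=eps)).values
        np.testing.assert_allclose(m_p, m[np.ix_(perm, perm)], atol=1e-12)


@given(seed=st.integers(0, 10_000))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_rows_always_sum_to_one(seed):
    """Row-stochasticity holds for arbitrary random weighted data sets."""
    rng = np.random.default_rng(seed)
    ds = random_weighted_dataset(rng)
    m = transition_matrix(reweighted_kernel(ds)).values
    np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(m >= 0) and np.all(m <= 1 + 1e-15)


class TestWeightedDataset:
    def test_rejects_nonpositive_weights(self, rng):
        with pytest.raises(ValidationError):
            WeightedDataset(rng.normal(size=(5, 2)), np.array([1, 1, 0, 1, 1.0]))

    def test_rejects_nonfinite_samples(self):
        bad = np.ones((4, 2))
        bad[2, 1] = np.nan
        with pytest.raises(ValidationError):
            WeightedDataset(bad)

    def test_rejects_too_few_samples(self):
        with pytest.raises(ValidationError):
            WeightedDataset(np.ones((2, 2)))

    def test_subset_validation(self, small_dataset):
        with pytest.raises(ValidationError):
            small_dataset.resolve_subset([0, 0])
        with pytest.raises(ValidationError):
            small_dataset.resolve_subset([3])
        with pytest.raises(ValidationError):
            small_dataset.resolve_subset([])
        assert small_dataset.resolve_subset([2, 0]) == (0, 2)

    def test_unit_weights_flag(self, small_dataset, weighted_dataset):
        assert small_dataset.is_unbiased
        assert not weighted_dataset.is_unbiased
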