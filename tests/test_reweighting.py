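import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinpred.reweighting import (
    BinSpec,
    WeightVector,
    bin_labels,
    cbw_weights,
    compute_weights,
    csw_weights,
    dmw_weights,
    effective_number,
    gaussian_kernel,
    lds_effective_density,
    lds_weights,
    rescale_mean_one,
    weights_from_density,
)


class TestDMW:
    def test_rule_application(self):
        wv = dmw_weights(np.array([1.0, 5.0]), multiplier=10)
        np.testing.assert_array_equal(wv.weights, [1.0, 10.0])

    def test_all_below_threshold_uniform(self):
        wv = dmw_weights(np.array([0.5, 3.9, -2.0]), multiplier=10)
        np.testing.assert_array_equal(wv.weights, np.ones(3))

    def test_normalized_sum_equals_n(self):
        wv = dmw_weights(np.array([1.0, 5.0]), multiplier=10, normalize=True)
        np.testing.assert_allclose(wv.weights, [2 / 11, 20 / 11])
        assert wv.weights.sum() == pytest.approx(2.0)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            dmw_weights(np.array([1.0]), multiplier=0)


class TestBinning:
    def test_right_open_rule_with_max_in_last_bin(self):
        index, counts = bin_labels(np.array([0.0, 0.5, 1.0]), BinSpec(n_bins=2))
        np.testing.assert_array_equal(index, [0, 1, 1])
        np.testing.assert_array_equal(counts, [1, 2])

    def test_degenerate_constant_labels(self):
        index, counts = bin_labels(np.full(5, 3.3), BinSpec(n_bins=4))
        np.testing.assert_array_equal(index, np.zeros(5))
        assert counts[0] == 5 and counts.sum() == 5

    @given(st.integers(1, 200), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_counts_conserved(self, n, seed):
        labels = np.random.default_rng(seed).normal(size=n)
        index, counts = bin_labels(labels, BinSpec(n_bins=131))
        assert counts.sum() == n
        assert index.min() >= 0 and index.max() < 131


class TestCSW:
    @pytest.mark.parametrize(
        "variant,expected",
        [("plain", [1.0, 0.25]), ("root", [1.0, 0.5]), ("square", [1.0, 0.0625])],
    )
    def test_three_formulas(self, variant, expected):
        counts = np.array([1, 4])
        index = np.array([0, 1])
        wv = csw_weights(counts, index, variant)
        np.testing.assert_allclose(wv.weights, expected)

    def test_uniform_counts_give_uniform_weights(self):
        counts = np.full(4, 3)
        index = np.repeat(np.arange(4), 3)
        for variant in ("plain", "root", "square"):
            w = csw_weights(counts, index, variant).weights
            assert np.allclose(w, w[0])

    def test_singleton_bins_give_unit_weights(self):
        counts = np.ones(131, dtype=int)
        index = np.arange(131)
        np.testing.assert_array_equal(csw_weights(counts, index).weights, np.ones(131))

    def test_empty_bin_inconsistency(self):
        with pytest.raises(ValueError):
            csw_weights(np.array([0, 2]), np.array([0, 1]))


class TestCBW:
    def test_singleton_bin_weight_one(self):
        for beta in (0.0, 0.5, 0.9, 0.999):
            wv = cbw_weights(np.array([1]), np.array([0]), beta)
            assert wv.weights[0] == pytest.approx(1.0)

    def test_beta_zero_is_uniform(self):
        counts = np.array([1, 7, 100])
        index = np.array([0, 1, 1, 2, 2, 2])
        np.testing.assert_allclose(cbw_weights(counts, index, 0.0).weights, np.ones(6))

    def test_closed_form_beta_09(self):
        wv = cbw_weights(np.array([2]), np.array([0]), beta=0.9)
        assert wv.weights[0] == pytest.approx(1 / 1.9, abs=1e-12)

    def test_beta_to_one_converges_to_csw(self):
        counts = np.array([1, 5, 40])
        index = np.array([0, 1, 2])
        cbw = cbw_weights(counts, index, beta=0.9999).weights
        csw = csw_weights(counts, index, "plain").weights
        np.testing.assert_allclose(cbw, csw, rtol=0.01)

    def test_monotone_in_beta_for_counts_above_one(self):
        counts = np.array([10])
        index = np.array([0])
        weights = [cbw_weights(counts, index, b).weights[0] for b in (0.1, 0.5, 0.9, 0.99)]
        assert all(a > b for a, b in zip(weights, weights[1:]))

    def test_invalid_beta_rejected(self):
        for beta in (-0.1, 1.0, 2.0):
            with pytest.raises(ValueError):
                effective_number(np.array([3]), beta)


class TestLDS:
    def test_kernel_normalized_and_symmetric(self):
        for size in (3, 5, 7):
            for sigma in (1.0, 2.0):
                k = gaussian_kernel(size, sigma)
                assert k.sum() == pytest.approx(1.0, abs=1e-12)
                np.testing.assert_allclose(k, k[::-1])

    def test_kernel_closed_form_size3(self):
        k = gaussian_kernel(3, 1.0)
        raw = np.array([np.exp(-0.5), 1.0, np.exp(-0.5)])
        np.testing.assert_allclose(k, raw / raw.sum(), atol=1e-12)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(4, 1.0)

    def test_delta_kernel_reduces_to_csw(self):
        labels = np.random.default_rng(0).normal(size=300)
        index, counts = bin_labels(labels, BinSpec(n_bins=31))
        density = lds_effective_density(counts, np.array([1.0]))
        np.testing.assert_array_equal(density, counts.astype(float))
        lds = weights_from_density(density, index).weights
        csw = rescale_mean_one(csw_weights(counts, index, "plain").weights)
        np.testing.assert_allclose(lds, csw, atol=1e-12)

    def test_uniform_counts_interior_unchanged(self):
        density = lds_effective_density(np.full(9, 4.0), gaussian_kernel(3, 1.0))
        np.testing.assert_allclose(density[1:-1], 4.0)

    def test_hand_convolution(self):
        out = lds_effective_density(np.array([0.0, 4.0, 0.0]), np.array([0.25, 0.5, 0.25]))
        np.testing.assert_allclose(out, [1.0, 2.0, 1.0])

    def test_weights_from_hand_convolution(self):
        density = np.array([1.0, 2.0, 1.0])
        index = np.array([0, 1, 2])
        w = weights_from_density(density, index).weights
        np.testing.assert_allclose(w / w[0], [1.0, 0.5, 1.0])
        assert w.mean() == pytest.approx(1.0)

    def test_zero_density_at_occupied_bin_rejected(self):
        with pytest.raises(ValueError):
            weights_from_density(np.array([0.0, 1.0]), np.array([0]))

    def test_uniform_density_gives_unit_weights(self):
        w = weights_from_density(np.full(5, 2.0), np.arange(5)).weights
        np.testing.assert_allclose(w, np.ones(5))


class TestComputeWeights:
    @pytest.mark.parametrize(
        "scheme", ["uniform", "dmw", "csw", "csw_root", "csw_square", "cbw", "lds"]
    )
    def test_strictly_positive_and_aligned(self, scheme):
        labels = np.random.default_rng(4).normal(1.0, 1.4, size=500)
        wv = compute_weights(labels, scheme)
        assert len(wv) == 500
        assert np.all(wv.weights > 0)

    @pytest.mark.parametrize("scheme", ["csw", "csw_root", "csw_square", "cbw", "lds"])
    def test_bin_schemes_rescaled_to_mean_one(self, scheme):
        labels = np.random.default_rng(4).normal(size=400)
        wv = compute_weights(labels, scheme)
        assert wv.weights.mean() == pytest.approx(1.0)

    def test_sparse_bins_upweighted(self):
        # bell-shaped labels: tail samples must carry more weight than the mode
        labels = np.random.default_rng(0).normal(1.0, 1.4, size=2000)
        for scheme in ("csw", "cbw", "lds"):
            wv = compute_weights(labels, scheme)
            tail = wv.weights[labels > 4].mean()
            center = wv.weights[np.abs(labels - 1.0) < 0.5].mean()
            assert tail > center

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(np.ones(3), "smote")

    def test_weight_vector_validation(self):
        with pytest.raises(ValueError):
            WeightVector(np.array([0.0, 0.0]), "uniform")
        with pytest.raises(ValueError):
            WeightVector(np.array([-1.0, 2.0]), "uniform")
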