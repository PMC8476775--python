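import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from deephistoclass.errors import ConfigError
from deephistoclass.uncertainty import (DHC_CAP, MCPredictionSet,
                                        binary_entropy, cppd, dhc_score,
                                        jackknife_entropy,
                                        jackknife_mutual_information,
                                        mutual_information, normalize_dhc,
                                        predictive_mean, score_predictions)


from _oracles import bf_jackknife_entropy as brute_force_jackknife


class TestPredictiveMean:
    def test_arithmetic_mean(self):
        assert predictive_mean([0.2, 0.4, 0.6]) == pytest.approx(0.4)

    def test_constant(self):
        assert predictive_mean([0.3] * 5) == pytest.approx(0.3)

    def test_permutation_invariance(self, rng):
        v = rng.random(20)
        assert predictive_mean(v) == pytest.approx(
            predictive_mean(v[rng.permutation(20)]))

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            predictive_mean([])


class TestBinaryEntropy:
    def test_maximum_at_half(self):
        assert binary_entropy(0.5) == 1.0

    def test_degenerate_endpoints(self):
        assert binary_entropy(0.0) == 0.0
        assert binary_entropy(1.0) == 0.0

    def test_closed_form_point(self):
        assert binary_entropy(0.9) == pytest.approx(0.4690, abs=1e-4)

    def test_matches_scipy_oracle(self, rng):
        from scipy.stats import entropy as scipy_entropy
        p = rng.random(100)
        expect = np.array([scipy_entropy([q, 1 - q], base=2) for q in p])
        np.testing.assert_allclose(binary_entropy(p), expect, atol=1e-12)

    def test_domain_checked(self):
        with pytest.raises(ConfigError):
            binary_entropy(1.5)


class TestJackknifeEntropy:
    def test_constant_samples_equal_plugin(self):
        # all leave-one-out means coincide, so the correction vanishes and
        # the estimate collapses to the plug-in entropy of the mean
        assert jackknife_entropy(np.full(10, 0.3)) == pytest.approx(
            binary_entropy(0.3), abs=1e-12)
        assert jackknife_entropy(np.ones(10)) == 0.0
        assert jackknife_entropy(np.zeros(10)) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            T = int(rng.integers(2, 65))
            v = rng.random(T)
            assert jackknife_entropy(v) == pytest.approx(
                brute_force_jackknife(v), abs=1e-12)

    def test_reduces_bias_of_plugin(self, rng):
        # Bernoulli(0.2) draws: plug-in entropy is biased downward; the
        # jackknife correction should shrink the absolute bias
        p, T, reps = 0.2, 50, 2000
        truth = binary_entropy(p)
        draws = (rng.random((reps, T)) < p).astype(float)
        hj = jackknife_entropy(draws.T)
        hp = binary_entropy(draws.mean(axis=1))
        assert abs(hj.mean() - truth) < abs(hp.mean() - truth)

    def test_needs_two_samples(self):
        with pytest.raises(ConfigError):
            jackknife_entropy([0.5])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(arrays(np.float64, st.integers(min_value=2, max_value=64),
                  elements=st.floats(0, 1)))
    def test_oracle_property(self, v):
        assert jackknife_entropy(v) == pytest.approx(
            brute_force_jackknife(v), abs=1e-12)


class TestMutualInformation:
    def test_constant_samples_zero(self):
        assert mutual_information(np.full(10, 0.7)) == 0.0

    def test_maximally_disagreeing_passes(self):
        assert mutual_information(np.array([0.0, 1.0] * 5)) == pytest.approx(1.0)

    def test_bounded_by_predictive_entropy(self, rng):
        v = rng.random(50)
        assert mutual_information(v) <= binary_entropy(v.mean()) + 1e-12


class TestCPPD:
    @pytest.mark.parametrize("mu,expect", [(0.5, 0.0), (0.0, 1.0),
                                           (1.0, 1.0), (0.75, 0.5)])
    def test_per_label_convention(self, mu, expect):
        assert cppd(np.full(8, mu)) == pytest.approx(expect)

    def test_across_labels_mode(self):
        samples = np.tile([0.9, 0.6, 0.1], (5, 1))
        assert cppd(samples, mode="across_labels") == pytest.approx(0.3)


class TestJackknifeMutualInformation:
    def test_collapses_to_corrected_entropy_minus_sample_entropy(self, rng):
        v = rng.random(40)
        expect = jackknife_entropy(v) - np.mean([binary_entropy(p) for p in v])
        assert jackknife_mutual_information(v) == pytest.approx(expect,
                                                                abs=1e-12)

    def test_zero_for_constant_degenerate_samples(self):
        assert jackknife_mutual_information(np.ones(10)) == pytest.approx(0.0)
        assert jackknife_mutual_information(np.zeros(10)) == pytest.approx(0.0)

    def test_grows_with_dispersion_at_fixed_mean(self, rng):
        tight = np.mean([jackknife_mutual_information(
            rng.beta(0.8 * 100, 0.2 * 100, 50)) for _ in range(200)])
        loose = np.mean([jackknife_mutual_information(
            rng.beta(0.8 * 3, 0.2 * 3, 50)) for _ in range(200)])
        assert loose > tight


class TestDHCScore:
    def test_ratio_is_cppd_over_corrected_mutual_information(self, rng):
        v = rng.random(40)
        raw, comp = dhc_score(v)
        assert raw == pytest.approx(
            comp["cppd"] / max(comp["mi_jackknife"], 1e-10))

    def test_degenerate_denominator_hits_cap(self):
        raw, comp = dhc_score(np.ones(10))
        assert raw == DHC_CAP
        assert comp["cppd"] == pytest.approx(1.0)

    def test_uncertain_mean_gives_near_zero(self, rng):
        v = np.clip(0.5 + rng.normal(0, 0.1, 100), 0, 1)
        v = v - (v.mean() - 0.5)  # recenter exactly
        raw, _ = dhc_score(v)
        assert raw < 0.1

    def test_dispersion_decreases_score(self, rng):
        # fixed mean 0.8, Beta dispersion ladder: mean raw DHC must fall
        means = []
        for kappa in (200.0, 50.0, 12.0, 5.0, 2.5):
            raws = [dhc_score(rng.beta(0.8 * kappa, 0.2 * kappa, 50))[0]
                    for _ in range(300)]
            means.append(np.mean(raws))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_mean_shift_increases_score(self, rng):
        means = []
        for mu in (0.55, 0.65, 0.75, 0.85, 0.95):
            kappa = 20.0
            raws = [dhc_score(rng.beta(mu * kappa, (1 - mu) * kappa, 50))[0]
                    for _ in range(300)]
            means.append(np.mean(raws))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_permutation_invariance(self, rng):
        v = rng.random(30)
        raw1, c1 = dhc_score(v)
        raw2, c2 = dhc_score(v[rng.permutation(30)])
        assert raw1 == pytest.approx(raw2, abs=1e-12)
        assert c1["H_jackknife"] == pytest.approx(c2["H_jackknife"], abs=1e-12)


class TestNormalizeDHC:
    def test_min_max(self):
        np.testing.assert_allclose(normalize_dhc([0, 5, 10]), [0, 0.5, 1])

    def test_all_equal_maps_to_one(self):
        np.testing.assert_array_equal(normalize_dhc([3.3] * 4), np.ones(4))

    def test_rank_order_preserved(self, rng):
        x = rng.random(50) * 100
        np.testing.assert_array_equal(np.argsort(normalize_dhc(x)),
                                      np.argsort(x))


class TestScorePredictions:
    def test_long_table_shape_and_invariants(self, rng):
        mc = [MCPredictionSet(f"i{i}", rng.random((20, 8))) for i in range(5)]
        y = rng.integers(0, 2, (5, 8))
        df = score_predictions(mc, y_true=y)
        assert len(df) == 40
        assert df["H_plugin"].between(0, 1).all()
        np.testing.assert_allclose(df["cppd"], np.abs(2 * df["mu"] - 1),
                                   atol=1e-12)
        assert df["dhc_normalized"].between(0, 1).all()

    def test_requires_at_least_two_mc_samples(self, rng):
        mc = [MCPredictionSet("i0", rng.random((1, 8)))]
        with pytest.raises(ConfigError):
            score_predictions(mc)
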