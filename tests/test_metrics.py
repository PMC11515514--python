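"""Regression/calibration metrics against direct recomputation."""

import numpy as np
import pytest
from scipy import stats

from molnp.metrics import (ad_buckets, calibration_correlation,
                           confidence_percentiles, nlpd, r_squared,
                           relative_error, PercentileSummary)
from molnp.molrep import smiles_to_fingerprint
from molnp.np_core import PredictiveGaussian, log_predictive_density


class TestRSquared:
    def test_exact_cases(self):
        assert r_squared([0, 1, 2], [0, 1, 2]) == 1.0
        assert r_squared([0, 1, 2], [1, 1, 1]) == 0.0
        assert r_squared([0, 1, 2], [0, 1, 1]) == pytest.approx(0.5)

    def test_random_inputs_match_sklearn_formula(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        y_hat = y + 0.3 * rng.normal(size=50)
        expected = 1 - np.sum((y - y_hat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r_squared(y, y_hat) == pytest.approx(expected, abs=1e-12)

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestNlpd:
    def test_standard_normal(self):
        pred = PredictiveGaussian(mean=[0.0, 1.0], variance=[1.0, 1.0])
        assert nlpd(pred, [0.0, 1.0]) == pytest.approx(0.9189385, abs=1e-6)

    def test_equals_scaled_log_density(self):
        rng = np.random.default_rng(1)
        pred = PredictiveGaussian(mean=rng.normal(size=9),
                                  variance=rng.uniform(0.1, 2.0, size=9))
        y = rng.normal(size=9)
        assert nlpd(pred, y) == pytest.approx(
            -log_predictive_density(pred, y) / 9, abs=1e-12)

    def test_diverges_as_variance_shrinks(self):
        vals = [nlpd(PredictiveGaussian(mean=[0.0], variance=[v]), [1.0])
                for v in (1.0, 0.1, 0.01)]
        assert vals[0] < vals[1] < vals[2]


class TestRelativeError:
    @pytest.mark.parametrize("y,y_hat,expected", [
        (-10.0, -9.0, 10.0), (2.0, 3.0, 50.0), (4.0, 4.0, 0.0)])
    def test_values(self, y, y_hat, expected):
        assert relative_error(y, y_hat) == pytest.approx(expected)

    def test_zero_label_rejected(self):
        with pytest.raises(ValueError, match="y = 0"):
            relative_error(0.0, 1.0)


class TestConfidencePercentiles:
    def test_group_sizes(self):
        rng = np.random.default_rng(2)
        pred = PredictiveGaussian(mean=np.zeros(2500),
                                  variance=rng.uniform(0.1, 1, 2500))
        s = confidence_percentiles(pred, rng.normal(size=2500), 100)
        assert (s.group_sizes == 25).all()
        assert (np.diff(s.variance) >= -1e-12).all()   # ascending variance

    def test_brute_force_on_toy(self):
        var = np.array([0.5, 0.1, 0.9, 0.3, 0.7, 0.2, 0.8, 0.4, 0.6, 1.0])
        mean = np.zeros(10)
        y = np.arange(10.0)
        s = confidence_percentiles(
            PredictiveGaussian(mean=mean, variance=var), y, 5)
        order = np.argsort(var, kind="stable")
        for g in range(5):
            idx = order[2 * g: 2 * g + 2]
            assert s.mse[g] == pytest.approx(np.mean(y[idx] ** 2))
            assert s.variance[g] == pytest.approx(np.mean(var[idx]))

    def test_remainder_goes_to_last_group(self):
        pred = PredictiveGaussian(mean=np.zeros(11), variance=np.arange(1, 12.))
        s = confidence_percentiles(pred, np.zeros(11), 3)
        assert list(s.group_sizes) == [3, 3, 5]

    def test_constant_variance_stable_order(self):
        pred = PredictiveGaussian(mean=np.zeros(6), variance=np.ones(6))
        y = np.array([1.0, 2, 3, 4, 5, 6])
        s = confidence_percentiles(pred, y, 3)
        assert s.mse[0] == pytest.approx(np.mean([1, 4]))   # original order

    def test_too_few_points(self):
        pred = PredictiveGaussian(mean=np.zeros(3), variance=np.ones(3))
        with pytest.raises(ValueError, match="n_groups"):
            confidence_percentiles(pred, np.zeros(3), 5)


class TestCalibrationCorrelation:
    def test_perfectly_calibrated_is_one(self):
        var = np.array([0.1, 0.5, 1.0, 2.0])
        s = PercentileSummary(mse=var.copy(), variance=var,
                              group_sizes=np.full(4, 10))
        assert calibration_correlation(s) == pytest.approx(1.0)

    def test_anticorrelated_is_minus_one(self):
        # geometric sequence: logs are linear, so the reversal is exact
        var = np.array([0.1, 0.2, 0.4, 0.8])
        s = PercentileSummary(mse=var[::-1].copy(), variance=var,
                              group_sizes=np.full(4, 10))
        assert calibration_correlation(s) == pytest.approx(-1.0)

    def test_three_group_toy_matches_pearson(self):
        mse = np.array([0.2, 0.9, 1.4])
        var = np.array([0.3, 0.6, 2.0])
        s = PercentileSummary(mse=mse, variance=var,
                              group_sizes=np.full(3, 5))
        expected, _ = stats.pearsonr(np.log(mse), np.log(var))
        assert calibration_correlation(s) == pytest.approx(expected)

    def test_group_order_irrelevant(self):
        rng = np.random.default_rng(3)
        mse = rng.uniform(0.1, 1, 8)
        var = rng.uniform(0.1, 1, 8)
        s1 = PercentileSummary(mse=mse, variance=var,
                               group_sizes=np.full(8, 4))
        perm = rng.permutation(8)
        s2 = PercentileSummary(mse=mse[perm], variance=var[perm],
                               group_sizes=np.full(8, 4))
        assert calibration_correlation(s1) == pytest.approx(
            calibration_correlation(s2))

    def test_nonpositive_groups_dropped_with_warning(self):
        s = PercentileSummary(mse=np.array([0.0, 0.2, 0.4, 0.8]),
                              variance=np.array([0.1, 0.2, 0.4, 0.8]),
                              group_sizes=np.full(4, 2))
        with pytest.warns(UserWarning, match="non-positive"):
            calibration_correlation(s)


class TestADBuckets:
    @pytest.fixture
    def fps(self):
        train = [smiles_to_fingerprint(s)
                 for s in ["CCO", "CCN", "c1ccccc1", "CCCC"]]
        test = [smiles_to_fingerprint(s)
                for s in ["CCO", "c1ccncc1", "C(F)(F)F"]]
        return train, test

    def test_identical_molecule_in_bucket_zero(self, fps):
        train, test = fps
        rep = ad_buckets(test, train, np.ones(3), np.full(3, 2.0))
        assert rep.counts.sum() == 3
        # "CCO" is in the training set: distance 0 -> bucket 0
        assert rep.counts[0] >= 1

    def test_distance_one_goes_to_last_bucket(self):
        a = [smiles_to_fingerprint("CCO")]
        far = [smiles_to_fingerprint("c1ccc2ccccc2c1")]   # disjoint bits
        rep = ad_buckets(far, a, np.array([1.0]), np.array([2.0]))
        assert rep.counts[19] == 1

    def test_zero_labels_excluded_with_warning(self, fps):
        train, test = fps
        with pytest.warns(UserWarning, match="label 0"):
            rep = ad_buckets(test, train, np.ones(3),
                             np.array([2.0, 0.0, 1.0]))
        assert rep.counts.sum() == 2
        assert rep.n_excluded == 1

    def test_empty_train_rejected(self, fps):
        _, test = fps
        with pytest.raises(ValueError, match="train"):
            ad_buckets(test, [], np.ones(3), np.ones(3))
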