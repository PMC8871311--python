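import math

import numpy as np
import pytest

from eegfusion import emd_decompose, featurize_dwt, featurize_emd, wavedec
from eegfusion.emd import IMFSet
from eegfusion.features import (
    CURVE_LENGTH_FLOOR,
    stat_curve_length,
    stat_kurtosis,
    stat_mean,
    stat_minima,
    stat_rms,
    stat_skewness,
    stat_std,
    stat_variance,
)


# -- brute-force re-implementations of the printed formulas (pure python) --

def bf_mean(x):
    return sum(x) / len(x)


def bf_variance(x):
    mu = bf_mean(x)
    return sum((v - mu) ** 2 for v in x) / len(x)


def bf_std(x):
    return math.sqrt(bf_variance(x))


def bf_rms(x):
    return math.sqrt(sum(v**2 for v in x) / len(x))


def bf_curve_length(x):
    return math.log(sum(abs(x[i] - x[i - 1]) for i in range(1, len(x))))


def bf_minima(x):
    return min(x)


def bf_skewness(x):
    mu, sigma = bf_mean(x), bf_std(x)
    return sum(((v - mu) / sigma) ** 3 for v in x) / len(x)


def bf_kurtosis(x):
    mu, sigma = bf_mean(x), bf_std(x)
    return sum(((v - mu) / sigma) ** 4 for v in x) / len(x)


ORACLES = [
    (stat_mean, bf_mean),
    (stat_variance, bf_variance),
    (stat_std, bf_std),
    (stat_rms, bf_rms),
    (stat_curve_length, bf_curve_length),
    (stat_minima, bf_minima),
    (stat_skewness, bf_skewness),
    (stat_kurtosis, bf_kurtosis),
]


@pytest.mark.parametrize("impl,oracle", ORACLES, ids=[f.__name__ for f, _ in ORACLES])
def test_feature_matches_brute_force_oracle(impl, oracle, rng):
    for _ in range(100):
        n = int(rng.integers(3, 200))
        x = (rng.standard_normal(n) * rng.uniform(0.1, 100)).tolist()
        assert impl(x) == pytest.approx(oracle(x), rel=1e-10)


class TestHandComputedExamples:
    def test_basic_moments(self):
        x = [1, 2, 3, 4]
        assert stat_mean(x) == pytest.approx(2.5)
        assert stat_variance(x) == pytest.approx(1.25)
        assert stat_std(x) == pytest.approx(math.sqrt(1.25))

    def test_rms(self):
        assert stat_rms([3, 4]) == pytest.approx(math.sqrt(12.5))

    def test_constant_degenerates(self):
        x = [7.0] * 10
        assert stat_variance(x) == 0.0
        assert stat_std(x) == 0.0
        assert stat_rms(x) == pytest.approx(7.0)
        assert stat_skewness(x) == 0.0
        assert stat_kurtosis(x) == 0.0
        assert stat_curve_length(x) == CURVE_LENGTH_FLOOR

    def test_curve_length(self):
        assert stat_curve_length([0, 1, 0, 1]) == pytest.approx(math.log(3))
        assert stat_curve_length([0, math.e]) == pytest.approx(1.0)

    def test_minima_global_reading(self):
        assert stat_minima([5, -2, 3]) == -2
        assert stat_minima([0, -1, -3, -1]) == -3
        assert stat_minima([4.0] * 3) == 4.0

    def test_minima_alternative_local_reading(self):
        # smallest absolute amplitude among strict local minima
        assert stat_minima([5, -2, 3, -8, 9], interpretation="local_min_abs") == 2

    def test_symmetric_sequence_has_zero_skewness(self):
        assert stat_skewness([1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_kurtosis(self):
        assert stat_kurtosis([-1, 1]) == pytest.approx(1.0)


class TestScaleBehavior:
    def test_homogeneity_degrees(self, rng):
        x = rng.standard_normal(64)
        a = 4.25
        assert stat_mean(a * x) == pytest.approx(a * stat_mean(x), rel=1e-10)
        assert stat_std(a * x) == pytest.approx(a * stat_std(x), rel=1e-10)
        assert stat_rms(a * x) == pytest.approx(a * stat_rms(x), rel=1e-10)
        assert stat_minima(a * x) == pytest.approx(a * stat_minima(x), rel=1e-10)
        assert stat_variance(a * x) == pytest.approx(a**2 * stat_variance(x), rel=1e-10)
        assert stat_skewness(a * x) == pytest.approx(stat_skewness(x), rel=1e-8)
        assert stat_kurtosis(a * x) == pytest.approx(stat_kurtosis(x), rel=1e-8)


class TestFeaturizeDwt:
    def test_segment_yields_42_named_features(self, rng):
        fv = featurize_dwt(wavedec(rng.standard_normal(512), level=5))
        assert len(fv.values) == 42
        assert fv.names[0] == "mean_cA5"
        assert fv.names[-1] == "minima_cD1"
        assert len(set(fv.names)) == 42
        assert np.all(np.isfinite(fv.values))

    def test_zero_segment_maps_to_finite_floor_values(self):
        fv = featurize_dwt(wavedec(np.zeros(512), level=5))
        assert np.all(np.isfinite(fv.values))
        by_name = dict(zip(fv.names, fv.values))
        assert by_name["mean_cA5"] == 0.0
        assert by_name["variance_cD3"] == 0.0
        assert by_name["curve_length_cD1"] == CURVE_LENGTH_FLOOR


class TestFeaturizeEmd:
    def test_five_imfs_yield_30_named_features(self, rng):
        t = np.arange(2048) / 256
        x = np.sin(2 * np.pi * 30 * t) + np.sin(2 * np.pi * 8 * t) + \
            0.5 * rng.standard_normal(2048)
        fv = featurize_emd(emd_decompose(x, max_imfs=5), expected_imfs=5)
        assert len(fv.values) == 30
        assert fv.names[0] == "variance_imf1"
        assert fv.names[-1] == "kurtosis_imf5"
        assert [n.rsplit("_", 1)[1] for n in fv.names] == \
            [f"imf{k}" for k in range(1, 6) for _ in range(6)]

    def test_short_imf_set_padded_with_zero_blocks(self):
        empty = IMFSet(imfs=[], residue=np.linspace(0, 1, 64))
        fv = featurize_emd(empty, expected_imfs=5)
        assert len(fv.values) == 30
        np.testing.assert_array_equal(fv.values, 0.0)
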