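"""Feature extractors against brute-force oracles and analytic cases."""

import numpy as np
import pytest

from msfs.features import (
    FEATURE_NAMES,
    FeatureParams,
    build_feature_matrix,
    feat_ica,
    feat_maxfft,
    feat_mean,
    feat_minfft,
    feat_psd,
    feat_sd,
    feat_shannon,
    feat_skew,
    feat_sure,
    feat_var,
    sure_threshold,
)
from msfs.normalization import to_frequency

from _oracles import (
    mean_loop,
    sd_loop,
    shannon_loop,
    skew_loop,
    sure_entropy_loop,
    sure_threshold_scan,
    var_loop,
    welch_curve_loop,
    welch_mean_loop,
)


class TestMoments:
    def test_mean_worked_examples(self):
        assert feat_mean(np.array([1.0, 2.0, 3.0])) == 2.0
        assert feat_mean(np.full(7, 4.2)) == pytest.approx(4.2)

    def test_hand_arithmetic_var_sd(self):
        v = np.array([1.0, 2.0, 3.0])
        assert feat_var(v) == pytest.approx(2 / 3)
        assert feat_sd(v) == pytest.approx(0.8165, abs=5e-5)

    def test_symmetric_vector_zero_skew(self, rng):
        half = rng.normal(size=50)
        v = np.concatenate([half, -half])  # symmetric about 0
        assert abs(feat_skew(v)) < 1e-12

    def test_sd_squared_equals_var(self, rng):
        v = rng.normal(size=100)
        assert feat_sd(v) ** 2 == pytest.approx(feat_var(v), rel=1e-12)

    @pytest.mark.parametrize("func,oracle", [
        (feat_mean, mean_loop),
        (feat_sd, sd_loop),
        (feat_var, var_loop),
        (feat_skew, skew_loop),
        (feat_shannon, shannon_loop),
    ])
    def test_matches_loop_oracle(self, func, oracle, rng):
        v = rng.normal(scale=2.0, size=97)
        assert func(v) == pytest.approx(oracle(v.tolist()), rel=1e-12, abs=1e-12)


class TestEntropy:
    def test_uniform_energy_maximizes(self):
        n = 37
        assert feat_shannon(np.full(n, 0.5)) == pytest.approx(np.log(n), rel=1e-12)

    def test_single_nonzero_entry_zero(self):
        v = np.zeros(16)
        v[3] = 2.5
        assert feat_shannon(v) == 0.0

    def test_all_zero_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert feat_shannon(np.zeros(8)) == 0.0


class TestSure:
    def test_threshold_matches_exhaustive_scan(self, rng):
        v = rng.normal(size=200)
        assert sure_threshold(v) == pytest.approx(sure_threshold_scan(v), rel=1e-10)

    def test_sure_entropy_matches_loop(self, rng):
        v = rng.normal(scale=0.5, size=150)
        assert feat_sure(v) == pytest.approx(sure_entropy_loop(v), rel=1e-10)

    def test_saturation_identities(self, rng):
        v = rng.normal(size=64)
        eps = sure_threshold(v)
        su = feat_sure(v)
        if np.all(np.abs(v) >= eps):
            assert su == pytest.approx(v.size * eps**2, rel=1e-12)
        small = v[np.abs(v) < eps]
        large_count = np.sum(np.abs(v) >= eps)
        assert su == pytest.approx(np.sum(small**2) + large_count * eps**2, rel=1e-12)


class TestSpectral:
    def test_white_noise_psd_level(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=4096)
        params = FeatureParams(welch_window_length=256, welch_overlap=128)
        got = feat_psd(v, params)
        n_bins = 129
        level = 2.0 * v.var() * (n_bins - 1) / n_bins  # one-sided density, fs=1
        assert got == pytest.approx(level, rel=0.10)

    def test_pure_tone_concentration(self):
        """The tone dominates the spectrum and our mean matches the curve mean."""
        n = 2048
        v = np.sin(2 * np.pi * 0.125 * np.arange(n))
        params = FeatureParams(welch_window_length=256, welch_overlap=128)
        curve = welch_curve_loop(v, 256, 128)
        assert curve.max() >= 100 * np.median(curve)
        assert feat_psd(v, params) == pytest.approx(curve.mean(), rel=1e-9)

    def test_matches_segment_average_oracle(self, rng):
        v = rng.normal(size=1024)
        params = FeatureParams(welch_window_length=128, welch_overlap=64)
        assert feat_psd(v, params) == pytest.approx(
            welch_mean_loop(v, 128, 64), rel=1e-9
        )

    def test_window_longer_than_signal_rejected(self, rng):
        with pytest.raises(ValueError):
            feat_psd(rng.normal(size=64), FeatureParams(welch_window_length=128))

    def test_max_min_fft(self, rng):
        v = rng.normal(size=128)
        spec = np.sort(to_frequency(v))
        assert feat_maxfft(v) == spec[-1]
        assert feat_minfft(v) == spec[0]
        assert feat_maxfft(v) >= feat_minfft(v)
        assert feat_maxfft(np.zeros(32)) == feat_minfft(np.zeros(32)) == 0.0


class TestICA:
    def test_recovers_source_from_known_mixing(self):
        rng = np.random.default_rng(11)
        s = rng.uniform(-1, 1, size=(5000, 2))
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        X = s @ A.T
        comp = feat_ica(X, FeatureParams(ica_seed=3))
        corr = max(abs(np.corrcoef(comp, s[:, j])[0, 1]) for j in range(2))
        assert corr >= 0.95

    def test_aligns_with_non_gaussian_column(self):
        rng = np.random.default_rng(13)
        non_gauss = rng.uniform(-1, 1, 5000) ** 3  # heavy-tailed, non-Gaussian
        gauss = rng.normal(size=5000)
        X = np.column_stack([non_gauss, gauss])
        comp = feat_ica(X, FeatureParams(ica_seed=3))
        assert abs(np.corrcoef(comp, non_gauss)[0, 1]) >= 0.9

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(500, 4))
        a = feat_ica(X, FeatureParams(ica_seed=9))
        b = feat_ica(X, FeatureParams(ica_seed=9))
        np.testing.assert_array_equal(a, b)


class TestBuildFeatureMatrix:
    def test_shape_and_finiteness(self, rng):
        scores = rng.normal(size=(30, 5))
        fm = build_feature_matrix(scores, np.repeat([0, 1, 2], 10))
        assert fm.values.shape == (30, 10)
        assert np.all(np.isfinite(fm.values))
        assert fm.feature_names == FEATURE_NAMES

    def test_single_record_matches_individual_extractors(self, rng):
        v = rng.normal(size=64)
        fm = build_feature_matrix(v[None, :], np.array([1]))
        row = dict(zip(fm.feature_names, fm.values[0]))
        assert row["M"] == pytest.approx(feat_mean(v))
        assert row["SD"] == pytest.approx(feat_sd(v))
        assert row["V"] == pytest.approx(feat_var(v))
        assert row["S"] == pytest.approx(float(feat_skew(v)))
        assert row["SE"] == pytest.approx(feat_shannon(v))
        assert row["SU"] == pytest.approx(float(feat_sure(v)))
        assert row["MAX"] == pytest.approx(feat_maxfft(v))
        assert row["MIN"] == pytest.approx(feat_minfft(v))

    def test_permutation_equivariance(self, rng):
        scores = rng.normal(size=(50, 6))
        signals = rng.normal(size=(50, 300))
        labels = np.arange(50) % 5
        params = FeatureParams(welch_window_length=128, welch_overlap=64, ica_seed=5)
        fm = build_feature_matrix(scores, labels, params=params, signals=signals)
        perm = rng.permutation(50)
        fm_p = build_feature_matrix(scores[perm], labels[perm], params=params,
                                    signals=signals[perm])
        np.testing.assert_allclose(fm_p.values, fm.values[perm], rtol=1e-6, atol=1e-9)

    def test_non_finite_rows_excluded_with_warning(self, rng):
        scores = rng.normal(size=(10, 4))
        signals = rng.normal(size=(10, 64))
        scores[3, :] = np.nan
        with pytest.warns(RuntimeWarning):
            fm = build_feature_matrix(scores, np.arange(10) % 2, signals=signals)
        assert fm.values.shape[0] == 9
        assert list(fm.excluded_rows) == [3]
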