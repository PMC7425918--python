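"""Normalization bank: method contracts, invariances, loop-oracle equivalence."""

import math
import warnings

import numpy as np
import pytest

from msfs.normalization import (
    NORMALIZATION_METHODS,
    REFERENCE_METHODS,
    ReferenceSignal,
    compute_reference,
    normalize,
    normalize_set,
    to_frequency,
)
from msfs.phantom import SignalRecord, SignalSet, clean_received, generate_dataset

EPS = 1e-12


def loop_normalize(v, method, ref=None, gstats=None):
    """Straightforward per-element reference implementation."""
    v = list(map(float, v))
    n = len(v)
    if method == "DS":
        peak = max(abs(x) for x in v)
        j = 0
        while peak / 10**j > 1:
            j += 1
        return [x / 10**j for x in v]
    if method == "ZS":
        mu = sum(v) / n
        sd = math.sqrt(sum((x - mu) ** 2 for x in v) / n)
        return [(x - mu) / sd for x in v]
    if method == "LS":
        peak = max(abs(x) for x in v)
        return [x / peak for x in v]
    if method == "MM":
        lo, hi = min(v), max(v)
        return [(x - lo) / (hi - lo) for x in v]
    if method == "MSD":
        mu, sd = gstats
        return [(x - mu) / sd for x in v]
    if method == "RV":
        return [x - r for x, r in zip(v, ref)]
    if method == "FVC":
        return [(x - r) / (abs(r) + EPS) for x, r in zip(v, ref)]
    if method == "RLV":
        return [math.log10((abs(x) + EPS) / (abs(r) + EPS)) for x, r in zip(v, ref)]
    energy = sum(r * r for r in ref)
    if method == "RSSV":
        return [(x - r) * abs(x - r) / energy for x, r in zip(v, ref)]
    return [math.log10(((x - r) ** 2 + EPS) / energy) for x, r in zip(v, ref)]


def make_set(vectors, sizes):
    records = [
        SignalRecord(amplitude=np.asarray(v, float), size_mm=s,
                     location_cm=None if s == 0 else (1.0, 1.0, 4.0), rep=i)
        for i, (v, s) in enumerate(zip(vectors, sizes))
    ]
    from msfs.phantom import AcquisitionConfig

    cfg = AcquisitionConfig(n_points=len(vectors[0]), window_ns=1.0,
                            tumor_sizes_mm=(2.0,), locations_cm=((1.0, 1.0, 4.0),),
                            reps_per_point=1, n_tumor_free=sum(1 for s in sizes if s == 0))
    return SignalSet(records=records, config=cfg)


class TestToFrequency:
    def test_pure_tone_concentrates_at_its_bin(self):
        n, k = 256, 17
        v = np.cos(2 * np.pi * k * np.arange(n) / n)
        spec = to_frequency(v)
        assert np.argmax(spec) == k
        assert spec[k] > 100 * np.median(spec)

    def test_received_pulse_peak_near_center_frequency(self):
        from msfs.phantom import AcquisitionConfig

        cfg = AcquisitionConfig()
        v = clean_received(cfg, 4.0, cfg.locations_cm[0])
        freqs = np.fft.rfftfreq(cfg.n_points, cfg.window_ns / cfg.n_points)
        peak = freqs[np.argmax(to_frequency(v))]
        # direct/echo interference ripples the spectrum; peak stays near f_c
        assert abs(peak - cfg.center_freq_ghz) <= 0.5

    def test_parseval_identity(self, rng):
        v = rng.normal(size=257)  # odd length: no bare Nyquist bin
        spec = to_frequency(v)
        rhs = (spec[0] ** 2 + 2 * np.sum(spec[1:] ** 2)) / v.size
        assert np.sum(v**2) == pytest.approx(rhs, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            to_frequency(np.array([]))


class TestReference:
    def test_single_record(self):
        s = make_set([[1.0, 2.0, 3.0]], [0])
        np.testing.assert_array_equal(compute_reference(s).amplitude, [1, 2, 3])

    def test_two_record_mean(self):
        s = make_set([[1.0, 2.0], [3.0, 6.0], [10.0, 10.0]], [0, 0, 2.0])
        np.testing.assert_allclose(compute_reference(s).amplitude, [2.0, 4.0])

    def test_no_tumor_free_rejected(self):
        s = make_set([[1.0, 2.0]], [2.0])
        with pytest.raises(ValueError):
            compute_reference(s)

    def test_clt_concentration_around_clean_pulse(self):
        """100 noisy null records: the mean is within 4 sd/sqrt(100) nearly everywhere."""
        import dataclasses

        from msfs.phantom import AcquisitionConfig

        cfg = AcquisitionConfig(
            n_points=256, window_ns=2.56, tumor_sizes_mm=(2.0,),
            locations_cm=((1.0, 1.0, 4.0),), reps_per_point=1,
            n_tumor_free=100, noise_sd=0.05, drift_amplitude=0.0, rng_seed=3,
        )
        ds = generate_dataset(cfg)
        ref = compute_reference(ds).amplitude
        clean = clean_received(cfg, 0.0, None)
        bound = 4 * cfg.noise_sd / math.sqrt(100)
        assert np.mean(np.abs(ref - clean) < bound) >= 0.99


class TestMethods:
    def test_min_max_worked_example(self):
        np.testing.assert_allclose(normalize([2, 4, 6], "MM"), [0, 0.5, 1])

    def test_zscore_worked_example(self):
        out = normalize([1, 2, 3], "ZS")
        np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=5e-5)

    def test_rv_identity_reference_is_zero(self, rng):
        v = rng.normal(size=32)
        out = normalize(v, "RV", reference=ReferenceSignal(v.copy()))
        np.testing.assert_array_equal(out, np.zeros_like(v))

    @pytest.mark.parametrize("method", NORMALIZATION_METHODS)
    def test_matches_loop_oracle(self, method, rng):
        v = rng.normal(scale=3.0, size=64)
        ref = rng.normal(scale=2.0, size=64)
        gstats = (1.3, 2.7)
        got = normalize(v, method, reference=ReferenceSignal(ref), global_stats=gstats)
        want = loop_normalize(v, method, ref=ref, gstats=gstats)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("method", NORMALIZATION_METHODS)
    def test_dimension_preserved_rows_and_matrix(self, method, rng):
        X = rng.normal(size=(5, 48))
        ref = rng.normal(size=48)
        out = normalize(X, method, reference=ReferenceSignal(ref), global_stats=(0.0, 1.0))
        assert out.shape == X.shape

    def test_range_invariants(self, rng):
        v = rng.normal(scale=40.0, size=128)
        assert np.all((normalize(v, "MM") >= 0) & (normalize(v, "MM") <= 1))
        assert np.max(np.abs(normalize(v, "DS"))) <= 1
        zs = normalize(v, "ZS")
        assert abs(zs.mean()) < 1e-9 and abs(zs.std() - 1) < 1e-9

    def test_rv_drift_invariance(self, rng):
        v = rng.normal(size=64)
        ref = rng.normal(size=64)
        out1 = normalize(v, "RV", reference=ReferenceSignal(ref))
        out2 = normalize(v + 0.37, "RV", reference=ReferenceSignal(ref + 0.37))
        np.testing.assert_allclose(out1, out2, atol=1e-12)

    @pytest.mark.parametrize("method", ["FVC", "RLV"])
    def test_scale_invariance(self, method, rng):
        v = rng.normal(size=64) + 5.0
        ref = rng.normal(size=64) + 5.0
        out1 = normalize(v, method, reference=ReferenceSignal(ref))
        out2 = normalize(3.5 * v, method, reference=ReferenceSignal(3.5 * ref))
        np.testing.assert_allclose(out1, out2, atol=1e-9)

    @pytest.mark.parametrize("method", ["ZS", "MM"])
    def test_constant_signal_degenerate_policy(self, method):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            out = normalize(np.full(16, 2.0), method, degenerate_policy="zeros")
        np.testing.assert_array_equal(out, np.zeros(16))
        assert any("degenerate" in str(x.message) for x in w)
        with pytest.raises(ValueError):
            normalize(np.full(16, 2.0), method, degenerate_policy="error")

    def test_reference_required_for_relative_methods(self, rng):
        for method in REFERENCE_METHODS:
            with pytest.raises(ValueError):
                normalize(rng.normal(size=8), method)

    def test_normalize_set_shape_and_metadata(self, tiny_dataset):
        nset = normalize_set(tiny_dataset, "RV")
        assert nset.matrix.shape == tiny_dataset.amplitude_matrix().shape
        assert nset.method_name == "RV"
        assert nset.reference_used
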