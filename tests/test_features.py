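"""Descriptor computation: fits, peaks, spectra, the 27-name vector."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calscreen import (
    FEATURE_NAMES,
    PhenotypeClass,
    TraceArchetypeParams,
    TraceSeries,
    detect_peaks,
    extract_features,
    fit_gaussian_spectrum,
    fit_polynomial,
    make_trace,
    normalize_dff,
    power_spectrum,
)
from calscreen.features import NUMERIC_COLUMNS, PowerSpectrum
from conftest import brute_force_power, naive_peak_indices

OSC, PEAK, OTHER = PhenotypeClass.OSC_PEAK, PhenotypeClass.PEAK, PhenotypeClass.OTHER


def series(values, rate=2.0):
    return TraceSeries("w", 0, np.asarray(values, float), rate)


class TestNormalizeDff:
    def test_constant_trace_maps_to_zero(self):
        out = normalize_dff(series(np.full(40, 250.0)))
        assert np.allclose(out.values, 0.0)

    def test_simple_ratio(self):
        y = np.full(40, 100.0)
        y[30:] = 150.0
        out = normalize_dff(series(y))
        assert out.values[35] == pytest.approx(0.5)

    def test_peak_archetype_plateau_ratio(self):
        # plateau = baseline + 2*baseline => dF/F0 = 2 at the plateau
        p = TraceArchetypeParams(baseline=150.0, peak_amplitude=300.0, noise_sd=0.0)
        out = normalize_dff(make_trace(PEAK, p, seed=0))
        assert out.values[-10:].mean() == pytest.approx(2.0, abs=0.01)

    def test_nonpositive_baseline_is_error(self):
        with pytest.raises(ValueError, match="F0"):
            normalize_dff(series(np.zeros(40)))


class TestFitPolynomial:
    def test_low_degree_polynomial_is_fit_exactly(self):
        x = np.linspace(-1, 1, 380)
        y = 2.0 + 3.0 * x - 1.5 * x**3
        fit = fit_polynomial(y, 8)
        assert fit.mse / np.mean(y**2) < 1e-9
        assert fit.coefficients.size == 9

    def test_noise_mse_matches_monte_carlo_expectation(self):
        # For white noise of unit variance, the order-8 residual MSE
        # averages (n - 9)/n ~ 0.976 over many realizations.
        rng = np.random.default_rng(12)
        mses = [fit_polynomial(rng.normal(0, 1, 380), 8).mse for _ in range(100)]
        assert np.mean(mses) == pytest.approx(1.0, rel=0.2)

    @pytest.mark.parametrize("cls", list(PhenotypeClass))
    def test_nested_orders_never_fit_worse(self, cls):
        tr = make_trace(cls, TraceArchetypeParams(noise_sd=15.0), seed=5)
        assert fit_polynomial(tr, 25).mse <= fit_polynomial(tr, 8).mse + 1e-9

    def test_oscillatory_trace_prefers_higher_order_strictly(self):
        tr = make_trace(OSC, TraceArchetypeParams(noise_sd=0.0), seed=0)
        assert fit_polynomial(tr, 25).mse < fit_polynomial(tr, 8).mse

    def test_order_at_least_length_is_error(self):
        with pytest.raises(ValueError):
            fit_polynomial(np.zeros(10), 10)


class TestDetectPeaks:
    def test_constant_signal_has_no_peaks(self):
        assert detect_peaks(np.full(50, 3.0), 3, 3.0).count == 0

    def test_triangular_bump_single_apex(self):
        y = np.zeros(31)
        y[10:16] = [2, 6, 10, 6, 2, 0]
        pl = detect_peaks(y, 3, 3.0)
        assert pl.indices.tolist() == [12]

    def test_five_sinusoid_cycles_counted(self):
        # 4 samples per cycle keeps the neighbor drop at full amplitude
        n = 21
        y = 5.0 * np.sin(2 * np.pi * np.arange(n) / 4.0)
        pl = detect_peaks(y, 3, 3.0)
        assert pl.count == 5
        assert pl.indices.tolist() == naive_peak_indices(y, 3, 3.0)

    def test_window_wider_than_signal_yields_empty(self):
        assert detect_peaks(np.arange(10.0), 51, 1.0).count == 0

    @pytest.mark.parametrize("width,threshold", [(3, 0.5), (3, 3.0), (7, 1.0), (51, 2.0)])
    def test_matches_enumeration_oracle_on_random_traces(self, width, threshold):
        rng = np.random.default_rng(width * 1000 + int(threshold * 10))
        for _ in range(250):
            n = int(rng.integers(20, 140))
            y = rng.normal(0, 1, n) + 3 * np.sin(np.arange(n) / rng.uniform(1, 8))
            got = detect_peaks(y, width, threshold).indices.tolist()
            assert got == naive_peak_indices(y, width, threshold)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=5, max_size=60),
        st.sampled_from([1, 3, 5, 9]),
        st.floats(0, 10),
    )
    def test_reported_peaks_satisfy_contract(self, values, width, threshold):
        pl = detect_peaks(np.array(values), width, threshold)
        assert np.all(np.diff(pl.indices) > 0)
        assert np.all(pl.prominences >= threshold)
        assert pl.count == pl.indices.size


class TestPowerSpectrum:
    def test_bin_frequency_sinusoid_concentrates_power(self):
        n, fs = 256, 2.0
        f0 = 16 * fs / n
        y = 100 + 5 * np.sin(2 * np.pi * f0 * np.arange(n) / fs)
        sp = power_spectrum(y, fs)
        k = 1 + int(np.argmax(sp.power[1:]))
        assert sp.frequencies[k] == pytest.approx(f0)
        assert sp.power[k] / sp.total_power > 0.99

    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 96) + np.linspace(0, 4, 96)
        sp = power_spectrum(y, 2.0)
        assert np.allclose(sp.power, brute_force_power(y), atol=1e-12)

    def test_normalized_power_sums_to_one(self):
        rng = np.random.default_rng(3)
        sp = power_spectrum(rng.normal(0, 1, 380), 2.0)
        assert sp.normalized_power.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_trace_flagged_undefined(self):
        sp = power_spectrum(np.full(64, 5.0), 2.0)
        assert not sp.defined
        assert sp.total_power == 0.0

    def test_noise_spectrum_flatter_than_sinusoid(self):
        rng = np.random.default_rng(4)
        n, fs = 380, 2.0
        sd_noise = []
        for _ in range(30):
            sp = power_spectrum(rng.normal(0, 1, n), fs)
            sd_noise.append(sp.normalized_power[1:].std())
        y = np.sin(2 * np.pi * 0.2 * np.arange(n) / fs)
        sd_sin = power_spectrum(y, fs).normalized_power[1:].std()
        assert np.mean(sd_noise) < sd_sin


class TestGaussianSpectrumFit:
    def test_recovers_sampled_gaussian(self):
        f = np.arange(0.0, 1.0, 0.01)
        p = 2.5 * np.exp(-((f - 0.2) ** 2) / (2 * 0.05**2))
        sp = PowerSpectrum(f, p, p / p.sum(), float(p.sum()))
        g = fit_gaussian_spectrum(sp)
        assert g.success
        assert g.center == pytest.approx(0.2, abs=1e-3)
        assert g.sd == pytest.approx(0.05, rel=0.05)

    def test_burst_archetype_center_within_one_bin(self):
        p = TraceArchetypeParams(peak_amplitude=0.0, osc_frequency=0.1, noise_sd=0.0)
        tr = make_trace(OSC, p, seed=0)
        sp = power_spectrum(tr)
        df = sp.frequencies[1] - sp.frequencies[0]
        for use_norm in (False, True):
            g = fit_gaussian_spectrum(sp, use_normalized=use_norm)
            assert g.success
            assert abs(g.center - 0.1) <= df

    def test_noise_spectrum_never_fits_a_narrow_spike(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            sp = power_spectrum(rng.normal(0, 1, 380), 2.0)
            df = sp.frequencies[1] - sp.frequencies[0]
            g = fit_gaussian_spectrum(sp)
            assert (not g.success) or g.sd >= 3 * df - 1e-12

    def test_undefined_spectrum_flagged(self):
        sp = power_spectrum(np.full(64, 5.0), 2.0)
        assert not fit_gaussian_spectrum(sp, use_normalized=True).success


class TestExtractFeatures:
    def test_descriptor_set_is_exactly_the_27_names(self):
        fv = extract_features(make_trace(OTHER, seed=0))
        assert set(fv.values) == set(FEATURE_NAMES)
        assert len(FEATURE_NAMES) == 27
        row = fv.to_row()
        assert set(row) == set(NUMERIC_COLUMNS)
        assert len(row) == 35

    def test_constant_trace_degenerate_descriptors(self):
        fv = extract_features(series(np.full(380, 100.0)))
        for name in ("SDF", "Variance", "dF", "lgePk", "1stSmlPk", "2ndSmlPk", "ampPS"):
            assert fv[name] == 0.0
        assert np.isnan(fv["ampNormPS"])  # normalized spectrum undefined
        assert np.isnan(fv["gauCentrPS"])

    def test_peak_archetype_descriptors(self):
        tr = make_trace(PEAK, TraceArchetypeParams(noise_sd=0.0), seed=0)
        fv = extract_features(tr)
        assert fv["1stSmlPk"] == 0.0
        assert fv["lgePk"] >= 1.0
        assert fv["dFP"] == pytest.approx(400.0, rel=0.05)
        assert fv["dTP"] > 0

    def test_oscillation_four_cycles_counted_in_first_window(self):
        # 0.25 Hz puts the sinusoid apexes exactly on the 2 Hz sample
        # grid; the short taper keeps all four inside the flat envelope
        p = TraceArchetypeParams(
            osc_frequency=0.25, osc_window=(12.5, 28.5), osc_taper=0.1, noise_sd=0.0
        )
        tr = make_trace(OSC, p, seed=0)
        fv = extract_features(tr)
        resid = tr.values - fit_polynomial(tr, 25).fitted_values
        oracle = len(naive_peak_indices(resid[:180], 3, 3.0))
        assert fv["1stSmlPk"] == oracle == 4

    def test_shift_invariance(self):
        tr = make_trace(OSC, TraceArchetypeParams(noise_sd=10.0), seed=6)
        shifted = series(tr.values + 500.0)
        a = extract_features(tr)
        b = extract_features(shifted)
        invariant = [n for n in FEATURE_NAMES
                     if n not in ("meanF", "medF", "expFitCoeff")]
        for name in invariant:
            va, vb = a[name], b[name]
            if np.isnan(va):
                assert np.isnan(vb)
            else:
                assert vb == pytest.approx(va, rel=1e-6, abs=1e-9), name
        assert b["meanF"] - a["meanF"] == pytest.approx(500.0)
        assert b["medF"] - a["medF"] == pytest.approx(500.0)

    def test_no_crash_on_all_archetypes_with_noise(self):
        for cls in PhenotypeClass:
            for seed in range(3):
                tr = make_trace(cls, TraceArchetypeParams(noise_sd=25.0), seed=seed)
                fv = extract_features(tr)
                assert set(fv.values) == set(FEATURE_NAMES)
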