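"""The 27 response descriptors of a single Ca2+ trace.

Each per-cell fluorescence time course is summarized by 27 named
descriptors combining curve fitting, peak detection and spectral
analysis:

* two least-squares polynomial fits (orders 8 and 25) on a time axis
  rescaled to [-1, 1]: the smooth order-8 curve carries the sustained
  ("macropore") signal and its mean squared error (expFitErr); the
  order-25 residual carries the intermediate oscillations;
* windowed peak detection with a prominence threshold: small peaks
  (width 3, threshold 3) counted on the order-25 residual in the first
  and last 90 s, large peaks (width 50, threshold 50) on the order-8
  fitted curve;
* the one-sided FFT power spectrum of the mean-subtracted trace, its
  total-power-normalized twin, their moments, and a single-Gaussian fit
  to each (center, width and weighted residual);
* plain trace statistics (mean, median, SD, variance, start-to-end
  change).

Descriptors that are undefined for a given trace (no large peak, zero
total power, non-convergent Gaussian fit) are emitted as NaN — a
sentinel the downstream classifier handles natively, never a crash.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import chebyshev as _cheb
from scipy.optimize import curve_fit

from .traces import TraceSeries

__all__ = [
    "FEATURE_NAMES",
    "NUMERIC_COLUMNS",
    "PolyFitResult",
    "PeakList",
    "PowerSpectrum",
    "GaussFitResult",
    "FeatureVector",
    "normalize_dff",
    "fit_polynomial",
    "detect_peaks",
    "power_spectrum",
    "fit_gaussian_spectrum",
    "extract_features",
    "features_frame",
]

#: The 27 named descriptors, in canonical (alphabetical) order.
FEATURE_NAMES: tuple[str, ...] = (
    "1stSmlPk", "2ndSmlPk", "ampNormPS", "ampPS", "dF", "dFP", "dTP",
    "expFitCoeff", "expFitErr", "gauCentrNormPS", "gauCentrPS",
    "gauNormRes", "gauNormSD", "gauRes", "gauSD", "lgePk", "meanF",
    "meanNormPS", "meanPS", "medF", "medNormPS", "medPS", "peakPS",
    "SDF", "SDNormPS", "SDPS", "Variance",
)

#: Flat numeric columns: expFitCoeff expands into its 9 order-8
#: coefficients for numeric consumers (the classifier, CSV export).
NUMERIC_COLUMNS: tuple[str, ...] = tuple(
    [f"expFitCoeff_{i}" for i in range(9)]
    + [n for n in FEATURE_NAMES if n != "expFitCoeff"]
)


def normalize_dff(trace: TraceSeries, baseline_seconds: float = 10.0) -> TraceSeries:
    """Convert a raw trace to relative changes dF/F0.

    F0 is the average fluorescence within the first ``baseline_seconds``
    of the recording (the initial resting condition); the output is
    (F - F0) / F0. A non-positive F0 (dye-free cell) is an error.
    """
    n0 = max(1, int(round(baseline_seconds * trace.sampling_rate)))
    f0 = float(trace.values[:n0].mean())
    if f0 <= 0:
        raise ValueError(f"baseline F0 must be positive, got {f0}")
    return TraceSeries(
        trace.well_id, trace.cell_id, (trace.values - f0) / f0, trace.sampling_rate
    )


# ---------------------------------------------------------------------------
# Polynomial fits


@dataclass
class PolyFitResult:
    """Least-squares polynomial fit of a trace.

    ``coefficients`` are power-series coefficients (ascending) in the
    rescaled time variable x in [-1, 1]; the fit itself is performed in
    the Chebyshev basis for conditioning (a raw monomial Vandermonde at
    order 25 over 380 points is numerically singular).
    """

    order: int
    coefficients: np.ndarray
    fitted_values: np.ndarray
    mse: float


def fit_polynomial(trace: TraceSeries | np.ndarray, order: int) -> PolyFitResult:
    """Fit a polynomial of the given order to a trace.

    Orders 8 and 25 are the analysis convention: the order-8 fit feeds
    the sustained-signal evaluation, the order-25 residual feeds
    oscillation detection.
    """
    y = trace.values if isinstance(trace, TraceSeries) else np.asarray(trace, float)
    n = y.size
    if order >= n:
        raise ValueError(f"order {order} requires more than {order} samples, got {n}")
    x = np.linspace(-1.0, 1.0, n)
    series = _cheb.Chebyshev.fit(x, y, deg=order, domain=[-1.0, 1.0])
    fitted = series(x)
    resid = y - fitted
    return PolyFitResult(
        order=order,
        coefficients=_cheb.cheb2poly(series.coef),
        fitted_values=fitted,
        mse=float(np.mean(resid**2)),
    )


# ---------------------------------------------------------------------------
# Peak detection


@dataclass
class PeakList:
    """Peaks found by windowed-maximum detection with a prominence gate."""

    indices: np.ndarray
    prominences: np.ndarray
    width_param: int
    threshold_param: float

    @property
    def count(self) -> int:
        return int(self.indices.size)


def detect_peaks(signal: np.ndarray, width: int, threshold: float) -> PeakList:
    """Detect peaks as strict windowed maxima with sufficient prominence.

    Sample i is a peak iff it is the (earliest, on ties) maximum of the
    centered window of ``width`` samples (width is rounded up to odd)
    and its prominence — height above the higher of the two flanking
    minima within the window span — is at least ``threshold``. Samples
    closer than half a window to either boundary have no centered window
    and cannot be peaks; a window wider than the signal yields no peaks.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    y = np.asarray(signal, dtype=float)
    # odd width, floored at 3: a 1-sample window has no flanking minima
    # to measure prominence against
    w = max(3, width if width % 2 == 1 else width + 1)
    half = w // 2
    n = y.size
    idx: list[int] = []
    prom: list[float] = []
    if w <= n:
        # Candidates: local maxima in the immediate-neighbor sense
        # (strictly above the previous sample, at least the next), then
        # verified against the full window.
        for i in range(max(1, half), min(n - 1, n - half)):
            if not (y[i] > y[i - 1] and y[i] >= y[i + 1]):
                continue
            left = y[i - half : i]
            right = y[i + 1 : i + half + 1]
            if left.size and left.max() >= y[i]:
                continue  # not the strict/earliest window maximum
            if right.size and right.max() > y[i]:
                continue
            base = max(left.min(), right.min())
            p = y[i] - base
            if p >= threshold:
                idx.append(i)
                prom.append(p)
    return PeakList(
        indices=np.asarray(idx, dtype=int),
        prominences=np.asarray(prom, dtype=float),
        width_param=w,
        threshold_param=float(threshold),
    )


# ---------------------------------------------------------------------------
# Spectra


@dataclass
class PowerSpectrum:
    """One-sided FFT power spectrum of a mean-subtracted trace.

    ``normalized_power`` is power divided by total power (summing to 1)
    and is None for an all-constant trace, whose spectrum is undefined.
    """

    frequencies: np.ndarray
    power: np.ndarray
    normalized_power: np.ndarray | None
    total_power: float

    @property
    def defined(self) -> bool:
        return self.normalized_power is not None


def power_spectrum(trace: TraceSeries | np.ndarray, sampling_rate: float | None = None) -> PowerSpectrum:
    """One-sided periodogram of the mean-subtracted trace.

    Power is |X_k|^2 / n^2 with the one-sided doubling of interior bins,
    so a pure sinusoid at a bin frequency concentrates its variance in a
    single bin. The DC bin is identically zero after mean subtraction.
    """
    if isinstance(trace, TraceSeries):
        y = trace.values
        fs = trace.sampling_rate
    else:
        y = np.asarray(trace, dtype=float)
        fs = sampling_rate if sampling_rate is not None else 2.0
    n = y.size
    if n < 4:
        raise ValueError("spectrum needs at least 4 samples")
    yc = y - y.mean()
    spec = np.fft.rfft(yc)
    power = np.abs(spec) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    total = float(power.sum())
    norm = power / total if total > 0 else None
    return PowerSpectrum(freqs, power, norm, total)


@dataclass
class GaussFitResult:
    """Single-Gaussian fit to a (non-DC) power spectrum."""

    center: float
    sd: float
    amplitude: float
    weighted_mean_error: float
    success: bool = True

    @classmethod
    def failed(cls) -> "GaussFitResult":
        return cls(float("nan"), float("nan"), float("nan"), float("nan"), False)


def _gauss(f: np.ndarray, amp: float, center: float, sd: float) -> np.ndarray:
    return amp * np.exp(-((f - center) ** 2) / (2.0 * sd**2))


def fit_gaussian_spectrum(spectrum: PowerSpectrum, use_normalized: bool = False) -> GaussFitResult:
    """Least-squares single-Gaussian fit to the non-DC spectrum.

    Initialization: center at the power maximum, amplitude at the
    maximum, width from the half-power half-width. The fitted width is
    bounded below by three frequency bins: an unconstrained fit of a
    noise (flat) spectrum collapses onto its single highest bin, and a
    three-bin floor keeps such spurious narrow peaks out while leaving
    genuine oscillation lines (a burst of tens of seconds spans several
    bins) essentially untouched. The weighted mean error is the squared
    residual weighted by power. A fit that does not converge within the
    bounded iteration budget is returned as a missing-flagged result,
    which downstream consumers treat as NaN.
    """
    if use_normalized:
        if spectrum.normalized_power is None:
            return GaussFitResult.failed()
        p = spectrum.normalized_power[1:]
    else:
        p = spectrum.power[1:]
    f = spectrum.frequencies[1:]
    if f.size < 4 or not np.any(p > 0):
        return GaussFitResult.failed()
    df = float(f[1] - f[0])
    k = int(np.argmax(p))
    amp0 = float(p[k])
    c0 = float(f[k])
    above = p >= amp0 / 2.0
    # Half-power half-width around the maximum.
    lo = k
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = k
    while hi < p.size - 1 and above[hi + 1]:
        hi += 1
    sd_floor = 3.0 * df
    sd0 = max(sd_floor, (f[hi] - f[lo]) / 2.0)
    try:
        popt, _ = curve_fit(
            _gauss,
            f,
            p,
            p0=[amp0, c0, sd0],
            bounds=([0.0, f[0] - df, sd_floor], [np.inf, f[-1] + df, 10.0 * (f[-1] - f[0])]),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return GaussFitResult.failed()
    amp, center, sd = map(float, popt)
    resid = p - _gauss(f, amp, center, sd)
    wme = float(np.sum(p * resid**2) / np.sum(p))
    return GaussFitResult(center=center, sd=sd, amplitude=amp, weighted_mean_error=wme)


# ---------------------------------------------------------------------------
# The feature vector


@dataclass
class FeatureVector:
    """The 27 named descriptors of one trace.

    ``expFitCoeff`` is a length-9 vector (order-8 power-series
    coefficients in rescaled time); everything else is scalar. Undefined
    descriptors are NaN.
    """

    well_id: str
    cell_id: int
    values: dict[str, float | np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float | np.ndarray:
        return self.values[name]

    def to_row(self) -> dict[str, float]:
        """Flat numeric mapping with expFitCoeff expanded into 9 columns."""
        row: dict[str, float] = {}
        coeff = np.asarray(self.values["expFitCoeff"], dtype=float)
        for i in range(9):
            row[f"expFitCoeff_{i}"] = float(coeff[i]) if i < coeff.size else float("nan")
        for name in FEATURE_NAMES:
            if name == "expFitCoeff":
                continue
            row[name] = float(self.values[name])
        return row


def _spectral_moments(freqs: np.ndarray, power: np.ndarray) -> dict[str, float]:
    """amp / peak-location / mean / median / SD of the non-DC power vector."""
    p = power[1:]
    f = freqs[1:]
    k = int(np.argmax(p))
    return {
        "amp": float(p[k]),
        "peak_freq": float(f[k]),
        "mean": float(p.mean()),
        "median": float(np.median(p)),
        "sd": float(p.std()),
    }


def _large_peak(fit8: PolyFitResult, fs: float, width: int = 50, threshold: float = 50.0):
    """Large-peak count and (valley -> peak) amplitude/time descriptors.

    Primary route: prominence peaks of the order-8 fitted curve. A
    sustained rise to a plateau has no prominence peak at all, yet it is
    exactly the macropore signature this descriptor must capture, so
    when no prominence peak exists but the fitted curve ends at least
    ``threshold`` above its start, the sustained rise is counted as one
    large peak at the curve's maximum with the preceding minimum as its
    valley.
    """
    yf = fit8.fitted_values
    peaks = detect_peaks(yf, width, threshold)
    if peaks.count > 0:
        p = int(peaks.indices[0])
        v = int(np.argmin(yf[: p + 1]))
        return peaks.count, float(yf[p] - yf[v]), (p - v) / fs
    if yf[-1] - yf[0] >= threshold:
        p = int(np.argmax(yf))
        v = int(np.argmin(yf[: p + 1])) if p > 0 else 0
        return 1, float(yf[p] - yf[v]), (p - v) / fs
    return 0, float("nan"), float("nan")


def extract_features(trace: TraceSeries) -> FeatureVector:
    """Compute all 27 descriptors of one trace.

    Small-peak counts use the order-25 fit residual restricted to the
    first and last 90 s (180 samples at the nominal 2 Hz, counted as
    frames regardless of exposure time); the large-peak descriptors use
    the order-8 fitted curve; spectral descriptors come from the raw and
    total-power-normalized spectra and their Gaussian fits; dF, meanF,
    medF, SDF and Variance come directly from the trace.
    """
    y = trace.values
    fs = trace.sampling_rate
    nan = float("nan")

    fit8 = fit_polynomial(y, 8)
    fit25 = fit_polynomial(y, 25)
    resid25 = y - fit25.fitted_values

    n90 = int(round(90.0 * fs))
    first = resid25[:n90]
    last = resid25[-n90:] if n90 <= resid25.size else resid25
    n_first = detect_peaks(first, 3, 3.0).count
    n_last = detect_peaks(last, 3, 3.0).count

    lge, dfp, dtp = _large_peak(fit8, fs)

    spec = power_spectrum(y, fs)
    if spec.defined:
        raw = _spectral_moments(spec.frequencies, spec.power)
        nrm = _spectral_moments(spec.frequencies, spec.normalized_power)
        g_raw = fit_gaussian_spectrum(spec, use_normalized=False)
        g_nrm = fit_gaussian_spectrum(spec, use_normalized=True)
    else:
        # A constant trace has an identically zero raw spectrum: its
        # moments are genuinely 0, while the peak location, the
        # normalized spectrum and the Gaussian fits are undefined.
        raw = {"amp": 0.0, "peak_freq": nan, "mean": 0.0, "median": 0.0, "sd": 0.0}
        nrm = {"amp": nan, "peak_freq": nan, "mean": nan, "median": nan, "sd": nan}
        g_raw = g_nrm = GaussFitResult.failed()

    values: dict[str, float | np.ndarray] = {
        "1stSmlPk": float(n_first),
        "2ndSmlPk": float(n_last),
        "ampNormPS": nrm["amp"],
        "ampPS": raw["amp"],
        "dF": float(y[-1] - y[0]),
        "dFP": dfp,
        "dTP": dtp,
        "expFitCoeff": fit8.coefficients,
        "expFitErr": fit8.mse,
        "gauCentrNormPS": g_nrm.center if g_nrm.success else nan,
        "gauCentrPS": g_raw.center if g_raw.success else nan,
        "gauNormRes": g_nrm.weighted_mean_error if g_nrm.success else nan,
        "gauNormSD": g_nrm.sd if g_nrm.success else nan,
        "gauRes": g_raw.weighted_mean_error if g_raw.success else nan,
        "gauSD": g_raw.sd if g_raw.success else nan,
        "lgePk": float(lge),
        "meanF": float(y.mean()),
        "meanNormPS": nrm["mean"],
        "meanPS": raw["mean"],
        "medF": float(np.median(y)),
        "medNormPS": nrm["median"],
        "medPS": raw["median"],
        "peakPS": raw["peak_freq"],
        "SDF": float(y.std()),
        "SDNormPS": nrm["sd"],
        "SDPS": raw["sd"],
        "Variance": float(y.var()),
    }
    return FeatureVector(trace.well_id, trace.cell_id, values)


def features_frame(traces: list[TraceSeries]):
    """Feature table for a list of traces: one row per cell.

    Returns a pandas DataFrame keyed by (well_id, cell_id) with the 35
    numeric descriptor columns (expFitCoeff expanded).
    """
    import pandas as pd

    rows = []
    for tr in traces:
        fv = extract_features(tr)
        row = {"well_id": fv.well_id, "cell_id": fv.cell_id}
        row.update(fv.to_row())
        rows.append(row)
    return pd.DataFrame(rows, columns=["well_id", "cell_id", *NUMERIC_COLUMNS])
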