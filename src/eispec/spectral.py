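"""Spectral analysis of simulated field potentials and BOLD series.

Welch power spectra, piecewise aperiodic (1/f) slope fits over the 1-30 Hz
and 30-100 Hz bands, band-limited power time courses, time-lagged
LFP-power-to-BOLD correlations, and the fractional amplitude of
low-frequency fluctuations (fALFF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "PSDEstimate",
    "SlopeFit",
    "BandPowerSeries",
    "LagCorrelation",
    "welch_psd",
    "fit_piecewise_slopes",
    "band_power_timecourse",
    "lagged_band_bold_correlation",
    "compute_falff",
]

BANDS: Dict[str, Tuple[float, float]] = {
    "alpha": (8.0, 12.0),
    "beta": (15.0, 30.0),
    "gamma": (40.0, 100.0),
    "total": (0.0, 100.0),
}


@dataclass
class PSDEstimate:
    freqs: np.ndarray
    power: np.ndarray
    n_segments: int
    overlap: float


@dataclass
class SlopeFit:
    slope_low: float
    slope_high: float
    intercept_low: float
    intercept_high: float
    r2_low: float
    r2_high: float
    range_low: Tuple[float, float] = (1.0, 30.0)
    range_high: Tuple[float, float] = (30.0, 100.0)


@dataclass
class BandPowerSeries:
    band: Tuple[float, float]
    times: np.ndarray
    power: np.ndarray
    rate: float


@dataclass
class LagCorrelation:
    lags: np.ndarray
    r: Dict[str, np.ndarray]
    peak_lag: Dict[str, float] = field(default_factory=dict)
    peak_r: Dict[str, float] = field(default_factory=dict)


def welch_psd(
    series: np.ndarray,
    rate: float,
    n_segments: int = 10,
    overlap: float = 0.5,
) -> PSDEstimate:
    """Averaged-periodogram PSD, splitting the series into ``n_segments``
    Hamming-tapered segments with the given fractional overlap."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = series.size
    if n < n_segments:
        raise ValueError("series shorter than the requested segment count")
    # n_segments segments with fractional overlap o cover
    # nperseg * (n_segments * (1 - o) + o) samples
    nperseg = int(n / (n_segments * (1.0 - overlap) + overlap))
    nperseg = max(8, nperseg)
    freqs, power = sp_signal.welch(
        series,
        fs=rate,
        window="hamming",
        nperseg=min(nperseg, n),
        noverlap=int(min(nperseg, n) * overlap),
        detrend="constant",
    )
    return PSDEstimate(freqs=freqs, power=power, n_segments=n_segments, overlap=overlap)


def _loglog_fit(freqs, power, lo, hi):
    mask = (freqs >= lo) & (freqs <= hi) & (power > 0)
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 usable PSD bins in [{lo}, {hi}] Hz")
    x = np.log10(freqs[mask])
    y = np.log10(power[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


def fit_piecewise_slopes(
    psd: PSDEstimate,
    low: Tuple[float, float] = (1.0, 30.0),
    high: Tuple[float, float] = (30.0, 100.0),
) -> SlopeFit:
    """Two least-squares lines in (log10 f, log10 P): the aperiodic slope of
    the low- (default 1-30 Hz) and high-frequency (30-100 Hz) regions."""
    s_lo, i_lo, r2_lo = _loglog_fit(psd.freqs, psd.power, *low)
    s_hi, i_hi, r2_hi = _loglog_fit(psd.freqs, psd.power, *high)
    return SlopeFit(
        slope_low=float(s_lo),
        slope_high=float(s_hi),
        intercept_low=float(i_lo),
        intercept_high=float(i_hi),
        r2_low=float(r2_lo),
        r2_high=float(r2_hi),
        range_low=low,
        range_high=high,
    )


def band_power_timecourse(
    series: np.ndarray,
    rate: float,
    band: Tuple[float, float],
    window_s: float = 1.0,
    step_s: float = 0.5,
) -> BandPowerSeries:
    """Band-integrated power per sliding window, timestamped at window
    centers.  Windows are Hamming-tapered; power integrates the windowed
    periodogram over the band."""
    series = np.asarray(series, dtype=float)
    f_lo, f_hi = band
    if f_hi > rate / 2:
        raise ValueError("band extends above the Nyquist frequency")
    if f_lo > 0 and window_s < 2.0 / f_lo:
        raise ValueError("window too short to resolve the band's lower edge")
    nperseg = int(round(window_s * rate))
    step = int(round(step_s * rate))
    freqs, times, sxx = sp_signal.spectrogram(
        series,
        fs=rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg - step,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    df = freqs[1] - freqs[0]
    power = sxx[mask].sum(axis=0) * df
    return BandPowerSeries(band=band, times=times, power=power, rate=1.0 / step_s)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def lagged_band_bold_correlation(
    lfp,
    bold,
    bands: Optional[Dict[str, Tuple[float, float]]] = None,
    max_lag_s: float = 10.0,
    window_s: float = 1.0,
    step_s: float = 0.5,
) -> LagCorrelation:
    """Pearson correlation between LFP band-power time courses and the BOLD
    series, as a function of the (non-negative) lag of BOLD behind the LFP.

    ``lfp`` and ``bold`` carry ``samples`` and ``rate`` attributes and are
    assumed to cover the same interval.  Band power is resampled to the
    BOLD rate by linear interpolation.  Lags with fewer than 10 overlapping
    samples are omitted with a warning.
    """
    if bands is None:
        bands = {k: v for k, v in BANDS.items() if k != "total"}
    bold_rate = bold.rate
    n_bold = len(bold.samples)
    t_bold = np.arange(n_bold) / bold_rate
    lag_step = 1.0 / bold_rate
    n_lags = int(max_lag_s / lag_step) + 1
    lags = np.arange(n_lags) * lag_step

    r: Dict[str, np.ndarray] = {}
    peak_lag: Dict[str, float] = {}
    peak_r: Dict[str, float] = {}
    kept_mask = None
    for name, band in bands.items():
        bp = band_power_timecourse(lfp.samples, lfp.rate, band, window_s, step_s)
        bp_on_bold = np.interp(t_bold, bp.times, bp.power)
        rr = np.full(n_lags, np.nan)
        for k in range(n_lags):
            x = bp_on_bold[: n_bold - k]
            y = np.asarray(bold.samples)[k:]
            if x.size < 10:
                continue
            rr[k] = _pearson(x, y)
        valid = np.isfinite(rr)
        if not valid.all():
            warnings.warn("some lags omitted: fewer than 10 overlapping samples")
        kept_mask = valid if kept_mask is None else (kept_mask & valid)
        r[name] = rr
        best = int(np.nanargmax(rr))
        peak_lag[name] = float(lags[best])
        peak_r[name] = float(rr[best])
    return LagCorrelation(lags=lags, r=r, peak_lag=peak_lag, peak_r=peak_r)


def compute_falff(
    bold,
    low_band: Tuple[float, float] = (0.01, 0.08),
    total_band: Tuple[float, float] = (0.0, 0.25),
) -> float:
    """Fractional amplitude of low-frequency fluctuations: the sum of
    spectral amplitudes inside ``low_band`` over the sum inside
    ``total_band`` (DC excluded), in [0, 1]."""
    samples = np.asarray(bold.samples, dtype=float)
    rate = bold.rate
    if rate < 2 * total_band[1]:
        raise ValueError("sampling rate below twice the total band's upper edge")
    freqs, power = sp_signal.periodogram(samples, fs=rate, detrend="constant")
    amplitude = np.sqrt(power)
    lo = (freqs >= low_band[0]) & (freqs <= low_band[1])
    tot = (freqs > max(total_band[0], 0.0)) & (freqs <= total_band[1]) & (freqs > 0)
    if not lo.any() or not tot.any():
        raise ValueError("empty frequency band for fALFF")
    denom = amplitude[tot].sum()
    if denom == 0:
        raise ValueError("zero total spectral amplitude")
    return float(amplitude[lo & tot].sum() / denom)
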