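"""Standard time- and frequency-domain pulse-rate-variability indices.

Time domain: Mean, SDNN (population form, 1/N), RMSSD, PNN50 (percentage of
successive differences exceeding 50 ms) and CV = SDNN/Mean.  Frequency domain:
the interval tachogram is resampled evenly by cubic spline, mean-removed, fit
with a Burg autoregressive model, and the AR spectrum is integrated over the
low-frequency (0.04–0.15 Hz) and high-frequency (0.15–0.4 Hz) bands; LF/HF is
their ratio, the classic sympathovagal-balance proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from statsmodels.regression.linear_model import burg as _burg

from .preprocess import PPISeries

__all__ = ["HRVIndices", "time_domain", "frequency_domain", "hrv_indices", "LF_BAND", "HF_BAND"]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass
class HRVIndices:
    """Per-epoch indices; fields are NaN until the corresponding domain is run."""

    mean_s: float = math.nan
    sdnn_s: float = math.nan
    rmssd_s: float = math.nan
    pnn50: float = math.nan
    cv: float = math.nan
    lf: float = math.nan
    hf: float = math.nan
    lf_hf: float = math.nan


def time_domain(ppi: PPISeries) -> HRVIndices:
    """Mean, SDNN, RMSSD, PNN50 and CV of one epoch.

    SDNN uses the population normaliser 1/N; RMSSD averages the N-1 squared
    successive differences; PNN50 counts |successive difference| > 50 ms as a
    percentage of the N-1 pairs.
    """
    x = ppi.intervals if isinstance(ppi, PPISeries) else np.asarray(ppi, float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two intervals for time-domain indices")
    mean = float(x.mean())
    sdnn = float(np.sqrt(np.mean((x - mean) ** 2)))
    d = np.diff(x)
    rmssd = float(np.sqrt(np.sum(d**2) / (n - 1)))
    pnn50 = float(100.0 * np.count_nonzero(np.abs(d) > 0.050) / (n - 1))
    return HRVIndices(
        mean_s=mean, sdnn_s=sdnn, rmssd_s=rmssd, pnn50=pnn50, cv=sdnn / mean
    )


def _ar_psd(rho: np.ndarray, sigma2: float, fs: float, nfreq: int = 16385):
    # A dense grid matters: AR spectra of near-periodic tachograms have very
    # narrow peaks whose band mass a coarse grid undersamples.
    """One-sided AR power spectral density on a uniform frequency grid."""
    freqs = np.linspace(0.0, fs / 2.0, nfreq)
    k = np.arange(1, len(rho) + 1)
    # A(f) = 1 - sum_k rho_k exp(-2 pi i f k / fs)
    a = 1.0 - np.exp(-2j * np.pi * np.outer(freqs, k) / fs) @ rho
    psd = 2.0 * sigma2 / fs / np.abs(a) ** 2
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[mask], freqs[mask]))


def frequency_domain(
    ppi: PPISeries,
    ar_order: int = 16,
    resample_hz: float = 4.0,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    nfreq: int = 16385,
) -> HRVIndices:
    """LF and HF band powers (s^2) and LF/HF from a Burg AR spectrum.

    The tachogram (interval value at the beat's cumulative time) is resampled
    at ``resample_hz`` by cubic spline and mean-removed before the AR fit.
    LF/HF is NaN when the HF power is numerically zero.  Requires at least
    60 s of data.
    """
    x = ppi.intervals
    if ppi.duration_s < 60.0:
        raise ValueError("need at least 60 s of intervals for spectral indices")
    t = np.cumsum(x)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    even = CubicSpline(t, x)(grid)
    even = even - even.mean()
    rho, sigma2 = _burg(even, order=ar_order)
    freqs, psd = _ar_psd(rho, float(sigma2), resample_hz, nfreq=nfreq)
    lf = band_power(freqs, psd, lf_band)
    hf = band_power(freqs, psd, hf_band)
    lf_hf = lf / hf if hf > 1e-15 else math.nan
    return HRVIndices(lf=lf, hf=hf, lf_hf=lf_hf)


def hrv_indices(ppi: PPISeries, ar_order: int = 16, resample_hz: float = 4.0) -> HRVIndices:
    """All time- and frequency-domain indices of one epoch."""
    td = time_domain(ppi)
    fd = frequency_domain(ppi, ar_order=ar_order, resample_hz=resample_hz)
    td.lf, td.hf, td.lf_hf = fd.lf, fd.hf, fd.lf_hf
    return td
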