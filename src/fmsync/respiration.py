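"""ECG-derived respiration (EDR) from the maternal tachogram.

Respiratory sinus arrhythmia modulates the maternal heart rate at the
breathing frequency, so the beat-to-beat HR series carries a spectral
line at the respiration rate.  The estimator interpolates the HR values
(one per RR interval) onto a uniform grid with a cubic spline, removes
the mean, and reads the respiration frequency off the FFT magnitude
spectrum as the in-band (0.1–0.5 Hz) argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.interpolate import CubicSpline

from .preprocess import RRSeries

__all__ = ["EdrWaveform", "RespirationEstimate", "edr_waveform", "estimate_resp_rate"]

RESP_BAND_HZ = (0.1, 0.5)


@dataclass
class EdrWaveform:
    """Mean-removed, uniformly resampled HR fluctuation (bpm deviations)."""

    times: np.ndarray
    values: np.ndarray
    resample_hz: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass
class RespirationEstimate:
    freq_hz: float
    rate_cpm: float
    peak_power_fraction: float
    low_confidence: bool
    band_hz: tuple = RESP_BAND_HZ

    def to_dict(self) -> dict:
        return {
            "freq_hz": self.freq_hz,
            "rate_cpm": self.rate_cpm,
            "peak_power_fraction": self.peak_power_fraction,
            "low_confidence": self.low_confidence,
        }


def edr_waveform(rr: RRSeries, resample_hz: float = 4.0) -> EdrWaveform:
    """Cubic-spline resampling of the tachogram HR onto a uniform grid.

    4 Hz is the conventional HRV resampling rate: at least 8x the upper
    band edge of interest (0.5 Hz).  Only the mean is removed; the RSA
    line survives untouched.
    """
    if len(rr) < 4:
        raise ValueError("need at least 4 RR intervals for cubic-spline EDR")
    hr = 60000.0 / rr.rr
    t = rr.onset_times
    spline = CubicSpline(t, hr)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    values = spline(grid)
    return EdrWaveform(times=grid, values=values - values.mean(), resample_hz=resample_hz)


def estimate_resp_rate(
    edr: EdrWaveform,
    band_hz: tuple = RESP_BAND_HZ,
    zero_pad_factor: int = 4,
    low_confidence_fraction: float = 0.1,
) -> RespirationEstimate:
    """In-band FFT argmax of the EDR spectrum.

    Zero-padding refines the frequency grid to <= 1/(pad x span) Hz; the
    respiration frequency is the magnitude-spectrum argmax restricted to
    the 0.1-0.5 Hz band.  ``peak_power_fraction`` (peak-bin power over
    total in-band power) gauges how line-like the spectrum is; a flat
    spectrum makes the argmax meaningless and sets the low-confidence
    flag.
    """
    if edr.span < 60.0:
        raise ValueError("EDR span below 60 s: frequency resolution too coarse")
    n = len(edr.values)
    nfft = int(2 ** np.ceil(np.log2(max(zero_pad_factor * n, 2))))
    mag = np.abs(rfft(edr.values, n=nfft))
    freqs = rfftfreq(nfft, d=1.0 / edr.resample_hz)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    band_mag = mag[in_band]
    band_freqs = freqs[in_band]
    peak_idx = int(np.argmax(band_mag))
    freq = float(band_freqs[peak_idx])
    power = band_mag**2
    total = float(power.sum())
    frac = float(power[peak_idx] / total) if total > 0 else 0.0
    return RespirationEstimate(
        freq_hz=freq,
        rate_cpm=60.0 * freq,
        peak_power_fraction=frac,
        low_confidence=frac < low_confidence_fraction,
    )
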