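"""ECG preprocessing: baseline removal, normalization, R-peak detection,
RR/HR series, and 3-minute segmentation.

The pipeline assumes already-separated single-channel maternal and fetal
ECG streams (abdominal-signal source separation happens upstream of this
package).  Raw samples are high-pass filtered at 5 Hz to remove baseline
wander, normalized to unit peak amplitude, and R peaks are picked with an
adaptive threshold that follows the local signal amplitude.  Beat trains
are then converted to RR-interval (ms) and instantaneous heart-rate (bpm)
series and cut into non-overlapping 180 s analysis segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d

__all__ = [
    "EcgRecord",
    "BeatTimes",
    "RRSeries",
    "HRSeries",
    "Segment",
    "LowQualityError",
    "highpass_baseline",
    "normalize_amplitude",
    "detect_r_peaks",
    "beats_to_rr",
    "rr_to_hr",
    "segment_record",
    "rr_range_flags",
    "read_beats_csv",
    "write_beats_csv",
    "read_waveform_csv",
    "write_waveform_csv",
]

ROLES = ("maternal", "fetal")

#: role-dependent minimum R-R separation (s), from physiological rate ceilings
#: (maternal ~180 bpm, fetal ~300 bpm, with margin)
MIN_PEAK_SEPARATION_S = {"maternal": 0.33, "fetal": 0.2}

#: physiological RR plausibility ranges (ms) used for quality flagging
RR_RANGE_MS = {"maternal": (300.0, 1500.0), "fetal": (200.0, 600.0)}

SEGMENT_LENGTH_S = 180.0


class LowQualityError(ValueError):
    """Raised when a record yields too few beats to be analyzable."""


def _check_role(role: str) -> str:
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}, got {role!r}")
    return role


@dataclass
class EcgRecord:
    """Uniformly sampled single-channel ECG."""

    samples: np.ndarray
    fs: float
    role: str = "maternal"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError("fs must be a positive finite sampling rate")
        _check_role(self.role)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class BeatTimes:
    """Strictly increasing R-peak occurrence times (s) for one heart."""

    times: np.ndarray
    role: str = "maternal"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("beat times must be finite")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("beat times must be strictly increasing")
        _check_role(self.role)

    def __len__(self) -> int:
        return len(self.times)

    def clipped(self, t_start: float, t_end: float) -> "BeatTimes":
        """Beats within the half-open window [t_start, t_end)."""
        mask = (self.times >= t_start) & (self.times < t_end)
        return replace(self, times=self.times[mask])


@dataclass
class RRSeries:
    """RR intervals (ms), each anchored at the onset (earlier) beat."""

    onset_times: np.ndarray
    rr: np.ndarray  # milliseconds

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.onset_times.shape != self.rr.shape:
            raise ValueError("onset_times and rr must have equal length")
        if np.any(self.rr <= 0):
            raise ValueError("RR intervals must be positive")

    def __len__(self) -> int:
        return len(self.rr)


@dataclass
class HRSeries:
    """Instantaneous heart rate (bpm), one value per RR interval or sample."""

    times: np.ndarray
    hr: np.ndarray  # bpm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.times.shape != self.hr.shape:
            raise ValueError("times and hr must have equal length")
        if not np.all(np.isfinite(self.hr)):
            raise ValueError("heart rate values must be finite")

    def __len__(self) -> int:
        return len(self.hr)


@dataclass
class Segment:
    """One 180 s analysis window carrying both beat channels."""

    subject_id: str
    index: int
    t_start: float
    t_end: float
    maternal: BeatTimes
    fetal: BeatTimes

    def __post_init__(self) -> None:
        if not np.isclose(self.t_end - self.t_start, SEGMENT_LENGTH_S):
            raise ValueError("segments must be exactly 180 s long")


def highpass_baseline(
    record: EcgRecord, cutoff_hz: float = 5.0, order: int = 4
) -> EcgRecord:
    """Zero-phase Butterworth high-pass to remove baseline wander.

    Zero-phase (forward-backward) filtering is used so R-peak times are
    not lag-shifted by the filter.
    """
    if record.duration < 1.0:
        raise ValueError("record shorter than 1 s cannot be filtered reliably")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=record.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, record.samples)
    return replace(record, samples=filtered)


def normalize_amplitude(record: EcgRecord) -> EcgRecord:
    """Divide by the maximum absolute amplitude so max |sample| == 1."""
    peak = float(np.max(np.abs(record.samples)))
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero record")
    return replace(record, samples=record.samples / peak)


def detect_r_peaks(
    record: EcgRecord,
    role: str | None = None,
    threshold_frac: float = 0.4,
    threshold_window_s: float = 2.0,
    min_separation_s: float | None = None,
) -> BeatTimes:
    """Adaptive-threshold R-peak detection.

    A candidate local maximum counts as an R peak when it exceeds
    ``threshold_frac`` times the rolling maximum of the signal over a
    ``threshold_window_s`` window (the threshold tracks varying R-peak
    amplitude), and is separated from the previous peak by at least the
    role-dependent physiological minimum.
    """
    role = _check_role(role or record.role)
    if min_separation_s is None:
        min_separation_s = MIN_PEAK_SEPARATION_S[role]
    x = record.samples
    win = max(3, int(round(threshold_window_s * record.fs)))
    rolling_max = maximum_filter1d(x, size=win, mode="nearest")
    height = threshold_frac * np.maximum(rolling_max, 1e-12)
    distance = max(1, int(round(min_separation_s * record.fs)))
    peaks, _ = signal.find_peaks(x, height=height, distance=distance)
    # quality gate: scale the 10-peaks-per-3-min floor to the record length
    min_peaks = max(2, int(np.ceil(10.0 * record.duration / 180.0)))
    if len(peaks) < min_peaks:
        raise LowQualityError(
            f"only {len(peaks)} peaks detected in {record.duration:.0f} s "
            f"(need >= {min_peaks})"
        )
    return BeatTimes(peaks / record.fs, role=role, subject_id=record.subject_id)


def beats_to_rr(beats: BeatTimes) -> RRSeries:
    """RR intervals in milliseconds, anchored at the onset beat."""
    if len(beats) < 2:
        raise ValueError("need at least 2 beats to form RR intervals")
    rr_ms = np.diff(beats.times) * 1000.0
    return RRSeries(onset_times=beats.times[:-1], rr=rr_ms)


def rr_to_hr(rr: RRSeries) -> HRSeries:
    """Instantaneous HR (bpm) per RR interval: hr = 60000 / rr_ms."""
    return HRSeries(times=rr.onset_times, hr=60000.0 / rr.rr)


def rr_range_flags(rr: RRSeries, role: str) -> np.ndarray:
    """Boolean mask of RR intervals outside the physiological range.

    Out-of-range intervals are flagged for review, never silently dropped.
    """
    lo, hi = RR_RANGE_MS[_check_role(role)]
    return (rr.rr < lo) | (rr.rr > hi)


def segment_record(
    maternal: BeatTimes,
    fetal: BeatTimes,
    segment_s: float = SEGMENT_LENGTH_S,
) -> list[Segment]:
    """Cut the common time support into consecutive non-overlapping 180 s windows.

    Windows are anchored at the start of the common support; the trailing
    remainder shorter than one window is discarded.  Window membership is
    half-open, so no beat appears in two segments.
    """
    if len(maternal) == 0 or len(fetal) == 0:
        warnings.warn("empty beat train: no segments", stacklevel=2)
        return []
    lo = max(maternal.times[0], fetal.times[0])
    hi = min(maternal.times[-1], fetal.times[-1])
    n_seg = int(np.floor((hi - lo) / segment_s + 1e-9))
    if n_seg < 1:
        warnings.warn(
            f"common support {hi - lo:.1f} s is shorter than one "
            f"{segment_s:.0f} s segment",
            stacklevel=2,
        )
        return []
    segments = []
    subject = maternal.subject_id or fetal.subject_id
    for i in range(n_seg):
        t0 = lo + i * segment_s
        t1 = t0 + segment_s
        # include a beat landing exactly on the final boundary in the last window
        m_clip = maternal.clipped(t0, t1)
        f_clip = fetal.clipped(t0, t1)
        segments.append(
            Segment(
                subject_id=subject,
                index=i,
                t_start=t0,
                t_end=t1,
                maternal=m_clip,
                fetal=f_clip,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# CSV interfaces (UTF-8, header row, '.' decimal separator)
# ---------------------------------------------------------------------------


def write_beats_csv(beats: BeatTimes, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"subject_id": beats.subject_id, "time_s": beats.times}
    ).to_csv(path, index=False)


def read_beats_csv(path, role: str = "maternal") -> BeatTimes:
    import pandas as pd

    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: expected a 'time_s' column")
    subject = str(df["subject_id"].iloc[0]) if "subject_id" in df.columns and len(df) else ""
    return BeatTimes(df["time_s"].to_numpy(float), role=role, subject_id=subject)


def write_waveform_csv(record: EcgRecord, path) -> None:
    import pandas as pd

    pd.DataFrame({"time_s": record.times, "amplitude": record.samples}).to_csv(
        path, index=False
    )


def read_waveform_csv(path, role: str = "maternal", subject_id: str = "") -> EcgRecord:
    import pandas as pd

    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: waveform too short")
    dt = np.median(np.diff(t))
    return EcgRecord(
        df["amplitude"].to_numpy(float), fs=1.0 / dt, role=role, subject_id=subject_id
    )
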