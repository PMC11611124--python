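"""Fetal behavioral state (quiet vs active) from 3-minute fetal HR segments.

Before ~32 weeks of gestation the four canonical fetal states (1F-4F)
cannot be told apart, so the classification collapses to quiet (1F+3F)
vs active (2F+4F).  A segment is *quiet* only when all three heart-rate
pattern criteria hold:

    baseline < 160 bpm, oscillation bandwidth < 7.5 bpm, no accelerations
    (> 15 bpm above baseline sustained >= the minimum duration)

Any violated criterion makes the segment *active*; boundary values
(baseline exactly 160, bandwidth exactly 7.5) classify active, matching
the strict quiet inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .preprocess import HRSeries

__all__ = [
    "StateCriteria",
    "Acceleration",
    "StateLabel",
    "estimate_baseline",
    "oscillation_bandwidth",
    "detect_accelerations",
    "classify_state",
]


@dataclass(frozen=True)
class StateCriteria:
    """Quiet/active decision thresholds (bpm, s)."""

    baseline_cut: float = 160.0
    band_cut: float = 7.5
    accel_cut: float = 15.0
    accel_min_duration: float = 10.0
    accel_merge_gap: float = 2.0

    def __post_init__(self) -> None:
        for name in ("baseline_cut", "band_cut", "accel_cut", "accel_min_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Acceleration:
    onset: float
    duration: float
    peak_excess: float  # bpm above baseline


@dataclass
class StateLabel:
    state: str  # 'quiet' | 'active'
    baseline: float
    bandwidth: float
    n_accelerations: int
    criteria_fired: tuple = ()
    accelerations: tuple = ()


#: running-median window (s) for the acceleration-exclusion pass; long
#: relative to acceleration durations so bumps do not drag the local median
_BASELINE_MEDIAN_WINDOW_S = 60.0


def _running_median(hr: HRSeries, window_s: float) -> np.ndarray:
    dt = np.median(np.diff(hr.times)) if len(hr) > 1 else 1.0
    size = max(3, int(round(window_s / max(dt, 1e-6))))
    size = min(size, len(hr.hr) if len(hr.hr) % 2 else len(hr.hr) - 1)
    if size % 2 == 0:
        size += 1
    return median_filter(hr.hr, size=max(size, 3), mode="nearest")


def estimate_baseline(hr: HRSeries, accel_excess: float = 15.0) -> float:
    """Acceleration-excluded median fetal HR.

    Two passes break the circularity between baseline estimation and
    acceleration detection: samples exceeding a long-window running
    median by more than ``accel_excess`` bpm are excluded, and the
    baseline is the plain median of the rest.
    """
    if len(hr) < 30:
        raise ValueError("need at least 30 HR samples for a baseline estimate")
    if hr.times[-1] - hr.times[0] < 60.0:
        raise ValueError("need at least 60 s of HR data for a baseline estimate")
    runmed = _running_median(hr, _BASELINE_MEDIAN_WINDOW_S)
    keep = hr.hr <= runmed + accel_excess
    values = hr.hr[keep] if keep.any() else hr.hr
    return float(np.median(values))


def oscillation_bandwidth(hr: HRSeries, baseline: float) -> float:
    """Robust peak deviation of HR from baseline (bpm).

    bandwidth = max(p97.5(hr − baseline), −p2.5(hr − baseline)) on
    acceleration-excluded samples; the +/-7.5 bpm quiet envelope then maps
    to bandwidth < 7.5.  Percentiles rather than the raw extremes keep
    single outlier beats from dominating.
    """
    if not np.isfinite(baseline):
        raise ValueError("baseline must be finite")
    dev = hr.hr - baseline
    dev = dev[dev <= 15.0]  # acceleration-range samples excluded
    if len(dev) == 0:
        return 0.0
    hi = float(np.percentile(dev, 97.5))
    lo = float(np.percentile(dev, 2.5))
    return max(hi, -lo, 0.0)


def detect_accelerations(
    hr: HRSeries, baseline: float, criteria: StateCriteria = StateCriteria()
) -> list[Acceleration]:
    """Maximal runs of hr − baseline > accel_cut lasting >= the minimum duration.

    Runs separated by gaps shorter than ``accel_merge_gap`` seconds are
    merged before the duration gate is applied.
    """
    if not np.isfinite(baseline):
        raise ValueError("baseline must be finite")
    above = hr.hr - baseline > criteria.accel_cut
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    for s, e in runs[1:]:
        prev_s, prev_e = merged[-1]
        if hr.times[s] - hr.times[prev_e - 1] < criteria.accel_merge_gap:
            merged[-1] = (prev_s, e)
        else:
            merged.append((s, e))
    events = []
    for s, e in merged:
        duration = float(hr.times[e - 1] - hr.times[s])
        if duration >= criteria.accel_min_duration:
            events.append(
                Acceleration(
                    onset=float(hr.times[s]),
                    duration=duration,
                    peak_excess=float(np.max(hr.hr[s:e] - baseline)),
                )
            )
    return events


def classify_state(hr: HRSeries, criteria: StateCriteria = StateCriteria()) -> StateLabel:
    """Quiet iff baseline, bandwidth, and acceleration criteria all hold.

    The quiet state is a conjunction; any single active criterion makes
    the segment active.  The returned label carries the evidence.
    """
    baseline = estimate_baseline(hr, accel_excess=criteria.accel_cut)
    bandwidth = oscillation_bandwidth(hr, baseline)
    accels = detect_accelerations(hr, baseline, criteria)
    fired = []
    if baseline >= criteria.baseline_cut:
        fired.append("baseline")
    if bandwidth >= criteria.band_cut:
        fired.append("bandwidth")
    if accels:
        fired.append("accelerations")
    return StateLabel(
        state="active" if fired else "quiet",
        baseline=baseline,
        bandwidth=bandwidth,
        n_accelerations=len(accels),
        criteria_fired=tuple(fired),
        accelerations=tuple(accels),
    )
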