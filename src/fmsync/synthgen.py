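"""Synthetic maternal/fetal beat trains, ECG waveforms, and whole cohorts.

All generators are seeded and deterministic.  The beat model is
integrate-and-fire: given an instantaneous heart-rate trajectory HR(t)
(bpm), a beat fires whenever the integral of HR(t)/60 accrues one full
cycle.  Maternal HR carries respiratory sinus arrhythmia (a sinusoid at
the breathing frequency) plus smooth broadband variability; fetal trains
are either phase-locked to the maternal train at one of the studied
[m:n] ratios with von Mises phase jitter, or free-running with a
state-dependent HR profile (baseline + band-limited oscillation +
acceleration bumps).

Cohort generation draws gestational ages per group, chooses the von
Mises concentration κ by inverting the squared Bessel ratio
(I₁(κ)/I₀(κ))² = λ_target, and retains all ground-truth columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .coupling import DEFAULT_WINDOW_BEATS, STUDIED_RATIOS, CouplingRatio
from .preprocess import BeatTimes, EcgRecord, HRSeries

__all__ = [
    "MaternalSimParams",
    "FetalSimParams",
    "CohortSpec",
    "CohortSegment",
    "gen_maternal_beats",
    "gen_fetal_beats_locked",
    "gen_fetal_hr_profile",
    "gen_fetal_beats_free",
    "synthesize_ecg",
    "gen_cohort",
    "bessel_ratio",
    "kappa_for_lambda",
    "write_cohort_csv",
]

#: integration grid for the integrate-and-fire model (Hz)
_GRID_HZ = 200.0
#: knot rate for the smooth broadband HR-variability noise process (Hz)
_NOISE_KNOT_HZ = 2.0
#: grid for free-running fetal HR profiles (Hz)
PROFILE_HZ = 4.0


def _require_finite(**kwargs) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class MaternalSimParams:
    """Maternal beat-train parameters.

    ``rsa_freq`` is the respiration frequency (Hz) the EDR estimator
    should recover; ``rsa_amp`` the peak HR deviation (bpm) of the
    respiratory modulation; ``hrv_noise_sd`` the s.d. (bpm) of the
    smooth non-respiratory variability.
    """

    duration: float = 180.0
    hr_base: float = 80.0
    rsa_freq: float = 0.25
    rsa_amp: float = 2.5
    hrv_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        _require_finite(
            duration=self.duration,
            hr_base=self.hr_base,
            rsa_freq=self.rsa_freq,
            rsa_amp=self.rsa_amp,
            hrv_noise_sd=self.hrv_noise_sd,
        )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 40.0 <= self.hr_base <= 140.0:
            raise ValueError("hr_base must lie in [40, 140] bpm")
        if not 0.0 <= self.rsa_freq <= 1.0:
            raise ValueError("rsa_freq must lie in [0, 1] Hz")
        if self.rsa_amp < 0 or self.hrv_noise_sd < 0:
            raise ValueError("rsa_amp and hrv_noise_sd must be non-negative")


@dataclass(frozen=True)
class FetalSimParams:
    """Fetal generator parameters (locked or free-running mode)."""

    mode: str = "free"  # 'locked' | 'free'
    ratio: CouplingRatio | None = None
    kappa: float = math.inf
    state: str | None = None  # 'quiet' | 'active' (free mode)
    baseline_bpm: float = 140.0
    osc_band_bpm: float = 4.0
    accel_events: tuple = ()  # (onset s, duration s, amplitude bpm)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("locked", "free"):
            raise ValueError("mode must be 'locked' or 'free'")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.baseline_bpm <= 0:
            raise ValueError("baseline_bpm must be positive")
        if self.osc_band_bpm < 0:
            raise ValueError("osc_band_bpm must be >= 0")
        for onset, dur, amp in self.accel_events:
            if amp <= 0 or dur <= 0:
                raise ValueError("acceleration amplitudes and durations must be positive")

    @classmethod
    def quiet_preset(cls, seed: int = 0) -> "FetalSimParams":
        """A randomized quiet-state profile, >= 1 bpm inside every criterion."""
        rng = np.random.default_rng(seed)
        return cls(
            mode="free",
            state="quiet",
            baseline_bpm=float(rng.uniform(120.0, 150.0)),
            osc_band_bpm=float(rng.uniform(2.0, 6.0)),
            accel_events=(),
            seed=seed,
        )

    @classmethod
    def active_preset(cls, seed: int = 0) -> "FetalSimParams":
        """A randomized active profile violating one quiet criterion by >= 1 bpm."""
        rng = np.random.default_rng(seed)
        kind = rng.integers(0, 3)
        baseline = float(rng.uniform(125.0, 150.0))
        osc = float(rng.uniform(2.0, 6.0))
        accels: tuple = ()
        if kind == 0:  # tachycardic baseline
            baseline = float(rng.uniform(161.0, 175.0))
        elif kind == 1:  # wide oscillation band
            osc = float(rng.uniform(9.0, 13.0))
        else:  # acceleration episode
            onset = float(rng.uniform(30.0, 120.0))
            dur = float(rng.uniform(14.0, 25.0))
            amp = float(rng.uniform(18.0, 25.0))
            accels = ((onset, dur, amp),)
        return cls(
            mode="free",
            state="active",
            baseline_bpm=baseline,
            osc_band_bpm=osc,
            accel_events=accels,
            seed=seed,
        )


def _integrate_and_fire(t: np.ndarray, hr_bpm: np.ndarray) -> np.ndarray:
    """Beat times where the integrated rate (beats) crosses each integer."""
    rate = np.maximum(hr_bpm, 1.0) / 60.0  # beats per second
    phase = cumulative_trapezoid(rate, t, initial=0.0)
    n_beats = int(np.floor(phase[-1] + 1e-9))
    return np.interp(np.arange(n_beats + 1, dtype=float), phase, t)


def _smooth_noise(rng, t: np.ndarray, sd: float, knot_hz: float = _NOISE_KNOT_HZ) -> np.ndarray:
    """Band-limited Gaussian process: white knots linearly interpolated."""
    if sd == 0:
        return np.zeros_like(t)
    n_knots = int(np.ceil(t[-1] * knot_hz)) + 2
    knots_t = np.arange(n_knots) / knot_hz
    knots_v = rng.normal(0.0, sd, size=n_knots)
    return np.interp(t, knots_t, knots_v)


def gen_maternal_beats(params: MaternalSimParams, subject_id: str = "") -> BeatTimes:
    """Integrate-and-fire maternal beat train.

    HR(t) = hr_base + rsa_amp·sin(2π·rsa_freq·t) + smooth noise(sd);
    with zero modulation the train is exactly periodic at hr_base.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration + 0.5 / _GRID_HZ, 1.0 / _GRID_HZ)
    hr = params.hr_base + params.rsa_amp * np.sin(2 * np.pi * params.rsa_freq * t)
    hr = hr + _smooth_noise(rng, t, params.hrv_noise_sd)
    beats = _integrate_and_fire(t, hr)
    beats = beats[beats <= params.duration + 1e-9]
    return BeatTimes(beats, role="maternal", subject_id=subject_id)


def maternal_hr_trajectory(params: MaternalSimParams) -> HRSeries:
    """The deterministic + noise HR trajectory used by the beat generator."""
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration + 0.5 / _GRID_HZ, 1.0 / _GRID_HZ)
    hr = params.hr_base + params.rsa_amp * np.sin(2 * np.pi * params.rsa_freq * t)
    hr = hr + _smooth_noise(rng, t, params.hrv_noise_sd)
    return HRSeries(times=t, hr=hr)


def gen_fetal_beats_locked(
    maternal: BeatTimes,
    ratio: CouplingRatio,
    kappa: float = math.inf,
    seed: int = 0,
    subject_id: str = "",
) -> BeatTimes:
    """Fetal beats phase-locked to the maternal train at ratio [m:n].

    Within each consecutive non-overlapping cycle of m maternal beats,
    n fetal beats sit at target relative phases (j + 0.5)/n — centred
    between cycle boundaries so no beat coincides with a boundary — each
    perturbed by von Mises(0, κ) angular noise on the 2πnΨ circle
    (i.e. Ψ ← Ψ + δ/(2πn), δ ~ vM(0, κ), wrapped into the cycle).
    κ = inf means zero jitter.
    """
    if ratio.m <= 0 or ratio.n <= 0:
        raise ValueError("ratio components must be positive")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    mt = maternal.times
    m, n = ratio.m, ratio.n
    if len(mt) < m + 1:
        raise ValueError(f"need at least {m + 1} maternal beats")
    n_cycles = (len(mt) - 1) // m
    bounds = mt[: n_cycles * m + 1 : m]
    starts = bounds[:-1]
    lengths = np.diff(bounds)
    targets = (np.arange(n) + 0.5) / n
    psi = np.tile(targets, (n_cycles, 1))
    if np.isfinite(kappa):
        rng = np.random.default_rng(seed)
        if kappa == 0:
            delta = rng.uniform(-np.pi, np.pi, size=psi.shape)
        else:
            delta = rng.vonmises(0.0, kappa, size=psi.shape)
        psi = (psi + delta / (2 * np.pi * n)) % 1.0
    times = starts[:, None] + psi * lengths[:, None]
    times = np.sort(times.ravel())
    return BeatTimes(times, role="fetal", subject_id=subject_id)


def _accel_bump(t: np.ndarray, onset: float, dur: float, amp: float,
                taper: float = 0.15) -> np.ndarray:
    """Smooth plateau bump: raised-cosine ramps (``taper`` of the duration
    on each side) around a flat top at ``amp``, so the excursion is
    sustained for most of its nominal duration."""
    x = (t - onset) / dur
    bump = np.zeros_like(t)
    inside = (x >= 0) & (x <= 1)
    xi = x[inside]
    shape = np.ones_like(xi)
    rise = xi < taper
    fall = xi > 1 - taper
    shape[rise] = 0.5 * (1 - np.cos(np.pi * xi[rise] / taper))
    shape[fall] = 0.5 * (1 - np.cos(np.pi * (1 - xi[fall]) / taper))
    bump[inside] = amp * shape
    return bump


def gen_fetal_hr_profile(params: FetalSimParams, duration: float) -> HRSeries:
    """Free-running fetal HR trajectory sampled at 4 Hz.

    HR(t) = baseline + a slow sinusoidal oscillation with peak deviation
    ``osc_band_bpm`` (seeded random frequency in the 0.03-0.12 Hz band)
    + smooth plateau acceleration bumps reaching their stated amplitude.
    A single sinusoid is used so the robust (percentile-based) bandwidth
    read off the profile tracks the generative peak deviation.
    """
    if params.mode != "free":
        raise ValueError("HR profiles are defined for free-running mode only")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, duration, 1.0 / PROFILE_HZ)
    hr = np.full_like(t, params.baseline_bpm)
    if params.osc_band_bpm > 0:
        f = rng.uniform(0.03, 0.12)
        phi = rng.uniform(0, 2 * np.pi)
        hr = hr + params.osc_band_bpm * np.sin(2 * np.pi * f * t + phi)
    for onset, dur, amp in params.accel_events:
        hr = hr + _accel_bump(t, onset, dur, amp)
    return HRSeries(times=t, hr=hr)


def gen_fetal_beats_free(
    params: FetalSimParams, duration: float, subject_id: str = ""
) -> BeatTimes:
    """Integrate-and-fire fetal beats from a free-running HR profile."""
    profile = gen_fetal_hr_profile(params, duration)
    t = np.arange(0.0, duration + 0.5 / _GRID_HZ, 1.0 / _GRID_HZ)
    hr = np.interp(t, profile.times, profile.hr)
    beats = _integrate_and_fire(t, hr)
    return BeatTimes(beats[beats <= duration + 1e-9], role="fetal", subject_id=subject_id)


# ---------------------------------------------------------------------------
# ECG waveform synthesis
# ---------------------------------------------------------------------------


def _mexican_hat(t: np.ndarray, width_s: float) -> np.ndarray:
    """Symmetric Mexican-hat (Ricker) QRS template, main lobe ~``width_s``."""
    a = width_s / 4.0  # zero crossings at +/- width/4 around the peak
    x = t / a
    return (1.0 - x**2) * np.exp(-0.5 * x**2)


def synthesize_ecg(
    beats: BeatTimes,
    fs: float = 1000.0,
    qrs_amp: float = 1.0,
    noise_sd: float = 0.0,
    baseline_wander_amp: float = 0.0,
    wander_freq_hz: float = 0.2,
    qrs_width_s: float = 0.04,
    snr_db: float | None = None,
    seed: int = 0,
    duration: float | None = None,
) -> EcgRecord:
    """One QRS-like wavelet per beat + low-frequency wander + white noise.

    If ``snr_db`` is given it overrides ``noise_sd``: the noise standard
    deviation is set so the clean-signal RMS to noise RMS power ratio
    equals ``snr_db``.  No P or T waves are modelled; R-peak detection is
    the only downstream consumer.
    """
    if fs < 250.0:
        raise ValueError("fs below 250 Hz cannot resolve the QRS template")
    if len(beats) == 0:
        raise ValueError("need at least one beat")
    if duration is None:
        duration = float(beats.times[-1]) + 0.5
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    clean = np.zeros(n)
    half = int(round(3 * qrs_width_s * fs))  # template support: +/- 3 widths/4
    tmpl_t = np.arange(-half, half + 1) / fs
    tmpl = qrs_amp * _mexican_hat(tmpl_t, qrs_width_s)
    centers = np.round(beats.times * fs).astype(int)
    for c in centers:
        lo = max(0, c - half)
        hi = min(n, c + half + 1)
        clean[lo:hi] += tmpl[lo - (c - half) : hi - (c - half)]
    wander = baseline_wander_amp * np.sin(2 * np.pi * wander_freq_hz * t)
    if snr_db is not None:
        rms = float(np.sqrt(np.mean(clean**2)))
        noise_sd = rms * 10 ** (-snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    return EcgRecord(clean + wander + noise, fs=fs, role=beats.role, subject_id=beats.subject_id)


# ---------------------------------------------------------------------------
# κ <-> λ calibration and cohort generation
# ---------------------------------------------------------------------------


def bessel_ratio(kappa: float) -> float:
    """Mean resultant length ρ = I₁(κ)/I₀(κ) of a von Mises distribution."""
    if kappa == 0:
        return 0.0
    if np.isinf(kappa):
        return 1.0
    return float(i1e(kappa) / i0e(kappa))


def kappa_for_lambda(
    target_lambda: float, window_beats: int = DEFAULT_WINDOW_BEATS
) -> float:
    """Invert (I₁(κ)/I₀(κ))² = λ_target for the von Mises concentration.

    λ targets at or below the incoherent floor 1/N, or above 1, are
    unreachable and rejected.  λ = 1 maps to the zero-jitter sentinel
    κ = inf.
    """
    floor = 1.0 / window_beats
    if not np.isfinite(target_lambda) or target_lambda > 1.0 or target_lambda <= floor:
        raise ValueError(
            f"target lambda must lie in ({floor:.4f}, 1], got {target_lambda!r}"
        )
    if target_lambda == 1.0:
        return math.inf
    rho_target = math.sqrt(target_lambda)
    hi = 1e6
    if bessel_ratio(hi) < rho_target:
        return math.inf
    return float(brentq(lambda k: bessel_ratio(k) - rho_target, 1e-8, hi, xtol=1e-10))


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort (per-group sizes, GA ranges, λ targets).

    ``lambda_trend`` maps ratio strings ('1:2') to per-group target mean
    λ values; segments are locked at the first ratio listed.  ``state_mix``
    is the fraction of quiet segments per group.
    """

    n_subjects_per_group: int = 30
    ga_ranges: tuple = ((16.0, 25.0), (25.0, 32.0), (32.0, 40.0))
    group_names: tuple = ("Early", "Mid", "Late")
    state_mix: float = 0.5
    lambda_trend: dict = field(
        default_factory=lambda: {"1:2": {"Early": 0.5, "Mid": 0.4, "Late": 0.3}}
    )
    segment_duration: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if len(self.ga_ranges) != 3 or len(self.group_names) != 3:
            raise ValueError("exactly three GA groups are required")
        prev_hi = -np.inf
        for lo, hi in self.ga_ranges:
            if lo >= hi or lo < prev_hi:
                raise ValueError("GA group intervals must be ordered and disjoint")
            prev_hi = hi
        if not 0.0 <= self.state_mix <= 1.0:
            raise ValueError("state_mix must lie in [0, 1]")
        if not self.lambda_trend:
            raise ValueError("lambda_trend must name at least one ratio")
        for ratio_s, per_group in self.lambda_trend.items():
            CouplingRatio.parse(ratio_s)
            for g in self.group_names:
                if g not in per_group:
                    raise ValueError(f"lambda_trend[{ratio_s!r}] missing group {g!r}")


@dataclass
class CohortSegment:
    """One synthetic 3-min segment with full ground truth."""

    subject_id: str
    ga_weeks: float
    group: str
    state_true: str
    ratio: CouplingRatio
    kappa: float
    lambda_target: float
    rsa_freq_hz: float
    maternal: BeatTimes
    fetal: BeatTimes


def _accel_warp(beats: np.ndarray, events, base_hr: float) -> np.ndarray:
    """Compress beat times inside acceleration windows.

    The time warp g with g'(t) = 1/(1 + bump(t)/base_hr) shortens local
    inter-beat intervals so the instantaneous HR rises by the bump
    amplitude, leaving phases outside the window shifted by a constant.
    """
    if not events or len(beats) == 0:
        return beats
    t = np.arange(0.0, beats[-1] + 1.0, 0.02)
    bump = np.zeros_like(t)
    for onset, dur, amp in events:
        bump += _accel_bump(t, onset, dur, amp)
    g = cumulative_trapezoid(1.0 / (1.0 + bump / base_hr), t, initial=0.0)
    return np.interp(beats, t, g)


def gen_cohort(spec: CohortSpec):
    """Generate the per-segment beat-train pairs plus a metadata table.

    Returns ``(segments, metadata)`` where ``segments`` is a list of
    :class:`CohortSegment` and ``metadata`` a pandas DataFrame with the
    ground-truth columns (subject_id, ga_weeks, group, state_true,
    ratio, kappa, lambda_target, rsa_freq_hz).
    """
    import pandas as pd

    root = np.random.SeedSequence(spec.seed)
    lock_ratio = CouplingRatio.parse(next(iter(spec.lambda_trend)))
    segments: list[CohortSegment] = []
    rows = []
    subj = 0
    for (ga_lo, ga_hi), group in zip(spec.ga_ranges, spec.group_names):
        target = float(spec.lambda_trend[str(lock_ratio)][group])
        kappa = kappa_for_lambda(target)
        group_seeds = root.spawn(spec.n_subjects_per_group)
        for ss in group_seeds:
            subj += 1
            sid = f"S{subj:04d}"
            rng = np.random.default_rng(ss)
            child = ss.spawn(3)
            ga = float(rng.uniform(ga_lo, ga_hi))
            state = "quiet" if rng.uniform() < spec.state_mix else "active"
            mparams = MaternalSimParams(
                duration=spec.segment_duration,
                hr_base=float(rng.uniform(68.0, 76.0)),
                rsa_freq=float(rng.uniform(0.2, 0.35)),
                rsa_amp=2.5,
                hrv_noise_sd=0.5,
                seed=int(child[0].generate_state(1)[0] % (2**31)),
            )
            maternal = gen_maternal_beats(mparams, subject_id=sid)
            fetal = gen_fetal_beats_locked(
                maternal,
                lock_ratio,
                kappa=kappa,
                seed=int(child[1].generate_state(1)[0] % (2**31)),
                subject_id=sid,
            )
            if state == "active":
                arng = np.random.default_rng(child[2])
                onset = float(arng.uniform(30.0, spec.segment_duration - 60.0))
                events = [(onset, float(arng.uniform(14.0, 25.0)), float(arng.uniform(18.0, 25.0)))]
                base_f = mparams.hr_base * lock_ratio.n / lock_ratio.m
                fetal = BeatTimes(
                    _accel_warp(fetal.times, events, base_f),
                    role="fetal",
                    subject_id=sid,
                )
            segments.append(
                CohortSegment(
                    subject_id=sid,
                    ga_weeks=ga,
                    group=group,
                    state_true=state,
                    ratio=lock_ratio,
                    kappa=kappa,
                    lambda_target=target,
                    rsa_freq_hz=mparams.rsa_freq,
                    maternal=maternal,
                    fetal=fetal,
                )
            )
            rows.append(
                {
                    "subject_id": sid,
                    "ga_weeks": ga,
                    "group": group,
                    "state_true": state,
                    "ratio": str(lock_ratio),
                    "kappa": kappa,
                    "lambda_target": target,
                    "rsa_freq_hz": mparams.rsa_freq,
                }
            )
    return segments, pd.DataFrame(rows)


def write_cohort_csv(segments, metadata, out_dir) -> None:
    """Write per-segment beat CSVs plus the metadata table."""
    from pathlib import Path

    from .preprocess import write_beats_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for seg in segments:
        write_beats_csv(seg.maternal, out / f"{seg.subject_id}_maternal.csv")
        write_beats_csv(seg.fetal, out / f"{seg.subject_id}_fetal.csv")
    metadata.to_csv(out / "metadata.csv", index=False)
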