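"""m:n phase coupling between maternal and fetal beat trains.

The maternal beat train is partitioned into consecutive non-overlapping
cycles of ``m`` inter-beat intervals.  Each fetal beat falling inside a
complete cycle gets a relative phase Ψ ∈ [0, 1): its linear position
within the cycle.  Under m:n locking the fetal phases occupy n bands, so
the unit vectors exp(i·2π·n·Ψ) align, and the windowed phase coupling
index

    λ(t_k) = | (1/M) Σ_j exp(i·2π·n·Ψ_j) |²

(the squared mean resultant length over the M fetal-phase samples within
the window of N maternal beats centered at beat k) approaches 1.  For
phases scattered uniformly on the circle E[λ] = 1/M, the incoherent
floor.  N defaults to 70 maternal beats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "STUDIED_RATIOS",
    "CouplingRatio",
    "RelativePhaseSeries",
    "LambdaSeries",
    "CouplingSummary",
    "relative_phase",
    "coupling_index",
    "summarize_coupling",
]

#: the six maternal:fetal locking ratios under study
STUDIED_RATIOS = ((1, 2), (1, 3), (2, 3), (2, 4), (3, 4), (3, 5))

DEFAULT_WINDOW_BEATS = 70


@dataclass(frozen=True)
class CouplingRatio:
    """[m:n]: m maternal beats per n fetal beats in one locking cycle."""

    m: int
    n: int

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and isinstance(self.n, (int, np.integer))):
            raise ValueError("m and n must be integers")
        if self.m <= 0 or self.n <= 0:
            raise ValueError("m and n must be positive")
        if (self.m, self.n) not in STUDIED_RATIOS:
            raise ValueError(
                f"[{self.m}:{self.n}] is not in the studied ratio set "
                f"{['%d:%d' % r for r in STUDIED_RATIOS]}"
            )

    @classmethod
    def parse(cls, text: str) -> "CouplingRatio":
        try:
            m_s, n_s = text.split(":")
            return cls(int(m_s), int(n_s))
        except ValueError as exc:
            raise ValueError(f"cannot parse coupling ratio {text!r}") from exc

    def __str__(self) -> str:
        return f"{self.m}:{self.n}"

    @property
    def label(self) -> str:
        """Column-safe name, e.g. 'lam_1_2'."""
        return f"lam_{self.m}_{self.n}"


@dataclass
class RelativePhaseSeries:
    """Fetal-beat relative phases Ψ ∈ [0,1) within m-maternal-beat cycles."""

    fetal_times: np.ndarray
    psi: np.ndarray
    ratio: CouplingRatio

    def __post_init__(self) -> None:
        self.fetal_times = np.asarray(self.fetal_times, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.fetal_times.shape != self.psi.shape:
            raise ValueError("fetal_times and psi must have equal length")
        if len(self.psi) and not ((self.psi >= 0).all() and (self.psi < 1).all()):
            raise ValueError("psi must lie in [0, 1)")

    def __len__(self) -> int:
        return len(self.psi)


@dataclass
class LambdaSeries:
    """Windowed phase coupling index λ(t) ∈ [0,1] for one ratio.

    ``lam`` may contain NaN where the window holds fewer than half the
    expected fetal-phase sample count (missing value, not zero).
    """

    eval_times: np.ndarray
    lam: np.ndarray
    ratio: CouplingRatio
    window_beats: int = DEFAULT_WINDOW_BEATS

    def __post_init__(self) -> None:
        self.eval_times = np.asarray(self.eval_times, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.eval_times.shape != self.lam.shape:
            raise ValueError("eval_times and lam must have equal length")
        finite = self.lam[np.isfinite(self.lam)]
        if len(finite) and not ((finite >= 0).all() and (finite <= 1 + 1e-12).all()):
            raise ValueError("lambda must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.lam)


@dataclass
class CouplingSummary:
    """Per-segment mean λ for each computed ratio (NaN where undefined)."""

    segment_id: str
    mean_lambda: dict
    flagged: tuple = ()


def relative_phase(maternal, fetal, ratio: CouplingRatio) -> RelativePhaseSeries:
    """Relative phase of each fetal beat within m-maternal-beat cycles.

    Cycles are consecutive non-overlapping blocks of ``ratio.m``
    inter-beat intervals anchored at the first maternal beat.  For a
    fetal beat t in cycle [t_k, t_{k+m}):

        Ψ = (t − t_k) / (t_{k+m} − t_k)

    Cycle membership is half-open: a fetal beat exactly at a cycle end
    belongs to the next cycle.  Fetal beats before the first or at/after
    the end of the last complete cycle are omitted.
    """
    mt = np.asarray(maternal.times, dtype=float)
    ft = np.asarray(fetal.times, dtype=float)
    m = ratio.m
    if len(mt) < m + 1:
        raise ValueError(f"need at least {m + 1} maternal beats for an m={m} cycle")
    n_cycles = (len(mt) - 1) // m
    bounds = mt[: n_cycles * m + 1 : m]  # cycle boundaries, length n_cycles + 1
    inside = (ft >= bounds[0]) & (ft < bounds[-1])
    ft_in = ft[inside]
    idx = np.searchsorted(bounds, ft_in, side="right") - 1
    psi = (ft_in - bounds[idx]) / (bounds[idx + 1] - bounds[idx])
    psi = np.clip(psi, 0.0, np.nextafter(1.0, 0.0))
    return RelativePhaseSeries(fetal_times=ft_in, psi=psi, ratio=ratio)


def coupling_index(
    phases: RelativePhaseSeries,
    maternal,
    window_beats: int = DEFAULT_WINDOW_BEATS,
) -> LambdaSeries:
    """Sliding-window phase coupling index λ at each maternal beat.

    λ is evaluated at every maternal beat k whose centered window of
    ``window_beats`` maternal beats (N/2 on each side) lies inside the
    record; edge beats yield no value rather than a shrunken-window
    estimate.  Windows holding fewer than half the expected number of
    fetal-phase samples (M < n·⌈N/(2m)⌉) yield NaN.
    """
    mt = np.asarray(maternal.times, dtype=float)
    N = int(window_beats)
    if N < 2:
        raise ValueError("window_beats must be >= 2")
    h = N // 2
    if len(mt) < N + 1:
        warnings.warn(
            f"record has {len(mt)} maternal beats < window of {N}; empty λ series",
            stacklevel=2,
        )
        return LambdaSeries(np.empty(0), np.empty(0), phases.ratio, N)
    ks = np.arange(h, len(mt) - h)
    lo = mt[ks - h]
    hi = mt[ks + h]
    ft = phases.fetal_times
    z = np.exp(2j * np.pi * phases.ratio.n * phases.psi)
    cz = np.concatenate([[0.0 + 0.0j], np.cumsum(z)])
    i0 = np.searchsorted(ft, lo, side="left")
    i1 = np.searchsorted(ft, hi, side="right")
    M = i1 - i0
    with np.errstate(invalid="ignore"):
        mean_vec = (cz[i1] - cz[i0]) / np.maximum(M, 1)
    lam = np.abs(mean_vec) ** 2
    m_min = phases.ratio.n * int(np.ceil(N / (2 * phases.ratio.m)))
    lam[M < m_min] = np.nan
    lam = np.minimum(lam, 1.0)  # guard float round-up at perfect coherence
    return LambdaSeries(eval_times=mt[ks], lam=lam, ratio=phases.ratio, window_beats=N)


def summarize_coupling(*lambda_series: LambdaSeries, segment_id: str = "") -> CouplingSummary:
    """Arithmetic mean λ per ratio over defined (non-NaN) values.

    Ratios whose λ series is entirely missing get a NaN summary and are
    listed in ``flagged``.
    """
    means = {}
    flagged = []
    for series in lambda_series:
        key = str(series.ratio)
        finite = series.lam[np.isfinite(series.lam)]
        if len(finite) == 0:
            means[key] = float("nan")
            flagged.append(key)
        else:
            means[key] = float(np.mean(finite))
    return CouplingSummary(segment_id=segment_id, mean_lambda=means, flagged=tuple(flagged))
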