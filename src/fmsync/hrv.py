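"""Time-domain heart-rate-variability summaries per analysis segment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import RRSeries

__all__ = ["HrvSummary", "hrv_summary"]


@dataclass
class HrvSummary:
    """MRR / SDNN / mean HR for one RR series.

    mrr: arithmetic mean RR (ms); sdnn: sample standard deviation with
    the n−1 denominator (ms); mean_hr: mean of the per-interval HR
    values 60000/rr — note this differs from 60000/MRR by the Jensen
    gap, which grows with RR dispersion.
    """

    mrr: float
    sdnn: float
    mean_hr: float
    n_beats: int


def hrv_summary(rr: RRSeries) -> HrvSummary:
    if len(rr) < 2:
        raise ValueError("need at least 2 RR intervals for HRV summaries")
    return HrvSummary(
        mrr=float(np.mean(rr.rr)),
        sdnn=float(np.std(rr.rr, ddof=1)),
        mean_hr=float(np.mean(60000.0 / rr.rr)),
        n_beats=len(rr) + 1,
    )
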