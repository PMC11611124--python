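"""Cohort assembly and group-level statistics.

Each 3-minute segment contributes one row of features (per-ratio mean
coupling index λ, maternal respiration rate, maternal/fetal mean HR,
fetal MRR and SDNN, behavioral state).  Group comparisons across
gestational-age groups use the Kruskal–Wallis test with Dunn's post-hoc
pairwise z tests and Benjamini–Hochberg FDR adjustment within each
variable's pairwise family.  Scatter relationships are summarized with
OLS regression, Pearson r, the two-sided slope p-value, and a 95%
prediction-interval band.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import coupling, fbs, hrv, respiration
from .coupling import STUDIED_RATIOS, CouplingRatio
from .preprocess import BeatTimes, beats_to_rr, read_beats_csv, rr_to_hr

__all__ = [
    "GA_GROUPS",
    "assign_ga_group",
    "GroupComparison",
    "RegressionFit",
    "kruskal_dunn",
    "kw_dunn",
    "regression_with_pi",
    "PipelineConfig",
    "PipelineResult",
    "process_segment_pair",
    "run_pipeline",
]

log = logging.getLogger("fmsync")

#: gestational-age groups, half-open intervals [low, high) in weeks
GA_GROUPS = (("Early", 16.0, 25.0), ("Mid", 25.0, 32.0), ("Late", 32.0, 40.0))
GROUP_ORDER = tuple(g[0] for g in GA_GROUPS)


def assign_ga_group(ga_weeks: float) -> str:
    """Early [16,25), Mid [25,32), Late [32,40) weeks."""
    if not np.isfinite(ga_weeks) or not (16.0 <= ga_weeks < 40.0):
        raise ValueError(f"gestational age {ga_weeks!r} outside [16, 40) weeks")
    for name, lo, hi in GA_GROUPS:
        if lo <= ga_weeks < hi:
            return name
    raise AssertionError("unreachable")


@dataclass
class GroupComparison:
    """Kruskal–Wallis omnibus + Dunn pairwise results for one variable."""

    variable: str
    grouping: str
    group_sizes: dict
    h_statistic: float
    p_kw: float
    pairwise: list  # of dicts: pair, z, p_raw, p_fdr

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "grouping": self.grouping,
            "group_sizes": self.group_sizes,
            "H": self.h_statistic,
            "p_kw": self.p_kw,
            "pairwise": self.pairwise,
        }


@dataclass
class RegressionFit:
    """OLS fit of y on x with Pearson r and a 95% prediction band."""

    x_name: str
    y_name: str
    stratum: str
    slope: float
    intercept: float
    r: float
    p_slope: float
    n: int
    pi_x: np.ndarray
    pi_lower: np.ndarray
    pi_upper: np.ndarray

    def to_dict(self) -> dict:
        return {
            "x": self.x_name,
            "y": self.y_name,
            "stratum": self.stratum,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "p_slope": self.p_slope,
            "n": self.n,
            "pi_x": list(map(float, self.pi_x)),
            "pi_lower": list(map(float, self.pi_lower)),
            "pi_upper": list(map(float, self.pi_upper)),
        }


def _dunn_pairwise(samples: dict) -> list:
    """Dunn's z tests on pooled ranks with tie correction, BH-adjusted.

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − T)(1/n_i + 1/n_j)] with the
    tie term T = Σ(t³ − t) / (12(N − 1)); two-sided normal p-values,
    Benjamini–Hochberg adjustment across the pairwise family.
    """
    names = list(samples)
    pooled = np.concatenate([samples[k] for k in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    offset = 0
    for k in names:
        n_k = len(samples[k])
        mean_ranks[k] = float(np.mean(ranks[offset : offset + n_k]))
        offset += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(names, 2):
        var = base_var * (1.0 / len(samples[a]) + 1.0 / len(samples[b]))
        if var <= 0:
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"pair": f"{a} vs {b}", "z": float(z), "p_raw": p})
    if rows:
        _, p_fdr, _, _ = multipletests([r["p_raw"] for r in rows], method="fdr_bh")
        for r, adj in zip(rows, p_fdr):
            r["p_fdr"] = float(adj)
    return rows


def kruskal_dunn(samples: dict, variable: str = "", grouping: str = "") -> GroupComparison:
    """Kruskal–Wallis omnibus test plus Dunn pairwise comparisons.

    ``samples`` maps group name -> 1-D array.  When every observation in
    every group is identical the omnibus is degenerate: H = 0, p = 1.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has fewer than 3 observations")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        pairwise = [
            {"pair": f"{a} vs {b}", "z": 0.0, "p_raw": 1.0, "p_fdr": 1.0}
            for a, b in itertools.combinations(groups, 2)
        ]
        return GroupComparison(
            variable, grouping, {k: len(v) for k, v in groups.items()}, 0.0, 1.0, pairwise
        )
    h_stat, p_kw = stats.kruskal(*groups.values())
    return GroupComparison(
        variable=variable,
        grouping=grouping,
        group_sizes={k: len(v) for k, v in groups.items()},
        h_statistic=float(h_stat),
        p_kw=float(p_kw),
        pairwise=_dunn_pairwise(groups),
    )


def kw_dunn(
    table: pd.DataFrame,
    variable: str,
    group_col: str = "ga_group",
    state: str | None = None,
) -> GroupComparison:
    """Kruskal–Wallis + Dunn on one CohortTable column across GA groups."""
    df = table if state is None else table[table["state"] == state]
    df = df.dropna(subset=[variable])
    samples = {
        g: df.loc[df[group_col] == g, variable].to_numpy(float)
        for g in GROUP_ORDER
        if (df[group_col] == g).any()
    }
    grouping = group_col if state is None else f"{group_col} | state={state}"
    return kruskal_dunn(samples, variable=variable, grouping=grouping)


def regression_with_pi(
    x: np.ndarray,
    y: np.ndarray,
    x_name: str = "x",
    y_name: str = "y",
    stratum: str = "",
    alpha: float = 0.05,
    n_grid: int = 50,
) -> RegressionFit:
    """OLS of y on x with Pearson r and a t-based 95% prediction interval.

    The prediction band uses the standard formula with the leverage
    term, evaluated on an even grid over the observed x range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 10:
        raise ValueError("need at least 10 points per stratum")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), n_grid)
    pred = res.get_prediction(sm.add_constant(grid))
    band = pred.conf_int(obs=True, alpha=alpha)
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionFit(
        x_name=x_name,
        y_name=y_name,
        stratum=stratum,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r=r,
        p_slope=float(res.pvalues[1]),
        n=len(x),
        pi_x=grid,
        pi_lower=band[:, 0],
        pi_upper=band[:, 1],
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration of a full cohort run.

    Exactly one of ``cohort_spec`` (simulate) or ``input_dir`` (load
    beat CSVs + metadata.csv) must be set.  ``state_source`` chooses the
    behavioral-state column: 'classified' (HR-pattern classifier),
    'truth' (generator ground truth), or 'auto' (truth when available).
    ``per_subject_average`` collapses repeated segments per subject
    before statistics (default off: segments treated as observations).
    """

    cohort_spec: object | None = None
    input_dir: str | None = None
    ratios: tuple = STUDIED_RATIOS
    window_beats: int = 70
    state_source: str = "auto"
    per_subject_average: bool = False
    max_fail_fraction: float = 0.2
    output_dir: str | None = None
    criteria: fbs.StateCriteria = field(default_factory=fbs.StateCriteria)

    def __post_init__(self) -> None:
        if (self.cohort_spec is None) == (self.input_dir is None):
            raise ValueError("set exactly one of cohort_spec or input_dir")
        if self.state_source not in ("auto", "truth", "classified"):
            raise ValueError("state_source must be 'auto', 'truth' or 'classified'")
        self.ratios = tuple(
            (r.m, r.n) if isinstance(r, CouplingRatio) else tuple(r) for r in self.ratios
        )


@dataclass
class PipelineResult:
    table: pd.DataFrame
    comparisons: list
    regressions: list
    n_failed: int


def process_segment_pair(
    maternal: BeatTimes,
    fetal: BeatTimes,
    ratios=STUDIED_RATIOS,
    window_beats: int = 70,
    criteria: fbs.StateCriteria | None = None,
) -> dict:
    """All per-segment features from one maternal/fetal beat-train pair."""
    criteria = criteria or fbs.StateCriteria()
    rr_m = beats_to_rr(maternal)
    rr_f = beats_to_rr(fetal)
    hrv_m = hrv.hrv_summary(rr_m)
    hrv_f = hrv.hrv_summary(rr_f)
    row: dict = {
        "maternal_mean_hr_bpm": hrv_m.mean_hr,
        "fetal_mean_hr_bpm": hrv_f.mean_hr,
        "fetal_mrr_ms": hrv_f.mrr,
        "fetal_sdnn_ms": hrv_f.sdnn,
        "maternal_mrr_ms": hrv_m.mrr,
        "maternal_sdnn_ms": hrv_m.sdnn,
    }
    series = []
    for m, n in ratios:
        ratio = CouplingRatio(m, n)
        phases = coupling.relative_phase(maternal, fetal, ratio)
        series.append(coupling.coupling_index(phases, maternal, window_beats))
    summary = coupling.summarize_coupling(*series)
    for (m, n) in ratios:
        row[f"lam_{m}_{n}"] = summary.mean_lambda[f"{m}:{n}"]
    edr = respiration.edr_waveform(rr_m)
    resp = respiration.estimate_resp_rate(edr)
    row["resp_rate_cpm"] = resp.rate_cpm
    row["resp_low_confidence"] = resp.low_confidence
    label = fbs.classify_state(rr_to_hr(rr_f), criteria)
    row["state_classified"] = label.state
    row["fetal_baseline_bpm"] = label.baseline
    row["fetal_bandwidth_bpm"] = label.bandwidth
    row["n_accelerations"] = label.n_accelerations
    return row


def _load_input_dir(input_dir: str):
    from .synthgen import CohortSegment  # noqa: F401  (shape only)

    path = Path(input_dir)
    meta_path = path / "metadata.csv"
    if not path.is_dir() or not meta_path.exists():
        raise FileNotFoundError(f"no metadata.csv under {input_dir!r}")
    meta = pd.read_csv(meta_path)
    if len(meta) == 0:
        raise ValueError(f"{meta_path}: empty metadata table")
    entries = []
    for _, rec in meta.iterrows():
        sid = str(rec["subject_id"])
        maternal = read_beats_csv(path / f"{sid}_maternal.csv", role="maternal")
        fetal = read_beats_csv(path / f"{sid}_fetal.csv", role="fetal")
        entries.append((rec.to_dict(), maternal, fetal))
    return entries


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Process every segment and compute the cohort-level statistics.

    Per-segment failures are logged and excluded; the run aborts if more
    than ``max_fail_fraction`` of segments fail.  Outputs (cohort.csv,
    group_tests.json, regressions.json, run.log) are written when
    ``output_dir`` is set.
    """
    if config.cohort_spec is not None:
        from .synthgen import gen_cohort

        segments, _ = gen_cohort(config.cohort_spec)
        entries = [
            (
                {
                    "subject_id": s.subject_id,
                    "ga_weeks": s.ga_weeks,
                    "state_true": s.state_true,
                    "lambda_target": s.lambda_target,
                    "kappa": s.kappa,
                    "rsa_freq_hz": s.rsa_freq_hz,
                },
                s.maternal,
                s.fetal,
            )
            for s in segments
        ]
    else:
        entries = _load_input_dir(config.input_dir)

    rows = []
    n_failed = 0
    for meta, maternal, fetal in entries:
        sid = meta.get("subject_id", "?")
        try:
            row = process_segment_pair(
                maternal, fetal, config.ratios, config.window_beats, config.criteria
            )
        except Exception as exc:  # logged and excluded, never silently dropped
            n_failed += 1
            log.warning("segment %s failed: %s", sid, exc)
            continue
        row["subject_id"] = sid
        row["ga_weeks"] = float(meta["ga_weeks"])
        row["ga_group"] = assign_ga_group(row["ga_weeks"])
        if "state_true" in meta and not pd.isna(meta["state_true"]):
            row["state_true"] = meta["state_true"]
        rows.append(row)
    if n_failed > config.max_fail_fraction * max(len(entries), 1):
        raise RuntimeError(
            f"{n_failed}/{len(entries)} segments failed "
            f"(> {config.max_fail_fraction:.0%} allowed)"
        )
    if not rows:
        raise RuntimeError("no segments could be processed")
    table = pd.DataFrame(rows)

    have_truth = "state_true" in table.columns and table["state_true"].notna().all()
    source = config.state_source
    if source == "auto":
        source = "truth" if have_truth else "classified"
    if source == "truth" and not have_truth:
        raise ValueError("state_source='truth' but no ground-truth labels present")
    table["state"] = table["state_true"] if source == "truth" else table["state_classified"]

    lead = ["subject_id", "ga_weeks", "ga_group", "state"]
    table = table[lead + [c for c in table.columns if c not in lead]]
    if config.per_subject_average:
        numeric = table.select_dtypes("number").columns
        table = (
            table.groupby(["subject_id", "ga_group", "state"], as_index=False)[list(numeric)]
            .mean()
        )

    lam_cols = [f"lam_{m}_{n}" for m, n in config.ratios]
    variables = lam_cols + ["resp_rate_cpm", "maternal_mean_hr_bpm", "fetal_mean_hr_bpm",
                            "fetal_mrr_ms", "fetal_sdnn_ms"]
    comparisons = []
    regressions = []
    for state in sorted(table["state"].unique()):
        sub = table[table["state"] == state]
        for var in variables:
            try:
                comparisons.append(kw_dunn(table, var, state=state))
            except ValueError as exc:
                log.info("comparison %s | %s skipped: %s", var, state, exc)
        reg_pairs = [("ga_weeks", v) for v in lam_cols]
        reg_pairs += [
            ("ga_weeks", "maternal_mean_hr_bpm"),
            ("ga_weeks", "resp_rate_cpm"),
            ("ga_weeks", "fetal_mean_hr_bpm"),
            ("ga_weeks", "fetal_mrr_ms"),
            ("ga_weeks", "fetal_sdnn_ms"),
            ("resp_rate_cpm", "fetal_mean_hr_bpm"),
            ("maternal_mean_hr_bpm", "fetal_mean_hr_bpm"),
        ]
        reg_pairs += [("resp_rate_cpm", v) for v in lam_cols]
        for x_name, y_name in reg_pairs:
            pair = sub[[x_name, y_name]].dropna()
            try:
                regressions.append(
                    regression_with_pi(
                        pair[x_name].to_numpy(),
                        pair[y_name].to_numpy(),
                        x_name=x_name,
                        y_name=y_name,
                        stratum=f"state={state}",
                    )
                )
            except ValueError as exc:
                log.info("regression %s ~ %s | %s skipped: %s", y_name, x_name, state, exc)

    result = PipelineResult(
        table=table, comparisons=comparisons, regressions=regressions, n_failed=n_failed
    )
    if config.output_dir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out / "cohort.csv", index=False)
    with open(out / "group_tests.json", "w") as fh:
        json.dump([c.to_dict() for c in result.comparisons], fh, indent=1)
    with open(out / "regressions.json", "w") as fh:
        json.dump([r.to_dict() for r in result.regressions], fh, indent=1)
    with open(out / "run.log", "a") as fh:
        fh.write(
            f"segments={len(result.table)} failed={result.n_failed} "
            f"ratios={config.ratios} window_beats={config.window_beats} "
            f"state_source={config.state_source}\n"
        )
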