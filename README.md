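# fmsync

Analysis toolkit for **maternal–fetal heart rate synchronization** from
non-invasive ECG.  It is aimed at researchers in fetal cardiology and
physiological time-series analysis who work with paired maternal/fetal
R-peak trains (or raw single-channel ECG) and want to quantify m:n
phase coupling between the two hearts, relate it to gestational age,
maternal respiration, and fetal behavioral state — and validate the
whole chain on synthetic data with known ground truth.

## The measures

**Phase coupling index.**  The maternal beat train is cut into
consecutive cycles of *m* inter-beat intervals.  Each fetal beat inside
a cycle [t_k, t_{k+m}) gets a relative phase

    Ψ = (t − t_k) / (t_{k+m} − t_k)  ∈ [0, 1).

Under [m:n] locking the fetal phases occupy n bands, so the unit
vectors e^{i·2πnΨ} align.  The windowed coupling index at maternal beat
k is the squared mean resultant length

    λ(t_k) = | (1/M) Σ_j e^{i·2πnΨ_j} |²  ∈ [0, 1],

taken over the M fetal-phase samples inside the window of N = 70
maternal beats centred on beat k.  λ = 1 means perfect phase locking;
for uniformly scattered phases E[λ] = 1/M (the incoherent floor).  The
six ratios [1:2], [1:3], [2:3], [2:4], [3:4], [3:5] are computed per
3-minute segment.

**ECG-derived respiration (EDR).**  Respiratory sinus arrhythmia
modulates maternal HR at the breathing frequency; the per-interval HR
series is cubic-spline resampled to 4 Hz and the respiration frequency
is the FFT-magnitude argmax in 0.1–0.5 Hz (reported in cycles/min).

**Fetal behavioral state.**  A 3-minute fetal HR segment is *quiet* iff
baseline < 160 bpm, oscillation bandwidth < 7.5 bpm, and it contains no
acceleration (> 15 bpm above baseline, sustained ≥ 10 s); otherwise
*active*.

**Cohort statistics.**  Per-segment features (mean λ per ratio,
respiration rate, MRR, SDNN, mean HRs) are compared across gestational
age groups (Early [16, 25), Mid [25, 32), Late [32, 40) weeks) with
Kruskal–Wallis + Dunn's post-hoc z tests under Benjamini–Hochberg FDR
correction, and scatter relationships are summarized by OLS regression
with Pearson r and 95 % prediction intervals, stratified by state.

Because no clinical recordings ship with the package, `fmsync.synthgen`
generates seeded synthetic cohorts: integrate-and-fire maternal beats
with RSA, fetal trains phase-locked with von Mises jitter whose
concentration κ is chosen by inverting (I₁(κ)/I₀(κ))² = λ_target, ECG
waveforms for testing the R-peak detector, and free-running fetal HR
profiles for testing the state classifier.

## Worked example

```python
from fmsync import synthgen as sg, cohort_stats as cs

spec = sg.CohortSpec(
    n_subjects_per_group=10, state_mix=1.0, seed=7,
    lambda_trend={"1:2": {"Early": 0.5, "Mid": 0.4, "Late": 0.3}},
)
result = cs.run_pipeline(cs.PipelineConfig(cohort_spec=spec))
print(result.table.groupby("ga_group")["lam_1_2"].mean().round(3))
```

prints

```
ga_group
Early    0.510
Late     0.311
Mid      0.402
```

— the realized quiet-state mean λ[1:2] per gestational-age group tracks
the built-in targets (0.5 / 0.4 / 0.3) to within sampling error at
3-minute segments.  The associated regression of λ[1:2] on gestational
age gives slope −0.0133 (r = −0.892, p = 3.5e−11), and the
Kruskal–Wallis test across groups gives H = 25.55 (p = 2.8e−06) with
all three Dunn pairwise comparisons significant after FDR correction
(Early vs Late p_fdr = 1.3e−06).  The same pipeline runs from the shell:

```bash
fmsync simulate --out sim/ --seed 7 --n-subjects-per-group 10 --state-mix 1.0
fmsync analyze --input sim/ --out analysis/
```

writing `cohort.csv` (one row per 3-minute segment), `group_tests.json`
and `regressions.json`.

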