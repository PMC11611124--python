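# Methods

## Signal model and preprocessing

Inputs are single-channel maternal and fetal ECG streams that have
already been separated upstream (abdominal-lead source separation is
out of scope), or pre-detected R-peak time lists.  Raw waveforms pass
through a zero-phase 4th-order Butterworth high-pass at 5 Hz (zero-phase
so R-peak times are not lag-shifted), are normalized to unit peak
amplitude, and R peaks are local maxima above an adaptive threshold:
0.4 × the rolling 2-s maximum of the signal, with a role-dependent
minimum separation (maternal 0.33 s, fetal 0.2 s, from physiological
rate ceilings of ~180 and ~300 bpm).  Both the threshold fraction and
window are configurable.  A record yielding fewer than 10 peaks per
3 minutes raises a low-quality error.  RR intervals are anchored at the
onset beat (rr_i = t_{i+1} − t_i in ms; hr_i = 60000/rr_i), and
out-of-range intervals (maternal outside 300–1500 ms, fetal outside
200–600 ms) are flagged rather than dropped — an automated stand-in for
manual visual confirmation of detections.  Analyses run on consecutive
non-overlapping 180 s windows anchored at the start of the common
maternal/fetal support; the trailing remainder is discarded and window
membership is half-open, so no beat enters two segments.

## Phase coupling index

Maternal cycles are non-overlapping blocks of m inter-beat intervals
anchored at the first maternal beat.  A fetal beat t in cycle
[t_k, t_{k+m}) has relative phase Ψ = (t − t_k)/(t_{k+m} − t_k); a beat
exactly on a cycle boundary belongs to the next cycle.  The coupling
index is the squared mean resultant length of the vectors e^{i·2πnΨ}
over the fetal-phase samples inside a centred window of N = 70 maternal
beats, evaluated at every maternal beat whose full window fits in the
record (sliding, one value per beat).  Numerical choices:

- **Kernel.**  The n-fold phase multiplication e^{i·2πnΨ} is the
  standard n:m phase-coherence construction: it maps the n locked phase
  bands onto a single direction so perfect locking gives λ = 1 and
  uniform phases give E[λ] = 1/M.  Without the factor, all phase
  vectors would lie within one radian and λ could not discriminate.
- **Edges.**  λ is undefined (NaN) where the window would be truncated,
  keeping estimator variance uniform, and NaN where a window holds
  fewer than half the expected sample count (M < n·⌈N/(2m)⌉), e.g.
  during signal dropouts.
- **Averaging.**  The window mean runs over fetal-phase samples (Ψ
  exists only at fetal beats) and is normalized by the realized count M.
- The per-segment summary is the arithmetic mean of defined λ values;
  all-missing ratios are flagged, not zero-filled.

λ is invariant to a common time shift and to a common positive time
rescaling of both trains, properties the test suite checks.

## ECG-derived respiration

HR per RR interval is cubic-spline interpolated onto a uniform 4 Hz
grid (≥ 8× the 0.5 Hz band edge, the conventional HRV resampling rate),
mean-removed (no further detrending or tapering by default), zero-padded
by ≥ 4× to an FFT length that is a power of two, and the respiration
frequency is the magnitude argmax in 0.1–0.5 Hz.  The peak-bin power
over total in-band power gauges spectral concentration; below 0.1 the
estimate is flagged low-confidence (a flat spectrum makes the argmax
meaningless).  Records spanning < 60 s are rejected outright (frequency
resolution too coarse).

## Fetal behavioral state

Quiet requires the conjunction: baseline < 160 bpm AND oscillation
bandwidth < 7.5 bpm AND no accelerations; any violated criterion is
active, and boundary values (exactly 160 / exactly 7.5) are active.
Operationalizations, since only the criteria themselves are standard:

- **Baseline** = median HR after excluding samples that exceed a 60-s
  running median by > 15 bpm (a two-pass scheme that breaks the
  circularity between baseline estimation and acceleration detection;
  the median is robust to the very excursions being excluded).
- **Bandwidth** = max(p97.5, −p2.5) of the acceleration-excluded
  deviations from baseline — a robust peak deviation reading the
  "within ±7.5 bpm" envelope; percentiles keep single aberrant beats
  from dominating.  The literal active-state bandwidth condition
  ("≥ 7.5 and ≤ −7.5") is unsatisfiable as written and is read as the
  complement of the quiet envelope.
- **Accelerations** = maximal runs of deviation > 15 bpm lasting
  ≥ 10 s after merging gaps < 2 s.  The 10 s minimum (obstetric
  convention is 15 s) keeps sensitivity on 3-minute segments and is
  configurable.
- Baseline is computed per segment (not per recording).

## HRV summaries

MRR = mean RR (ms); SDNN = sample standard deviation with the n−1
denominator; mean HR = mean of per-interval 60000/rr, which differs
from 60000/MRR by the Jensen gap (documented so figures reproduce).

## Cohort statistics

Gestational-age groups are half-open: Early [16, 25), Mid [25, 32),
Late [32, 40) weeks.  Omnibus comparisons use Kruskal–Wallis with tie
correction; post-hoc pairwise comparisons use Dunn's z on pooled ranks
with the tie term Σ(t³−t)/(12(N−1)), two-sided normal p-values, and
Benjamini–Hochberg adjustment **within each variable's pairwise
family** (not across variables).  A fully degenerate comparison (all
observations identical) returns H = 0, p = 1.  Scatter relationships
use OLS with Pearson r, the two-sided slope p-value, and a t-based 95 %
**prediction** interval (with leverage term) — wider than a confidence
band, covering new observations.  All segment-level analyses stratify
by fetal state.  Repeated segments per subject are treated as
independent observations by default; a per-subject averaging switch
exists but no mixed-effects model is fitted (a known limitation).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with every random element seeded.

- **Maternal beats**: integrate-and-fire — a beat fires each time
  ∫HR(t)/60 dt accrues 1 — with HR(t) = hr_base + rsa_amp·sin(2π·f_r·t)
  + smooth noise (Gaussian knots at 2 Hz, linearly interpolated, so the
  variability is band-limited like real HRV rather than white).
  Integration uses a 200 Hz trapezoid grid with linear inversion of the
  cumulative phase; zero-modulation trains are exactly periodic.
  Defaults (hr_base 80 bpm, RSA amplitude 2.5 bpm at 0.25 Hz, noise sd
  0.5 bpm; cohort draws hr_base in 68–76 bpm and f_r in 0.20–0.35 Hz)
  are conventional adult-pregnancy values; they are not fitted to any
  dataset.
- **Locked fetal beats**: within each m-beat maternal cycle, n beats at
  target phases (j + 0.5)/n — centred so no beat ever coincides with a
  cycle boundary — jittered by von Mises(0, κ) noise on the 2πnΨ
  circle.  κ = ∞ is the zero-jitter sentinel; κ = 0 is uniform.  The
  asymptotic mean coupling index of such a train is (I₁(κ)/I₀(κ))², so
  cohort λ targets are hit by inverting that relation numerically
  (Brent on the exponentially-scaled Bessel ratio); targets at or below
  the 1/N floor or above 1 are rejected as unreachable.
- **Free-running fetal HR profiles**: baseline + a single slow sinusoid
  (seeded frequency in 0.03–0.12 Hz) scaled to the stated peak
  deviation + plateau-shaped acceleration bumps (raised-cosine ramps
  over 15 % of the duration on each side).  A single sinusoid is used
  so the robust percentile bandwidth read by the classifier tracks the
  generative peak deviation, and the plateau shape keeps the
  acceleration excursion above threshold for most of its nominal
  duration; quiet presets sit ≥ 1 bpm inside every quiet criterion and
  active presets violate exactly one criterion by ≥ 1 bpm.
- **ECG waveforms**: one symmetric Mexican-hat wavelet (~40 ms) per
  beat, optional sinusoidal baseline wander and white noise; SNR in dB
  is defined on signal-RMS over noise-RMS power.  No P/T waves and no
  maternal-fetal mixture — R-peak detection is the only consumer.
- **Cohorts**: per group, gestational ages drawn uniformly in the group
  interval, states drawn from the quiet fraction, fetal trains locked
  at the ratio named in `lambda_trend` with κ from the group's λ
  target; active segments additionally receive an acceleration
  time-warp (local beat-time compression raising fetal HR by the bump
  amplitude while leaving phases outside the window shifted only by a
  constant).  All ground-truth columns are retained.

### What the generator does and does not emulate

It reproduces the quantities the estimators consume: RSA spectral lines,
m:n phase structure with tunable coherence, HR patterns crossing the
state criteria, QRS trains at realistic rates.  It does **not**
reproduce morphological ECG realism, pathological rhythms, fetal
movement artifacts, non-stationary respiration, or the clinical
distributions of any real cohort — so passing tests demonstrate
estimator correctness under the assumed statistical structure, not
clinical-level validity.

One conflict between the generator's two fidelity goals is inherent:
i.i.d. von Mises beat jitter (needed for the analytic κ→λ calibration)
at mid-range λ targets implies beat-to-beat RR fluctuations far larger
than the 7.5 bpm quiet bandwidth criterion, so jittered locked "quiet"
segments would be classified active from their HR pattern.  Real data
do not exhibit this because physiological phase wander is slow, not
beat-to-beat independent.  The pipeline therefore exposes a
`state_source` switch ('truth' / 'classified' / 'auto', default auto =
ground truth when available), and classifier validity is demonstrated
on free-running profiles, where HR-pattern realism is under direct
control.

## Problem sizes in the test suite

The suite validates: the locking maximum at machine precision on
10-minute trains; the uniform null on 10⁴ independent 70-sample windows
against a brute-force resultant simulation; κ recovery at 10⁴ phase
samples per κ (with the standard (Mλ̄−1)/(M−1) finite-window
debiasing); EDR recovery on 100 seeded 180-s replicates per frequency;
Kruskal–Wallis type-I calibration on 2000 null replicates of 3×30;
trend recovery on cohorts of 30 subjects per group and null slope
calibration over 200 seeded cohort runs (restricted to the [1:2] ratio,
the variable under test).  These sizes give Monte-Carlo standard errors
comfortably below the tolerances asserted (3 SE throughout).

## Known limitations

- No maternal-ECG cancellation / fetal extraction: inputs must be
  separated channels.
- No surrogate-data significance testing of λ and no directionality
  measures (transfer entropy, partial directed coherence).
- Windows slide beat-by-beat; jumping windows are not implemented.
- No mixed-effects handling of repeated segments per subject.
- The four-state (1F–4F) classification is out of scope; only
  quiet/active is supported.
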