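# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the `mwbody` package.

## Attentional-state labeling

States are anchored to each self-caught mind-wandering (MW) report: MW is
`[report − 9, report − 5)` s, aware is `[report − 5, report − 1)` s, and
focus is the 4 s beginning at the first tone after task resumption.  All
windows are half-open on the sample grid.  Reports arriving within 10 s of
the preceding report are excluded from every signal analysis (their windows
would overlap the previous report's aftermath) but retained for behavioral
counts; the exclusion is evaluated against the raw previous report, so a
burst keeps only its first member.  Windows extending outside the recording
are dropped rather than truncated.

Behavioral metrics: reaction-time variability is the coefficient of
variation sd/mean with the sample (n−1) standard deviation; fewer than two
responses yield NaN, never zero.  Presses are matched to the most recent
unmatched tone within 1.2 s (the minimum inter-stimulus interval).
Heartbeat-counting accuracy is `1 − |actual − reported| / actual`, averaged
over trials; it is invariant to rescaling both counts.

## Synthetic-data generator

The generator defines the study conditions every downstream stage is tested
under.  One seeded generator drives each recording; per-modality streams
are spawned deterministically, so a fixed configuration reproduces the
recording byte for byte.

**Respiration.**  A quasi-sinusoidal belt trace whose cycle rises
(inhalation) over a configurable fraction of the cycle (default 0.4) and
falls over the rest.  Cycle rate defaults to 11 cycles/min breathing-focused
and 15 sound-focused — attention to the breath slows it, and the difference
must be large enough for a paired test at desk scale.  The rate is slowly
modulated (5% fractional jitter, 20-s smoothing), and the trace carries a
linear drift (0.02 units/s), a slow sinusoidal drift (amplitude 0.3, 120-s
period) and white noise (sd 0.05) so the preprocessing chain has real work
to do.  The abdomen belt shares the true phase stream with different gain,
drift and twice the noise, so belt selection by cycle count is exercised.

**ECG.**  A stylized beat template (Q/R/S Gaussians, ~80 ms complex, plus a
small T wave) placed at times obtained by integrating an instantaneous rate:
base heart rate (70 bpm) + respiratory sinus arrhythmia (±4 bpm, higher
while inhaling, so RR intervals lengthen during exhalation) + a
report-locked profile (−4 bpm through the MW window, −3 bpm 2–3 s before
the report, +4 bpm in the final second).  Only R-peak timing matters
downstream, so beat morphology is deliberately minimal.

**EEG.**  Per channel: 1/f background (exponent 1, sd 10 µV) + 10-Hz alpha
(6 µV envelope) and 20-Hz beta (3 µV) oscillations with random channel
phases.  Within 9.4 s of each report the band envelope follows a
two-segment linear trend anchored at a per-band change point (defaults:
alpha bends 4.7 s and beta 3.5 s before the report, post-slopes −0.8 and
−0.5 µV/s, pre-slopes 0).  Each R peak adds a Gaussian bump (center 480 ms,
sd 50 ms — bulk within 380–580 ms) on the parietal-row channels with an
amplitude set by the state containing the peak (MW 1.5 µV, aware and focus
0, elsewhere 0.75 µV): the parietal late HEP component is suppressed once
awareness approaches.  Amplitudes in physical units are free parameters of
the generator — chosen at realistic EEG scales, not calibrated to any
dataset.

**Events.**  Tones with inter-stimulus intervals uniform in [1.2, 2.0] s,
suppressed between a report and its resumption (resumption 4–8 s after the
report).  Sound-focused presses answer tones; breathing-focused presses are
locked to exhalation ends.  Press latency noise is state-dependent (sd
0.05 s in focus, 0.15 s in MW/aware) — the generator's way of producing the
elevated reaction-time variability that characterizes MW.  Reports are
placed by stick-breaking with a minimum separation (default 25 s).

What the generator does **not** emulate: eye/muscle/electrode artifacts
(the artifact-removal stages of a laboratory pipeline are out of scope
here), volume conduction and realistic topographies, ectopic beats,
non-stationary 1/f slopes.  Passing tests therefore demonstrate that the
analysis chain is correct and recovers known structure under realistic
noise — not that it is robust to every pathology of real recordings.

## Respiration analysis

Preprocessing applies, in order: a centered 25-ms moving average; global
linear detrending; subtraction of a centered 60-s sliding mean whose edge
windows use the valid part only.  Phase detection finds peaks and troughs
(minimum 1-s separation, prominence ≥ 0.3 × the trace interquartile range),
merges them into a strictly alternating sequence keeping the more extreme
of same-type runs, and labels trough→peak as inhalation.  Labels and cycle
counts are invariant to affine rescaling of the trace.

The pre-report analysis computes, per participant and lag k, the fraction
of reports whose sample at (report − k) s is inhalation, and compares it to
a participant-specific baseline: the inhalation fraction over 10,000
uniform draws (with replacement — immaterial at this draw count) from the
whole phase sequence.  The group test is a one-sample t on the
participant-level differences (rate − own baseline), which keeps the
participant as the exchangeable unit; Cohen's d is reported on the same
differences.

## Cardiac analysis

The ECG is band-passed 3–30 Hz (4th-order Butterworth, zero phase).  R-peak
detection works on |signal| (hence polarity- and amplitude-invariant):
candidates must exceed 40% of a 2-s rolling maximum and a global noise
floor, with a 250-ms refractory period; intervals deviating more than 30%
from an 11-beat rolling median are flagged rather than silently removed —
the automated replacement for manual inspection.  RR intervals carry their
onset-beat time; an interval belongs to a state when its onset beat lies in
the epoch (onset-beat containment — whether full containment was intended
is not decidable from the stated rule, and onset containment never double-
counts an interval).  Second-before-report labels use the ceiling rule on
`report − onset`, i.e. half-open bins `(k−1, k]`, and seconds 1–2 / 3–4
carry the inhalation- / exhalation-period proxy tags (fixed time windows,
not instantaneous phase — they mirror which phase dominates those seconds
in the breathing-focused condition).

## Heartbeat-evoked potentials

EEG preprocessing: polyphase resampling to 250 Hz, 0.5–50 Hz zero-phase
band-pass, removal of the 50-Hz line component by sinusoid regression, and
an average reference (idempotent by construction).  Epochs span −200…600 ms
around each detected R peak; epochs crossing recording edges are dropped;
participants with fewer than ten MW reports are excluded from HEP group
analyses.

Baseline handling is regression-based, never subtraction: per channel, with
the trial-mean voltage over −200…−75 ms as covariate b, all time points are
solved at once under the design `1 + C_perp + b + b×C_perp`, where `C_perp`
are sum-coded condition contrasts orthogonalized against b.  The
residualized waveform removes the fitted b and b×C contributions and keeps
intercept and condition structure.  The orthogonalization is deliberate:
any condition difference that is collinear with baseline differences is
attributed to the baseline and removed, which makes the residuals *exactly*
uncorrelated with the baseline covariate at every channel × time point (a
tested invariant) at the price of a conservatively estimated condition
effect.  The regression is fit per participant; group statistics operate on
per-participant cell means.

## Cluster-based permutation tests

Pointwise dependent-samples t statistics (zero-variance points set to t = 0)
are thresholded at two-tailed p < .05 with df = n−1.  Suprathreshold points
of equal sign form clusters under the union of channel adjacency (distance
threshold: 1.5 × median nearest-neighbor spacing of the montage; on the
synthetic grid montage this reproduces rook neighborhoods) and along-axis
adjacency (consecutive time or frequency bins).  The cluster statistic is
the summed t.  The null is the maximum |cluster sum| over sign-flip
permutations of the within-participant differences — the exchangeable unit
for a paired design — with the add-one correction
`p = (1 + #{null ≥ |obs|}) / (1 + n_perm)`, so p ≥ 1/(n_perm+1) and
significance is declared at p < .025 per tail.  The permuted t maps are
computed vectorized (the per-point sum of squares is sign-flip invariant),
and `clusterize` is validated against a brute-force connected-components
oracle on random grids.

## Change-point model

See the README for the generative equations.  Choices that the model
statement leaves open, and how they were resolved:

- **State evolution.**  The level evolves by the shared trend only
  (`mu[n,t] = mu[n,t−1] + delta[t−1]`); adding a separate level-noise term
  would change the model class (local level + trend) and weaken change-point
  identifiability.
- **Initial conditions.**  Pre and post series share the per-participant
  starting level `mu[n,0]`, which has a vague Normal prior centered on the
  row mean with sd = 10 × the row sd.  Initial trends have a N(0, 1) prior
  independent of the innovation scales, so the zero-innovation limit is two
  straight lines with a slope break (a tested limit).
- **Change-point prior and reporting.**  Uniform over interior steps.  The
  fitted change point is reported both as the posterior mode and as the
  posterior-mass mean with a central 95% interval; "the trend decreases
  after the change point" is declared when the 95% interval of
  (mean pre-trend − mean post-trend) lies above zero.
- **Sampler.**  The bundled sampler is a blocked Gibbs scheme with no
  external dependency: (i) the joint latent block (starting levels + both
  trend series) is redrawn exactly from its multivariate-Normal full
  conditional — the pre/post cross-precision vanishes because each time
  step loads on exactly one series, and the Gram matrices of the
  cumulative-sum designs are closed-form functions of max(s, s′); (ii) τ is
  redrawn from its conditional categorical distribution, every 10th
  iteration in *collapsed* form with the latent block integrated out
  analytically (this escapes the "early τ + wiggly trend" mode that traps a
  purely conditional update); (iii) scales are updated by univariate slice
  sampling, with an ancillarity–sufficiency interweaving step for the trend
  scales (rescaling the increments with the standardized innovations held
  fixed) that removes the usual funnel between a scale and its series.  The
  τ posterior is reported as the Rao-Blackwellized average of per-step
  conditional likelihoods over retained draws, and the τ-marginalized log
  density (log-sum over candidates) is exposed on the model object and
  cross-checked against per-τ brute-force evaluation in the tests.
- **Diagnostics.**  Split-chain R-hat and bulk ESS for every sampled
  parameter (arviz); the convergence criterion is max R-hat < 1.1.  A
  parameter constant across all draws (e.g. τ with all mass on one step)
  has undefined R-hat and is excluded from the maximum.
- **Course resolution.**  The band-power course is computed at 0.1-s steps,
  but the change-point fit decimates it to 0.5-s steps (pipeline default):
  the model assumes observation noise independent across steps, while
  wavelet smoothing correlates neighboring 0.1-s samples (the 10-Hz wavelet
  envelope has ≈0.2-s temporal sd), which otherwise biases τ toward the
  window start and inflates its spread.  At 0.5-s steps the full
  EEG → course → fit chain recovers an injected 4.7-s alpha change point to
  within half a second with 20 simulated participants (a tested property).

## Time–frequency details

Morlet power uses cycles `c(f) = 3 + 0.5·(f − 2)` on a 2–40 Hz grid (1-Hz
spacing); the slope is configurable since only the intercept of the rule is
fixed by convention.  Power is linear (µV²).  Band limits: theta < 7 Hz,
alpha 8–13 Hz, beta 13–30 Hz, gamma > 30 Hz.  Every epoch-level or course
computation pads its analysis segment by at least one wavelet half-length
(defined as 5 envelope sds) at the lowest frequency involved and discards
the padding, so no retained value touches convolution edges; the pre-report
course spans −9.4…−0.5 s for the same reason.

## Problem sizes

The bundled study runs at desk scale as a deliberate choice: 6 participants
× two 6-minute sessions for the analysis scripts, 10 × 50-step series for
the sampler checks, 200 null datasets for the familywise-error simulation,
20 datasets for parameter recovery.  Consequences worth knowing: the HEP
cluster contrast at n = 6 is underpowered (consistent with the power
analysis that demands 34 participants for d = 0.5 — the direct parietal
late-window amplitude difference still shows the injected suppression), and
the beta-band change point is poorly identified because the 3-µV beta
oscillation contributes little power over the 13–30 Hz band relative to the
1/f background.  Cluster detection power is instead demonstrated at n = 30
with waveform-level simulations, and change-point recovery across 20
repeated datasets in the model's native space.

## Limitations

- The generator's effect magnitudes are plausible but arbitrary; nothing
  here estimates or matches any real participant's physiology.
- The change-point model assumes a single change point shared across
  participants and iid observation noise within rows; both are
  simplifications the real transition need not respect.
- Regression-based baseline correction with per-channel covariates assumes
  the baseline–signal relationship is linear and stable across trials.
- The inhalation-rate test treats the per-second phase label as
  instantaneous; no circular statistics are attempted.
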