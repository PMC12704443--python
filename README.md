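# mwbody

Brain–body dynamics around self-caught mind-wandering reports: a tested,
fully synthetic-data-driven re-implementation of a multimodal
EEG/ECG/respiration analysis workflow.

## The problem

In self-caught mind-wandering (MW) paradigms, participants perform a simple
response task (pressing a key to tones, or at each end of exhalation) and
press a separate key the moment they notice their mind has wandered.  The
seconds before that report contain the transition from MW to awareness of
it.  Anchored to each report, three attentional states are defined:

- **MW**: `[report − 9, report − 5)` s,
- **aware**: `[report − 5, report − 1)` s (the final second is excluded to
  avoid report-related motor artifacts),
- **focus**: the 4 s from the first tone after task resumption.

The package implements everything needed to characterize brain–body
activity across these states and before the report:

- a **synthetic-data generator** producing seeded multichannel EEG (1/f
  background + alpha/beta oscillations whose envelopes bend at a known
  change point before each report + an R-peak-locked late potential on
  parietal channels), ECG with respiratory sinus arrhythmia and
  report-locked heart-rate changes, respiration belts with drift and noise,
  and a full event table — with every injected quantity returned as ground
  truth;
- **respiration**: 25-ms smoothing, linear detrend, 60-s sliding-baseline
  correction; extrema-based inhalation/exhalation segmentation; belt
  selection by cycle count; and the inhalation rate at each second before a
  report tested against a participant-specific baseline built from 10,000
  random draws of their whole phase sequence;
- **cardiac**: 3–30 Hz zero-phase filtering, adaptive-threshold R-peak
  detection with a 250-ms refractory period and quality flags, RR intervals
  labeled by attentional state or by second-before-report (ceiling rule: a
  beat 0.5 s before the report is labeled "1 s");
- **heartbeat-evoked potentials (HEP)**: −200…600 ms epochs around each R
  peak, a ≥10-report participant-inclusion rule, and *regression-based*
  baseline correction — per channel and time point, trial amplitude is
  modeled as `1 + baseline + condition + baseline×condition` (baseline =
  mean voltage over −200…−75 ms) and only the baseline-tied variance is
  removed, never a subtraction;
- **time–frequency**: Morlet power on a 2–40 Hz grid with cycles rising
  linearly from 3 (0.5 cycles/Hz), state-averaged channel × frequency maps,
  and the continuous band-power course over −9.4…−0.5 s before each report;
- **cluster statistics**: dependent-samples t maps thresholded at p < .05,
  summed-t clusters under channel ∪ axis adjacency, and a max-cluster
  sign-flip permutation null (1000 permutations, significance at p < .025
  per tail);
- **change-point model**: a Bayesian dual-trend state–space model

  ```
  Y[n,t] ~ Normal(mu_pre[n,t],  sigma_y[n])   if t <  tau
  Y[n,t] ~ Normal(mu_post[n,t], sigma_y[n])   if t >= tau
  mu[n,t]   = mu[n,t-1] + delta[t-1]
  delta[t]  = delta[t-1] + sigma_delta * eps[t],   eps ~ N(0,1)
  ```

  with trends shared across participants, half-Cauchy(0, 5) observation and
  half-Cauchy(0, 2.5) trend-scale priors, and a uniform prior on the
  discrete change point `tau`.  A bundled blocked Gibbs sampler (exact
  Gaussian latent draws, collapsed τ moves, slice-sampled scales with
  interweaving) runs the stated regime — 6000 iterations, 1000 burn-in,
  thinning 2, 4 chains → 2500 retained draws per chain, 10,000 total — and
  reports split-chain R-hat (criterion < 1.1) and ESS for every parameter.

## Worked example

```python
from mwbody import synth, timefreq, changepoint as cp
import numpy as np

# simulate 20 breathing-focused sessions with an alpha bend 4.7 s pre-report
courses = []
for i in range(20):
    cfg = synth.SimConfig(duration=150.0, n_mw_reports=4, seed=300 + i,
                          condition="BF", min_report_gap=25.0)
    rec = synth.simulate_recording(cfg)
    reports = rec.events.query("type == 'mw_report'")["onset_s"].to_numpy()
    _, c = timefreq.prereport_power_course(rec.eeg, rec.fs_eeg, reports,
                                           band="alpha")
    courses.append(c)

data = cp.CPData(Y=np.stack(courses)[:, ::5], step_dt=0.5, t0_offset=9.4)
post = cp.fit_mcmc(cp.build_model(data), chains=2, n_iter=1200,
                   burnin=400, thin=2, seed=3)
s = cp.summarize(post)
print(s["tau_seconds_before"], s["decrease_after_cp"])
```

prints a change point of **4.28 s before the report** (95% CI [3.90, 5.90]
s) with `decrease_after_cp = True` — the model recovers the injected
4.7-s alpha bend and certifies that the trend after the change point is
credibly lower than before it.

The numbered scripts under `analysis/` run the full study on a 6-participant
synthetic cohort (`python analysis/01_simulate.py`, then 02…07) and write
their tables to `results/study/`.  On that cohort they report, among other
things: reaction-time variability of 0.11 in the focus state versus ~0.34
during MW and the transition to awareness; ~8 fewer respiratory cycles per
session when breathing-focused (paired t(5) = −7.97); mean RR intervals of
0.875 s (focus) vs 0.929 s (MW); a parietal late-window HEP suppression of
−0.44 µV in the aware state (t(5) = −5.25); an alpha-band power drop in the
aware state detected as a significant 7–13 Hz cluster (p = .001); and an
alpha change point 4.01 s before the report (95% CI [3.90, 5.40]).

A file-based pipeline mirrors the scripts as subcommands
(`mwbody --outdir run --seed 1 all`), one stage per artifact, each with a
provenance sidecar.

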