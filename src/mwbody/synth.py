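"""Seeded multimodal recording simulator with ground truth.

Generates, per simulated session: a respiration belt trace (chest +
abdomen), an ECG with respiratory sinus arrhythmia and report-locked
heart-rate changes, multichannel EEG with state-dependent alpha/beta
envelopes containing a trend change point before each mind-wandering (MW)
report plus an R-peak-locked late potential on parietal channels, and an
event table (tones, presses, MW reports, resumptions).  Every injected
quantity is returned in a ground-truth record so downstream detectors and
models can be validated against it.

The generator is deliberately stylized: a fixed Gaussian QRS-like template
(only R-peak timing matters downstream), 1/f background EEG, and
phase-locked rate modulation for RSA.  One seeded generator per recording;
per-modality sub-streams are spawned deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .events import AttentionEpoch, label_states, make_event_table

DEFAULT_RESP_RATE = {"BF": 11.0, "SF": 15.0}  # cycles/min; slower when breath-focused
HEP_LATENCY = 0.48      # s after R peak, center of the injected late deflection
HEP_WIDTH = 0.05        # s Gaussian sd -> bulk of the bump in ~380-580 ms
PRE_REPORT_WINDOW = 9.4  # s before report over which band trends are injected


@dataclass
class SimConfig:
    """Study conditions for one simulated session."""

    duration: float = 720.0          # s (one 12-min session)
    n_channels: int = 16
    fs_eeg: float = 250.0            # Hz
    fs_physio: float = 250.0         # Hz
    n_mw_reports: int = 12
    condition: str = "BF"            # "BF" (breathing-focused) or "SF" (sound-focused)
    min_report_gap: float = 25.0     # s between MW reports
    seed: int = 0

    # EEG band dynamics (µV envelopes; change point in s before each report)
    alpha_cp_time: float = 4.7
    beta_cp_time: float = 3.5
    alpha_trend_pre: float = 0.0     # µV/s before the change point
    alpha_trend_post: float = -0.8   # µV/s after it (negative = decreasing)
    beta_trend_pre: float = 0.0
    beta_trend_post: float = -0.5
    alpha_amp: float = 6.0           # baseline envelope, µV
    beta_amp: float = 3.0
    pink_exponent: float = 1.0
    noise_sd_eeg: float = 10.0       # µV, 1/f background

    # Heartbeat-evoked late deflection on parietal channels, µV per state
    hep_late_amp_by_state: dict = field(
        default_factory=lambda: {"MW": 1.5, "aware": 0.0, "focus": 0.0, "none": 0.75}
    )

    # Cardiac
    base_hr: float = 70.0            # bpm
    rsa_gain: float = 4.0            # bpm swing with respiratory phase
    event_hr_profile: dict = field(
        default_factory=lambda: {1: 4.0, 2: -3.0, 3: -3.0, 4: -4.0, 5: -4.0,
                                 6: -4.0, 7: -4.0, 8: -4.0, 9: -4.0}
    )                                # bpm offset during [report-k, report-k+1):
                                     # slower heart rate through the MW/aware
                                     # windows, acceleration in the last second
    noise_sd_ecg: float = 0.03       # mV

    # Respiration
    resp_rate: float | None = None   # cycles/min; None -> condition default
    inhale_frac: float = 0.4         # fraction of the cycle spent inhaling
    rate_jitter: float = 0.05        # slow fractional modulation of cycle rate
    drift_slope: float = 0.02        # units/s linear drift
    drift_sin_amp: float = 0.3       # slow sinusoidal drift amplitude
    noise_sd_resp: float = 0.05

    # Behavior
    rt_mean: float = 0.45            # s
    rt_sd_by_state: dict = field(
        default_factory=lambda: {"focus": 0.05, "MW": 0.15, "aware": 0.15, "none": 0.08}
    )

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.condition not in ("BF", "SF"):
            raise ValueError("condition must be 'BF' or 'SF'")
        if self.fs_eeg <= 0 or self.fs_physio <= 0:
            raise ValueError("sampling rates must be > 0")
        if self.n_mw_reports < 0:
            raise ValueError("n_mw_reports must be >= 0")
        if self.effective_resp_rate <= 0:
            raise ValueError("resp_rate must be > 0")
        if not 0 < self.inhale_frac < 1:
            raise ValueError("inhale_frac must be in (0, 1)")
        if self.base_hr - abs(self.rsa_gain) <= 0:
            raise ValueError("base_hr - |rsa_gain| must be > 0")
        for cp in (self.alpha_cp_time, self.beta_cp_time):
            if not 0.0 < cp < PRE_REPORT_WINDOW:
                raise ValueError(
                    f"change-point time {cp} s outside the pre-report window "
                    f"(0, {PRE_REPORT_WINDOW})"
                )

    @property
    def effective_resp_rate(self) -> float:
        return self.resp_rate if self.resp_rate is not None else DEFAULT_RESP_RATE[self.condition]


@dataclass
class PhaseTruth:
    """Ground-truth respiratory phase: per-sample inhale flags + cycle onsets."""

    inhale: np.ndarray          # bool per sample (True = inhalation)
    cycle_onsets: np.ndarray    # sample indices where an inhalation starts
    fs: float


@dataclass
class SimRecording:
    eeg: np.ndarray             # channel x sample, µV
    ecg: np.ndarray             # sample, mV
    resp_chest: np.ndarray
    resp_abdomen: np.ndarray
    events: pd.DataFrame
    truth: dict
    ch_names: list
    ch_pos: np.ndarray          # channel x 2
    fs_eeg: float
    fs_physio: float
    condition: str


def _sub_rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_montage(n_channels: int):
    """Simple grid montage with row labels F/C/P/O (frontal...occipital).

    Parietal-row channels (names starting with 'P') carry the injected
    heartbeat-evoked deflection.
    """
    rows = ["F", "C", "P", "O"]
    per_row = int(np.ceil(n_channels / len(rows)))
    names, pos = [], []
    k = 0
    for i, row in enumerate(rows):
        for j in range(per_row):
            if k >= n_channels:
                break
            names.append(f"{row}{j + 1}")
            pos.append((j - (per_row - 1) / 2.0, (len(rows) - 1) / 2.0 - i))
            k += 1
    return names, np.asarray(pos, dtype=float)


def parietal_channels(ch_names) -> np.ndarray:
    return np.array([i for i, nm in enumerate(ch_names) if nm.startswith("P")], int)


# ---------------------------------------------------------------------------
# Respiration
# ---------------------------------------------------------------------------

def gen_respiration(cfg: SimConfig, rng=None):
    """Quasi-sinusoidal belt trace with drift + noise, and true phase labels.

    The cycle waveform rises (inhalation) over ``inhale_frac`` of the cycle
    and falls (exhalation) over the rest; cycle rate is slowly modulated by
    ``rate_jitter``.  Returns ``(trace, PhaseTruth)``.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_physio
    n = int(round(cfg.duration * fs))
    t = np.arange(n) / fs

    rate = cfg.effective_resp_rate / 60.0  # cycles/s
    if cfg.rate_jitter > 0:
        mod = rng.standard_normal(n)
        mod = uniform_filter1d(mod, size=max(1, int(20 * fs)), mode="nearest")
        sd = mod.std()
        mod = mod / sd * cfg.rate_jitter if sd > 0 else np.zeros(n)
        inst_rate = rate * np.clip(1.0 + mod, 0.2, 3.0)
    else:
        inst_rate = np.full(n, rate)

    phase = np.concatenate([[0.0], np.cumsum(inst_rate[:-1]) / fs])  # cycles
    u = phase % 1.0
    f = cfg.inhale_frac
    vol = np.where(u < f, -np.cos(np.pi * u / f), np.cos(np.pi * (u - f) / (1 - f)))
    inhale = u < f
    cycle_onsets = np.flatnonzero(np.diff(np.floor(phase), prepend=-1.0) > 0)

    drift = cfg.drift_slope * t + cfg.drift_sin_amp * np.sin(2 * np.pi * t / 120.0)
    noise = cfg.noise_sd_resp * rng.standard_normal(n) if cfg.noise_sd_resp > 0 else 0.0
    trace = vol + drift + noise
    return trace, PhaseTruth(inhale=inhale, cycle_onsets=cycle_onsets, fs=fs)


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def _place_reports(cfg: SimConfig, rng) -> np.ndarray:
    """MW report times with a minimum separation, away from recording edges."""
    if cfg.n_mw_reports == 0:
        return np.empty(0)
    lo, hi = 12.0, cfg.duration - 2.0
    gap = cfg.min_report_gap
    span = hi - lo - (cfg.n_mw_reports - 1) * gap
    if span < 0:
        raise ValueError("recording too short for n_mw_reports at min_report_gap")
    # stick-breaking: uniform slack distributed between consecutive reports
    slack = np.sort(rng.uniform(0.0, span, size=cfg.n_mw_reports))
    return lo + slack + gap * np.arange(cfg.n_mw_reports)


def _state_at(t: float, reports, focus_windows) -> str:
    for r in reports:
        if r - 9.0 <= t < r - 5.0:
            return "MW"
        if r - 5.0 <= t < r - 1.0:
            return "aware"
    for t0, t1 in focus_windows:
        if t0 <= t < t1:
            return "focus"
    return "none"


def gen_events(cfg: SimConfig, resp_truth: PhaseTruth | None = None, rng=None):
    """Event table: tones, presses, MW reports, resumptions.

    Tones follow a uniform 1.2-2.0 s ISI and are suppressed between a report
    and the resumption.  In the SF condition presses answer tones; in BF they
    are locked to exhalation ends (inhalation onsets of the true phase).
    Press timing noise depends on the attentional state at the cue.
    Returns ``(events, truth_dict)``.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    reports = _place_reports(cfg, rng)
    resumes = reports + rng.uniform(4.0, 8.0, size=reports.size)
    pauses = list(zip(reports, resumes))

    def in_pause(x):
        for a, b in pauses:
            if a <= x < b:
                return a, b
        return None

    tones = []
    t = 1.0 + rng.uniform(1.2, 2.0)
    while t < cfg.duration - 0.5:
        hit = in_pause(t)
        if hit is not None:
            t = hit[1] + rng.uniform(1.2, 2.0)
            continue
        tones.append(t)
        t += rng.uniform(1.2, 2.0)
    tones = np.asarray(tones)

    # focus windows (first tone after each resume + 4 s) for RT-noise labeling
    focus_windows = []
    for rs in resumes:
        after = tones[tones >= rs]
        if after.size:
            focus_windows.append((after[0], after[0] + 4.0))

    if cfg.condition == "SF":
        cues = tones
    else:
        if resp_truth is None:
            raise ValueError("BF condition needs resp_truth to place presses")
        cue_times = resp_truth.cycle_onsets / resp_truth.fs  # exhalation ends
        cues = np.array([c for c in cue_times if in_pause(c) is None and c > 1.0])

    presses = []
    for c in cues:
        state = _state_at(c, reports, focus_windows)
        sd = cfg.rt_sd_by_state.get(state, cfg.rt_sd_by_state["none"])
        rt = max(0.15, rng.normal(cfg.rt_mean, sd))
        p = c + rt
        if p < cfg.duration and in_pause(p) is None:
            presses.append(p)

    rows = (
        [(x, "tone") for x in tones]
        + [(x, "press") for x in presses]
        + [(x, "mw_report") for x in reports]
        + [(x, "resume") for x in resumes]
    )
    events = make_event_table(rows, condition=cfg.condition, participant="sim")
    truth = dict(
        report_times=reports,
        resume_times=resumes,
        focus_windows=np.asarray(focus_windows, dtype=float).reshape(-1, 2),
    )
    return events, truth


def gen_hct_trials(cfg: SimConfig, rng=None, accuracy: float = 0.85) -> pd.DataFrame:
    """Heartbeat-counting trials at the six standard windows (25...50 s)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    windows = np.array([25, 30, 35, 40, 45, 50], dtype=float)
    rng.shuffle(windows)
    actual = np.maximum(1, np.round(windows * cfg.base_hr / 60.0 + rng.normal(0, 1, 6)))
    reported = np.maximum(0, np.round(actual * np.clip(rng.normal(accuracy, 0.08, 6), 0, 1.3)))
    return pd.DataFrame({"window_s": windows, "actual": actual, "reported": reported})


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def _qrs_template(fs: float):
    """Stylized beat: Q/R/S Gaussians (~80 ms complex) plus a T wave; R at 0."""
    tt = np.arange(int(-0.08 * fs), int(0.42 * fs) + 1) / fs
    g = lambda mu, sd, a: a * np.exp(-0.5 * ((tt - mu) / sd) ** 2)
    w = g(0.0, 0.008, 1.0) + g(-0.028, 0.010, -0.12) + g(0.028, 0.010, -0.22) + g(0.28, 0.06, 0.18)
    return tt, w


def gen_ecg(cfg: SimConfig, resp_truth: PhaseTruth, report_times=None, rng=None):
    """Template ECG with RSA and report-locked heart-rate offsets.

    Instantaneous rate = ``base_hr + rsa_gain * rsa(t) + event profile`` where
    ``rsa(t)`` is +1 during inhalation and -1 during exhalation (smoothed),
    so RR intervals are shorter while inhaling.  Returns ``(trace_mV,
    r_peak_times_s)``.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if report_times is None:
        report_times = np.empty(0)
    fs = cfg.fs_physio
    n = resp_truth.inhale.size
    t = np.arange(n) / fs

    rsa = np.where(resp_truth.inhale, 1.0, -1.0)
    rsa = uniform_filter1d(rsa, size=max(1, int(0.5 * fs)), mode="nearest")
    hr = cfg.base_hr + cfg.rsa_gain * rsa
    for r in report_times:
        for k, bpm in cfg.event_hr_profile.items():
            a, b = r - float(k), r - float(k) + 1.0
            hr[(t >= a) & (t < b)] += bpm
    if np.any(hr <= 0):
        raise ValueError("instantaneous heart rate fell to <= 0")

    phase = np.concatenate([[0.0], np.cumsum(hr[:-1] / 60.0) / fs])
    beat_idx = np.flatnonzero(np.diff(np.floor(phase)) > 0) + 1
    peak_times = beat_idx / fs

    trace = np.zeros(n)
    tt, w = _qrs_template(fs)
    off = np.arange(tt.size) + int(round(tt[0] * fs))
    for b in beat_idx:
        idx = b + off
        ok = (idx >= 0) & (idx < n)
        trace[idx[ok]] += w[ok]
    if cfg.noise_sd_ecg > 0:
        trace = trace + cfg.noise_sd_ecg * rng.standard_normal(n)
    return trace, peak_times


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _pink_noise(rng, n_channels: int, n: int, exponent: float, sd: float):
    """1/f^exponent noise via spectral shaping, unit variance scaled to sd."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape, n=n, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return sd * out


def _band_envelope(t, reports, base_amp, cp_time, trend_pre, trend_post):
    """Per-sample envelope: flat at base_amp, two-segment linear trend in the
    pre-report window anchored at the change point (clipped at 0)."""
    env = np.full(t.size, base_amp)
    for r in reports:
        tc = r - cp_time
        w0 = r - PRE_REPORT_WINDOW
        pre = (t >= w0) & (t < tc)
        post = (t >= tc) & (t <= r)
        env[pre] = base_amp + trend_pre * (t[pre] - tc)
        env[post] = base_amp + trend_post * (t[post] - tc)
    return np.clip(env, 0.0, None)


def gen_eeg(cfg: SimConfig, r_peaks, report_times, focus_windows=None, rng=None):
    """Multichannel EEG: pink background + alpha/beta with injected trends +
    an R-peak-locked late deflection on parietal channels.

    Returns ``(eeg, truth)`` where truth carries the per-band envelopes, the
    per-report change-point times and the per-peak injected late amplitude.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if focus_windows is None:
        focus_windows = []
    fs = cfg.fs_eeg
    n = int(round(cfg.duration * fs))
    t = np.arange(n) / fs
    ch_names, ch_pos = make_montage(cfg.n_channels)

    eeg = _pink_noise(rng, cfg.n_channels, n, cfg.pink_exponent, cfg.noise_sd_eeg)

    env_a = _band_envelope(t, report_times, cfg.alpha_amp, cfg.alpha_cp_time,
                           cfg.alpha_trend_pre, cfg.alpha_trend_post)
    env_b = _band_envelope(t, report_times, cfg.beta_amp, cfg.beta_cp_time,
                           cfg.beta_trend_pre, cfg.beta_trend_post)
    for c in range(cfg.n_channels):
        pa = rng.uniform(0, 2 * np.pi)
        pb = rng.uniform(0, 2 * np.pi)
        eeg[c] += env_a * np.sin(2 * np.pi * 10.0 * t + pa)
        eeg[c] += env_b * np.sin(2 * np.pi * 20.0 * t + pb)

    # heartbeat-locked late deflection on parietal channels
    par = parietal_channels(ch_names)
    bump_t = np.arange(int((HEP_LATENCY - 4 * HEP_WIDTH) * fs),
                       int((HEP_LATENCY + 4 * HEP_WIDTH) * fs) + 1)
    bump = np.exp(-0.5 * ((bump_t / fs - HEP_LATENCY) / HEP_WIDTH) ** 2)
    hep_amp = np.zeros(len(r_peaks))
    for i, pk in enumerate(np.asarray(r_peaks, dtype=float)):
        state = _state_at(pk, report_times, focus_windows)
        amp = cfg.hep_late_amp_by_state.get(state, cfg.hep_late_amp_by_state["none"])
        hep_amp[i] = amp
        if amp == 0.0:
            continue
        idx = int(round(pk * fs)) + bump_t
        ok = (idx >= 0) & (idx < n)
        if par.size:
            eeg[np.ix_(par, idx[ok])] += amp * bump[ok]

    truth = dict(
        alpha_envelope=env_a,
        beta_envelope=env_b,
        alpha_cp_times=np.asarray(report_times) - cfg.alpha_cp_time,
        beta_cp_times=np.asarray(report_times) - cfg.beta_cp_time,
        hep_amp_per_peak=hep_amp,
        parietal_channels=par,
    )
    return eeg, truth


# ---------------------------------------------------------------------------
# Full recording / study
# ---------------------------------------------------------------------------

def simulate_recording(cfg: SimConfig) -> SimRecording:
    """Generate one fully synchronized session with ground truth."""
    cfg.validate()
    r_resp, r_ab, r_ev, r_ecg, r_eeg, r_hct = _sub_rngs(cfg.seed, 6)

    resp_chest, phase_truth = gen_respiration(cfg, rng=r_resp)
    ab_cfg = replace(cfg, noise_sd_resp=cfg.noise_sd_resp * 2.0,
                     drift_slope=-cfg.drift_slope)
    # abdomen shares the true phase stream; rebuild trace from it with its own noise
    n = phase_truth.inhale.size
    t = np.arange(n) / cfg.fs_physio
    u = _phase_fraction(phase_truth)
    f = cfg.inhale_frac
    vol_ab = np.where(u < f, -np.cos(np.pi * u / f), np.cos(np.pi * (u - f) / (1 - f)))
    resp_abdomen = (0.8 * vol_ab + ab_cfg.drift_slope * t
                    + ab_cfg.drift_sin_amp * np.sin(2 * np.pi * t / 90.0)
                    + ab_cfg.noise_sd_resp * r_ab.standard_normal(n))

    events, ev_truth = gen_events(cfg, resp_truth=phase_truth, rng=r_ev)
    reports = ev_truth["report_times"]
    ecg, r_peaks = gen_ecg(cfg, phase_truth, report_times=reports, rng=r_ecg)
    eeg, eeg_truth = gen_eeg(cfg, r_peaks, reports,
                             focus_windows=ev_truth["focus_windows"], rng=r_eeg)
    hct = gen_hct_trials(cfg, rng=r_hct)
    ch_names, ch_pos = make_montage(cfg.n_channels)

    truth = dict(
        r_peak_times=r_peaks,
        inhale=phase_truth.inhale,
        cycle_onsets=phase_truth.cycle_onsets,
        hct_trials=hct,
        **ev_truth,
        **eeg_truth,
    )
    return SimRecording(
        eeg=eeg, ecg=ecg, resp_chest=resp_chest, resp_abdomen=resp_abdomen,
        events=events, truth=truth, ch_names=ch_names, ch_pos=ch_pos,
        fs_eeg=cfg.fs_eeg, fs_physio=cfg.fs_physio, condition=cfg.condition,
    )


def _phase_fraction(truth: PhaseTruth) -> np.ndarray:
    """Reconstruct the within-cycle fraction u in [0,1) from truth labels.

    Piecewise linear between cycle onsets; used to rebuild a second belt
    trace sharing the same true phase.
    """
    n = truth.inhale.size
    u = np.zeros(n)
    on = truth.cycle_onsets
    for i, s in enumerate(on):
        e = on[i + 1] if i + 1 < on.size else n
        if e > s:
            u[s:e] = np.arange(e - s) / (e - s)
    if on.size and on[0] > 0:
        u[: on[0]] = np.linspace(0.5, 1.0, on[0], endpoint=False)
    return u


def labeled_epochs(rec: SimRecording) -> list[AttentionEpoch]:
    """Convenience: attentional-state epochs of a simulated recording."""
    return label_states(rec.events, rec_start=0.0, rec_end=rec.fs_eeg and rec.eeg.shape[1] / rec.fs_eeg)


def simulate_study(
    n_participants: int,
    seed: int = 0,
    duration: float = 480.0,
    n_mw_reports: int = 12,
    n_channels: int = 16,
    **overrides,
):
    """Simulate a BF + SF session pair for each participant.

    Between-participant heterogeneity: resting heart rate, respiration rate
    and report counts vary around the condition defaults.  Returns a list of
    ``{"BF": SimRecording, "SF": SimRecording}`` dicts.
    """
    master = np.random.SeedSequence(seed)
    out = []
    for p, ss in enumerate(master.spawn(n_participants)):
        prng = np.random.default_rng(ss)
        hr = float(np.clip(prng.normal(70, 7), 52, 95))
        max_rep = max(3, int((duration - 40.0) / 30.0))
        n_rep = int(np.clip(prng.poisson(n_mw_reports), 3, max_rep))
        recs = {}
        for cond in ("BF", "SF"):
            rate = DEFAULT_RESP_RATE[cond] * float(prng.uniform(0.9, 1.1))
            cfg = SimConfig(
                duration=duration,
                n_channels=n_channels,
                n_mw_reports=n_rep,
                condition=cond,
                base_hr=hr,
                resp_rate=rate,
                seed=int(prng.integers(0, 2**31 - 1)),
                **overrides,
            )
            rec = simulate_recording(cfg)
            rec.events["participant"] = f"p{p:02d}"
            recs[cond] = rec
        out.append(recs)
    return out
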