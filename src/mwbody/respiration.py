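"""Respiration preprocessing, phase detection, and the pre-report
inhalation-rate analysis against a resampled null.

The preprocessing chain is: 25-ms moving-average smoothing, global linear
detrend, then subtraction of a 60-s sliding mean (edges use the mean over
the valid part of the window).  Phases are segmented from signal extrema:
inhalation runs trough-to-peak, exhalation peak-to-trough, with a minimum
cycle duration and a prominence criterion to reject noise peaks.

The inhalation-rate test asks whether being in the inhalation phase at a
fixed lag before a mind-wandering report is more or less likely than a
participant-specific baseline, where the baseline is the inhalation
fraction over many random draws from that participant's whole phase
sequence.  Participant-level rate-minus-baseline differences are tested
against zero with a one-sample t test per lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.ndimage import uniform_filter1d

logger = logging.getLogger(__name__)

SMOOTH_WINDOW_S = 0.025
BASELINE_WINDOW_S = 60.0
DEFAULT_NULL_DRAWS = 10_000


@dataclass
class PhaseSeries:
    """Per-sample inhale/exhale labels with cycle boundaries."""

    inhale: np.ndarray          # bool per sample
    cycle_onsets: np.ndarray    # sample indices of inhalation starts (troughs)
    fs: float

    def __post_init__(self):
        self.inhale = np.asarray(self.inhale, dtype=bool)
        self.cycle_onsets = np.asarray(self.cycle_onsets, dtype=int)
        if np.any(np.diff(self.cycle_onsets) <= 0):
            raise ValueError("cycle onsets must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        """Complete inhale+exhale cycles (onset-to-onset intervals)."""
        return max(0, self.cycle_onsets.size - 1)

    @property
    def inhale_fraction(self) -> float:
        return float(self.inhale.mean()) if self.inhale.size else np.nan

    def label_at(self, times_s) -> np.ndarray:
        """True where the sample nearest each time is inhalation."""
        idx = np.clip(np.round(np.asarray(times_s) * self.fs).astype(int),
                      0, self.inhale.size - 1)
        return self.inhale[idx]


def _sliding_mean(x: np.ndarray, win: int) -> np.ndarray:
    # centered rolling mean; at the edges the mean is over the valid part
    return (
        pd.Series(x).rolling(win, center=True, min_periods=1).mean().to_numpy()
    )


def preprocess_resp(trace: np.ndarray, fs: float) -> np.ndarray:
    """Smooth, detrend and baseline-correct a raw belt trace."""
    x = np.asarray(trace, dtype=float)
    smooth_n = max(1, int(round(SMOOTH_WINDOW_S * fs)))
    if x.size <= smooth_n:
        raise ValueError("trace shorter than the smoothing window")
    x = _sliding_mean(x, smooth_n)
    x = signal.detrend(x, type="linear")
    base_n = min(x.size, int(round(BASELINE_WINDOW_S * fs)))
    return x - _sliding_mean(x, base_n)


def detect_phases(
    trace: np.ndarray,
    fs: float,
    min_cycle_s: float = 1.0,
    prominence_frac: float = 0.3,
) -> PhaseSeries:
    """Extrema-based phase segmentation of a preprocessed trace.

    Peaks and troughs must be at least ``min_cycle_s`` apart (same type) and
    have prominence above ``prominence_frac`` times the trace interquartile
    range.  Samples before the first extremum inherit the phase implied by
    the first segment.
    """
    x = np.asarray(trace, dtype=float)
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    prom = prominence_frac * iqr if iqr > 0 else None
    dist = max(1, int(round(min_cycle_s * fs)))
    peaks, _ = signal.find_peaks(x, distance=dist, prominence=prom)
    troughs, _ = signal.find_peaks(-x, distance=dist, prominence=prom)
    if peaks.size == 0 or troughs.size == 0:
        logger.warning("no detectable respiratory cycles")
        return PhaseSeries(np.zeros(x.size, bool), np.empty(0, int), fs)

    # merge into a strictly alternating trough/peak sequence, keeping the more
    # extreme of any same-type run
    ext = sorted([(i, +1) for i in peaks] + [(i, -1) for i in troughs])
    seq = []
    for i, kind in ext:
        if seq and seq[-1][1] == kind:
            j, _ = seq[-1]
            better = i if kind * x[i] > kind * x[j] else j
            seq[-1] = (better, kind)
        else:
            seq.append((i, kind))

    inhale = np.zeros(x.size, dtype=bool)
    for (i0, k0), (i1, _) in zip(seq[:-1], seq[1:]):
        inhale[i0:i1] = k0 == -1  # trough -> peak = inhalation
    # tails: before the first extremum, the opposite of the first segment;
    # after the last extremum, the segment started by the last extremum
    first_i, first_k = seq[0]
    inhale[:first_i] = first_k == +1
    last_i, last_k = seq[-1]
    inhale[last_i:] = last_k == -1
    onsets = np.array([i for i, k in seq if k == -1], dtype=int)
    return PhaseSeries(inhale=inhale, cycle_onsets=onsets, fs=fs)


def select_channel(chest: PhaseSeries, abdomen: PhaseSeries) -> PhaseSeries:
    """Pick the belt with more detected cycles (ties -> chest)."""
    if chest.n_cycles == 0 and abdomen.n_cycles == 0:
        raise ValueError("no respiratory cycles detected on either belt")
    if abdomen.n_cycles > chest.n_cycles:
        return abdomen
    if abdomen.n_cycles == chest.n_cycles:
        logger.info("equal cycle counts; keeping chest belt")
    return chest


def cycle_count(phase: PhaseSeries) -> int:
    """Number of complete respiratory cycles in the series."""
    return phase.n_cycles


def inhalation_baseline(
    phase: PhaseSeries, n_draws: int = DEFAULT_NULL_DRAWS, seed: int | None = 0
) -> float:
    """Chance-level inhalation proportion from random draws (with
    replacement) over the whole phase sequence."""
    if phase.inhale.size == 0:
        raise ValueError("empty phase series")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, phase.inhale.size, size=n_draws)
    return float(phase.inhale[idx].mean())


def inhalation_rate_test(
    phases: dict,
    report_times: dict,
    offsets=range(0, 6),
    baselines: dict | None = None,
    n_draws: int = DEFAULT_NULL_DRAWS,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-lag inhalation rate before reports vs. participant baselines.

    ``phases`` and ``report_times`` map participant id -> PhaseSeries /
    report times.  For each participant and lag k the rate is the fraction
    of reports whose sample at (report - k) s is inhalation; the one-sample
    t test is run across participants on rate - own baseline.  Returns a
    frame with columns offset_s, mean_rate, mean_baseline, t, p, d, n.
    """
    pids = [p for p, r in report_times.items() if len(np.atleast_1d(r)) > 0]
    dropped = set(report_times) - set(pids)
    if dropped:
        logger.info("excluding participants with no reports: %s", sorted(dropped))
    if len(pids) < 2:
        raise ValueError("need at least two participants with reports")
    if baselines is None:
        baselines = {
            p: inhalation_baseline(phases[p], n_draws=n_draws, seed=seed + i)
            for i, p in enumerate(sorted(pids))
        }
    rows = []
    for k in offsets:
        rates, bases = [], []
        for p in pids:
            r = np.atleast_1d(np.asarray(report_times[p], dtype=float))
            lab = phases[p].label_at(r - float(k))
            rates.append(lab.mean())
            bases.append(baselines[p])
        rates = np.asarray(rates)
        bases = np.asarray(bases)
        diff = rates - bases
        t, p_val = stats.ttest_1samp(diff, 0.0)
        sd = diff.std(ddof=1)
        d = diff.mean() / sd if sd > 0 else np.nan
        rows.append(dict(offset_s=k, mean_rate=rates.mean(),
                         mean_baseline=bases.mean(), t=float(t),
                         p=float(p_val), d=float(d), n=len(pids)))
    return pd.DataFrame(rows)
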