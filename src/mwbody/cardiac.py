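"""ECG filtering, R-peak detection and RR-interval labeling.

R peaks anchor two things downstream: heartbeat-evoked potential epochs and
the cardiac chronometry around mind-wandering reports.  Detection is
polarity-invariant adaptive thresholding with a 250-ms refractory period;
intervals that deviate strongly from the local median are flagged for
review rather than silently dropped (the manual-inspection step of a lab
workflow is replaced by these quality flags).

Two labeling schemes operate on the same RR series without mutating it:

* by attentional state -- an interval belongs to the epoch containing its
  onset beat, ensemble-averaged per participant x state;
* by second before report -- an interval whose onset beat falls in
  ``(k-1, k]`` s before a report is labeled "k s" (ceiling convention, so a
  beat exactly 2.0 s before the report is labeled 2 s); beats 0-2 s before
  the report additionally carry the inhalation-period tag and 2-4 s the
  exhalation-period tag (fixed time-window proxies for respiratory phase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import maximum_filter1d

logger = logging.getLogger(__name__)

REFRACTORY_S = 0.25
RR_MIN_S, RR_MAX_S = 0.25, 3.0   # physiological plausibility gate


@dataclass
class RPeakSeries:
    times: np.ndarray            # s from recording start, strictly increasing
    fs: float
    flags: np.ndarray            # bool per peak, True = quality concern

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.flags = np.asarray(self.flags, dtype=bool)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("peak times must be strictly increasing")


def filter_ecg(raw: np.ndarray, fs: float, band=(3.0, 30.0), order: int = 4) -> np.ndarray:
    """Zero-phase 3-30 Hz band-pass."""
    if fs <= 2 * band[1]:
        raise ValueError(f"fs={fs} too low for a {band[1]} Hz band edge")
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(raw, dtype=float))


def detect_rpeaks(
    filtered: np.ndarray,
    fs: float,
    threshold_frac: float = 0.4,
    rolling_window_s: float = 2.0,
    flag_dev: float = 0.3,
) -> RPeakSeries:
    """Adaptive-threshold R-peak picking on a band-passed ECG.

    A candidate extremum of |x| must exceed ``threshold_frac`` times the
    local rolling maximum of |x| (window ``rolling_window_s``) and a global
    noise floor; candidates within the 250-ms refractory period of a larger
    one are discarded.  Peaks whose neighboring RR interval deviates more
    than ``flag_dev`` from the local median RR are flagged.
    """
    x = np.abs(np.asarray(filtered, dtype=float))
    if x.size == 0 or np.all(x == 0):
        return RPeakSeries(np.empty(0), fs, np.empty(0, bool))
    win = max(1, int(round(rolling_window_s * fs)))
    local_max = maximum_filter1d(x, size=win, mode="nearest")
    floor = 4.0 * np.median(x) + 1e-12
    thr = np.maximum(threshold_frac * local_max, floor)

    cand, _ = signal.find_peaks(x, distance=max(1, int(round(REFRACTORY_S * fs))))
    cand = cand[x[cand] > thr[cand]]
    if cand.size == 0:
        return RPeakSeries(np.empty(0), fs, np.empty(0, bool))

    times = cand / fs
    flags = np.zeros(times.size, dtype=bool)
    rr = np.diff(times)
    if rr.size >= 3:
        med = pd.Series(rr).rolling(11, center=True, min_periods=3).median().to_numpy()
        bad = np.abs(rr - med) > flag_dev * med
        flags[1:] |= bad
        flags[:-1] |= bad
    flags |= np.concatenate([[False], (np.diff(times) < RR_MIN_S)])
    return RPeakSeries(times=times, fs=fs, flags=flags)


def rr_intervals(peaks: RPeakSeries, drop_flagged: bool = False) -> pd.DataFrame:
    """Beat-to-beat intervals tagged with the onset-beat time.

    Columns: ``onset_s`` (earlier beat), ``rr_s``, ``plausible`` (within the
    0.25-3 s physiological gate).
    """
    t = peaks.times
    if drop_flagged:
        t = t[~peaks.flags]
    rr = np.diff(t)
    df = pd.DataFrame({"onset_s": t[:-1], "rr_s": rr})
    df["plausible"] = (rr > RR_MIN_S) & (rr < RR_MAX_S)
    n_bad = int((~df["plausible"]).sum())
    if n_bad:
        logger.info("%d RR intervals outside the plausibility gate", n_bad)
    return df


def rr_by_state(rr: pd.DataFrame, epochs) -> pd.DataFrame:
    """Mean RR per participant x state x condition (onset-beat containment)."""
    rows = []
    for e in epochs:
        sel = rr.loc[(rr["onset_s"] >= e.t_start) & (rr["onset_s"] < e.t_end)]
        for _, r in sel.iterrows():
            rows.append(dict(participant=e.participant, condition=e.condition,
                             state=e.state, rr_s=r["rr_s"]))
    if not rows:
        return pd.DataFrame(columns=["participant", "condition", "state", "mean_rr_s", "n_beats"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["participant", "condition", "state"], as_index=False)
        .agg(mean_rr_s=("rr_s", "mean"), n_beats=("rr_s", "size"))
    )
    return out


def rr_by_second(rr: pd.DataFrame, report_times, horizon: float = 4.0) -> pd.DataFrame:
    """Label intervals by the second before the nearest upcoming report.

    The label is ``ceil(report - onset_beat)`` for beats within ``horizon``
    s before a report: a beat 0.5 s before the report is labeled 1, a beat
    exactly 2.0 s before is labeled 2.  Multiple beats in the same bin all
    receive that bin's label.  Beats beyond the horizon are unlabeled (0).
    """
    if horizon > 9.0:
        raise ValueError("horizon must be <= 9 s (inside the pre-report windows)")
    out = rr.copy()
    out["second_label"] = 0
    reports = np.sort(np.asarray(report_times, dtype=float))
    if reports.size:
        onset = out["onset_s"].to_numpy()
        nxt = np.searchsorted(reports, onset, side="left")
        has = nxt < reports.size
        dt = np.where(has, reports[np.minimum(nxt, reports.size - 1)] - onset, np.inf)
        lab = np.ceil(dt)
        sel = (dt > 0) & (dt <= horizon)
        out.loc[sel, "second_label"] = lab[sel].astype(int)
    return out


def label_rr_resp_phase(rr_labeled: pd.DataFrame) -> pd.DataFrame:
    """Tag the second-labeled intervals with the respiratory-period proxy:
    seconds 1-2 before the report -> inhalation period, 3-4 -> exhalation."""
    out = rr_labeled.copy()
    out["resp_period"] = ""
    out.loc[out["second_label"].isin([1, 2]), "resp_period"] = "inhalation"
    out.loc[out["second_label"].isin([3, 4]), "resp_period"] = "exhalation"
    return out
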