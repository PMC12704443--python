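"""Event tables, attentional-state labeling, and behavioral metrics.

Experiments with the self-caught method yield a sparse event stream per
session: tone onsets, key presses, mind-wandering (MW) reports, and task
resumptions.  Analysis windows are anchored to the MW reports:

* MW state      -- ``[report - 9, report - 5)`` s,
* aware state   -- ``[report - 5, report - 1)`` s (the second immediately
  before the report is excluded to avoid report-related motor artifacts),
* focus state   -- 4 s beginning at the first tone after task resumption.

Reports that follow the preceding report by less than 10 s are excluded
from signal epoching (their windows would overlap the previous report's
aftermath); they are still counted for behavioral summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["onset_s", "type", "condition", "participant"]
EVENT_TYPES = {"tone", "press", "mw_report", "resume", "hct_start", "hct_stop"}

MW_WINDOW = (9.0, 5.0)      # seconds before report: [report-9, report-5)
AWARE_WINDOW = (5.0, 1.0)   # seconds before report: [report-5, report-1)
FOCUS_LEN = 4.0             # seconds after the first post-resume tone
MIN_REPORT_GAP = 10.0       # reports closer than this to the previous one
                            # are excluded from signal epoching


@dataclass(frozen=True)
class AttentionEpoch:
    """A state-labeled half-open time window ``[t_start, t_end)``."""

    state: str              # "MW" | "aware" | "focus"
    t_start: float
    t_end: float
    anchor: float           # onset of the report/resume the epoch is tied to
    condition: str
    participant: str

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ValueError("epoch must have t_end > t_start")


def make_event_table(rows, condition: str = "", participant: str = "") -> pd.DataFrame:
    """Build a sorted event table from ``(onset_s, type)`` pairs."""
    df = pd.DataFrame(rows, columns=["onset_s", "type"])
    df["condition"] = condition
    df["participant"] = participant
    return df.sort_values("onset_s", kind="stable").reset_index(drop=True)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df


def write_events_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def retained_reports(report_times, min_gap: float = MIN_REPORT_GAP) -> np.ndarray:
    """Drop reports within ``min_gap`` s of the *preceding* report.

    The first report is always retained; exclusion is evaluated against the
    previous report in the raw sequence (not the previous retained one), so
    a burst of closely spaced reports keeps only its first member.
    """
    times = np.sort(np.asarray(report_times, dtype=float))
    if times.size == 0:
        return times
    keep = np.ones(times.size, dtype=bool)
    keep[1:] = np.diff(times) >= min_gap
    return times[keep]


def label_states(
    events: pd.DataFrame,
    rec_start: float = 0.0,
    rec_end: float | None = None,
    min_gap: float = MIN_REPORT_GAP,
) -> list[AttentionEpoch]:
    """Derive MW / aware / focus epochs from an event table.

    Epochs extending outside ``[rec_start, rec_end]`` are dropped.  A focus
    epoch requires a tone after the resumption; resumptions without one are
    logged and skipped.
    """
    if rec_end is None:
        rec_end = float(events["onset_s"].max()) if len(events) else 0.0
    condition = str(events["condition"].iloc[0]) if len(events) else ""
    participant = str(events["participant"].iloc[0]) if len(events) else ""

    reports = events.loc[events["type"] == "mw_report", "onset_s"].to_numpy(float)
    resumes = events.loc[events["type"] == "resume", "onset_s"].to_numpy(float)
    tones = events.loc[events["type"] == "tone", "onset_s"].to_numpy(float)

    epochs: list[AttentionEpoch] = []

    def _try_add(state, t0, t1, anchor):
        if t0 >= rec_start and t1 <= rec_end:
            epochs.append(AttentionEpoch(state, t0, t1, anchor, condition, participant))

    for r in retained_reports(reports, min_gap):
        _try_add("MW", r - MW_WINDOW[0], r - MW_WINDOW[1], r)
        _try_add("aware", r - AWARE_WINDOW[0], r - AWARE_WINDOW[1], r)

    for rs in np.sort(resumes):
        after = tones[tones >= rs]
        if after.size == 0:
            logger.info("resume at %.2f s has no subsequent tone; no focus epoch", rs)
            continue
        t0 = float(after[0])
        _try_add("focus", t0, t0 + FOCUS_LEN, rs)

    return sorted(epochs, key=lambda e: e.t_start)


def epochs_to_frame(epochs: list[AttentionEpoch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                state=e.state,
                t_start=e.t_start,
                t_end=e.t_end,
                anchor=e.anchor,
                condition=e.condition,
                participant=e.participant,
            )
            for e in epochs
        ],
        columns=["state", "t_start", "t_end", "anchor", "condition", "participant"],
    )


def match_presses(events: pd.DataFrame, max_latency: float = 1.2) -> pd.DataFrame:
    """Pair each press with the most recent unmatched tone within ``max_latency`` s.

    Returns a frame with columns ``tone_s``, ``press_s``, ``rt``.  Presses
    with no eligible tone are ignored.
    """
    tones = events.loc[events["type"] == "tone", "onset_s"].to_numpy(float)
    presses = events.loc[events["type"] == "press", "onset_s"].to_numpy(float)
    tones.sort()
    presses.sort()
    used = np.zeros(tones.size, dtype=bool)
    out = []
    for p in presses:
        i = np.searchsorted(tones, p, side="right") - 1
        while i >= 0 and (used[i] or p - tones[i] > max_latency):
            if p - tones[i] > max_latency:
                break
            i -= 1
        if i >= 0 and not used[i] and 0.0 <= p - tones[i] <= max_latency:
            used[i] = True
            out.append((tones[i], p, p - tones[i]))
    return pd.DataFrame(out, columns=["tone_s", "press_s", "rt"])


def reaction_metrics(
    events: pd.DataFrame,
    epochs: list[AttentionEpoch],
    max_latency: float = 1.2,
) -> pd.DataFrame:
    """Per-state mean reaction time and reaction-time variability.

    RTV is the coefficient of variation sd(RT)/mean(RT) within each state,
    with the sample (n-1) standard deviation.  States with fewer than two
    matched responses get ``NaN`` metrics and ``n`` reported, rather than a
    silent zero.  Responses are assigned to the state whose window contains
    the tone onset.
    """
    pairs = match_presses(events, max_latency=max_latency)
    rows = []
    for state in ("focus", "MW", "aware"):
        wins = [(e.t_start, e.t_end) for e in epochs if e.state == state]
        if wins:
            mask = np.zeros(len(pairs), dtype=bool)
            for t0, t1 in wins:
                mask |= (pairs["tone_s"] >= t0) & (pairs["tone_s"] < t1)
            rts = pairs.loc[mask, "rt"].to_numpy()
        else:
            rts = np.empty(0)
        n = rts.size
        mean = float(np.mean(rts)) if n else math.nan
        if n >= 2:
            sd = float(np.std(rts, ddof=1))
            rtv = sd / mean if mean else math.nan
        else:
            sd, rtv = math.nan, math.nan
            if n == 0:
                logger.info("no matched responses in state %s", state)
        rows.append(dict(state=state, n=n, rt_mean=mean, rt_sd=sd, rtv=rtv))
    return pd.DataFrame(rows)


def iacc(actual, reported) -> float:
    """Heartbeat-counting interoceptive accuracy: ``1 - |actual - reported| / actual``.

    Scalars give the per-trial score; sequences give the mean of per-trial
    scores.  ``actual`` must be positive.
    """
    actual = np.atleast_1d(np.asarray(actual, dtype=float))
    reported = np.atleast_1d(np.asarray(reported, dtype=float))
    if np.any(actual <= 0):
        raise ValueError("actual heartbeat count must be > 0")
    if actual.shape != reported.shape:
        raise ValueError("actual and reported must have the same shape")
    scores = 1.0 - np.abs(actual - reported) / actual
    return float(scores.mean())
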