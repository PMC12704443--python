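"""Study-level drivers: run each analysis stage over a set of recordings.

These functions operate on in-memory recordings (one BF + SF pair per
participant, as produced by :func:`mwbody.synth.simulate_study` or loaded
from disk) and return tidy tables / result objects.  The file-based
pipeline (:mod:`mwbody.pipeline`) and the numbered analysis scripts are
thin wrappers around them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import cardiac, cluster, hep, respiration, timefreq
from .events import label_states
from .synth import SimRecording, parietal_channels

logger = logging.getLogger(__name__)

CONDITIONS = ("BF", "SF")


def _participants(study) -> list:
    return [recs["BF"].events["participant"].iloc[0] for recs in study]


def recording_epochs(rec: SimRecording):
    dur = rec.eeg.shape[1] / rec.fs_eeg
    return label_states(rec.events, rec_start=0.0, rec_end=dur)


def mw_report_counts(study) -> dict:
    """Total mind-wandering reports per participant (both conditions)."""
    out = {}
    for recs in study:
        pid = recs["BF"].events["participant"].iloc[0]
        out[pid] = sum(
            int((recs[c].events["type"] == "mw_report").sum()) for c in CONDITIONS
        )
    return out


# ---------------------------------------------------------------------------
# respiration
# ---------------------------------------------------------------------------

def participant_phases(rec: SimRecording) -> respiration.PhaseSeries:
    """Preprocess both belts, detect phases, keep the belt with more cycles."""
    out = []
    for trace in (rec.resp_chest, rec.resp_abdomen):
        clean = respiration.preprocess_resp(trace, rec.fs_physio)
        out.append(respiration.detect_phases(clean, rec.fs_physio))
    return respiration.select_channel(*out)


def analyze_respiration(study, offsets=range(0, 6), seed: int = 0):
    """Cycle counts per condition and the pre-report inhalation-rate test.

    Returns ``(cycles_df, rate_tests: {condition: DataFrame})``.
    """
    cyc_rows = []
    phases = {c: {} for c in CONDITIONS}
    reports = {c: {} for c in CONDITIONS}
    for recs in study:
        pid = recs["BF"].events["participant"].iloc[0]
        for cond in CONDITIONS:
            rec = recs[cond]
            ph = participant_phases(rec)
            phases[cond][pid] = ph
            reports[cond][pid] = rec.events.loc[
                rec.events["type"] == "mw_report", "onset_s"
            ].to_numpy(float)
            cyc_rows.append(dict(participant=pid, condition=cond,
                                 n_cycles=respiration.cycle_count(ph)))
    tests = {}
    for cond in CONDITIONS:
        try:
            tests[cond] = respiration.inhalation_rate_test(
                phases[cond], reports[cond], offsets=offsets, seed=seed
            )
        except ValueError as exc:
            logger.warning("inhalation-rate test skipped for %s: %s", cond, exc)
    return pd.DataFrame(cyc_rows), tests


# ---------------------------------------------------------------------------
# cardiac
# ---------------------------------------------------------------------------

def participant_rpeaks(rec: SimRecording) -> cardiac.RPeakSeries:
    filt = cardiac.filter_ecg(rec.ecg, rec.fs_physio)
    return cardiac.detect_rpeaks(filt, rec.fs_physio)


def analyze_cardiac(study):
    """RR by attentional state and RR by second-before-report, all
    participants and conditions."""
    state_rows, second_rows = [], []
    for recs in study:
        pid = recs["BF"].events["participant"].iloc[0]
        for cond in CONDITIONS:
            rec = recs[cond]
            peaks = participant_rpeaks(rec)
            rr = cardiac.rr_intervals(peaks)
            epochs = recording_epochs(rec)
            st = cardiac.rr_by_state(rr, epochs)
            state_rows.append(st)
            rep = rec.events.loc[rec.events["type"] == "mw_report", "onset_s"]
            lab = cardiac.rr_by_second(rr, rep.to_numpy(float))
            lab = cardiac.label_rr_resp_phase(lab)
            lab = lab[lab["second_label"] > 0]
            g = lab.groupby("second_label", as_index=False)["rr_s"].mean()
            g["participant"] = pid
            g["condition"] = cond
            second_rows.append(g)
    rr_state = (pd.concat(state_rows, ignore_index=True)
                if state_rows else pd.DataFrame())
    rr_second = (pd.concat(second_rows, ignore_index=True)
                 if second_rows else pd.DataFrame())
    return rr_state, rr_second


# ---------------------------------------------------------------------------
# HEP
# ---------------------------------------------------------------------------

def participant_hep(rec: SimRecording, residualize: bool = True) -> hep.HEPSet:
    """Preprocess the EEG, epoch around detected R peaks, residualize."""
    eeg_rec = hep.EEGRecording(data=rec.eeg, fs=rec.fs_eeg,
                               ch_names=rec.ch_names, ch_pos=rec.ch_pos)
    clean = hep.preprocess_eeg(eeg_rec)
    peaks = participant_rpeaks(rec)
    epochs = recording_epochs(rec)
    pid = rec.events["participant"].iloc[0]
    hs = hep.epoch_hep(clean, peaks.times, epochs, condition=rec.condition,
                       participant=pid)
    if residualize and len(hs.meta) >= 2:
        hs = hep.baseline_regress(hs, condition_col="state")
    return hs


def analyze_hep(study, min_reports: int = hep.MIN_MW_REPORTS):
    """Per-participant state-mean residualized HEP waveforms.

    Applies the report-count inclusion rule, then returns
    ``(waves, kept_participants)`` where ``waves[(cond, state)]`` is a
    participant x channel x time array (participant order = kept list).
    """
    counts = mw_report_counts(study)
    kept = hep.inclusion_filter(counts, min_reports=min_reports)
    waves = {}
    for recs in study:
        pid = recs["BF"].events["participant"].iloc[0]
        if pid not in kept:
            continue
        for cond in CONDITIONS:
            hs = participant_hep(recs[cond])
            for state in ("focus", "MW", "aware"):
                sub = hs.select(state=state)
                if len(sub.meta) == 0:
                    logger.info("%s/%s: no %s trials", pid, cond, state)
                    continue
                waves.setdefault((cond, state), []).append(sub.average())
    out = {}
    for key, lst in waves.items():
        out[key] = np.stack(lst)
    return out, kept


def hep_state_contrast(waves, cond: str, state_a: str, state_b: str,
                       ch_pos, n_perm: int = 1000, seed: int = 0):
    """Cluster permutation test of two state-mean HEP maps within a condition."""
    a = waves[(cond, state_a)]
    b = waves[(cond, state_b)]
    n = min(a.shape[0], b.shape[0])
    adj = cluster.adjacency_from_positions(ch_pos)
    return cluster.permutation_test(a[:n], b[:n], adj, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# time-frequency
# ---------------------------------------------------------------------------

def analyze_state_power(study, freqs=None):
    """Time-averaged power per state, per participant and condition.

    Returns a long DataFrame (participant, condition, state, channel, freq,
    power) of epoch-mean values averaged over each participant's epochs.
    """
    rows = []
    for recs in study:
        pid = recs["BF"].events["participant"].iloc[0]
        for cond in CONDITIONS:
            rec = recs[cond]
            epochs = recording_epochs(rec)
            df = timefreq.state_power(rec.eeg, rec.fs_eeg, epochs, freqs=freqs)
            if df.empty:
                continue
            g = df.groupby(["state", "channel", "freq"], as_index=False)["power"].mean()
            g["participant"] = pid
            g["condition"] = cond
            rows.append(g)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def state_power_arrays(power_df: pd.DataFrame, cond: str, states,
                       n_channels: int, freqs):
    """Stack participant x channel x freq arrays for the given states,
    keeping only participants present in all of them."""
    sub = power_df[power_df["condition"] == cond]
    pids = None
    for s in states:
        have = set(sub.loc[sub["state"] == s, "participant"].unique())
        pids = have if pids is None else pids & have
    pids = sorted(pids or [])
    out = []
    for s in states:
        arr = np.full((len(pids), n_channels, len(freqs)), np.nan)
        ss = sub[sub["state"] == s]
        for i, p in enumerate(pids):
            pp = ss[ss["participant"] == p]
            arr[i, pp["channel"].to_numpy(int),
                np.searchsorted(freqs, pp["freq"].to_numpy())] = pp["power"].to_numpy()
        out.append(arr)
    return out, pids


def band_courses(study, band="alpha", cond="BF", channel_group="parietal"):
    """Participant x step matrix of pre-report band power for one condition.

    ``channel_group``: "parietal" restricts to the montage's parietal row
    (where the simulator injects band dynamics strongest is irrelevant --
    trends are global -- but a restricted group mirrors picking a
    representative site); None averages all channels.
    """
    courses, grid = [], None
    for recs in study:
        rec = recs[cond]
        rep = rec.events.loc[rec.events["type"] == "mw_report", "onset_s"].to_numpy(float)
        if rep.size == 0:
            continue
        if channel_group == "parietal":
            chans = parietal_channels(rec.ch_names)
            data = rec.eeg[chans] if chans.size else rec.eeg
        else:
            data = rec.eeg
        try:
            grid, course = timefreq.prereport_power_course(
                data, rec.fs_eeg, rep, band=band
            )
        except ValueError as exc:
            logger.info("participant dropped from %s course: %s", band, exc)
            continue
        courses.append(course)
    if not courses:
        raise ValueError("no participant contributed a power course")
    return grid, np.stack(courses)
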