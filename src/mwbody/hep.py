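"""Minimal EEG preprocessing and heartbeat-evoked potentials (HEP).

The HEP is the EEG average time-locked to the ECG R peak (epochs -200 to
600 ms here).  Instead of subtraction-based baseline correction -- whose
assumptions fail in a window contaminated by P/Q cardiac components -- a
regression-based correction is used: at every channel and time point the
across-trial amplitude is modeled as

    amplitude ~ 1 + baseline_mean + condition + baseline_mean:condition

with the mean voltage over -200..-75 ms as the baseline covariate and
sum-coded condition contrasts, and only the variance tied to the baseline
terms is removed.  Condition structure therefore survives into the
residualized waveforms that group statistics operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

TARGET_FS = 250.0
EPOCH_TMIN, EPOCH_TMAX = -0.2, 0.6
BASELINE_WINDOW = (-0.2, -0.075)
MIN_MW_REPORTS = 10


@dataclass
class EEGRecording:
    data: np.ndarray            # channel x sample, µV
    fs: float
    ch_names: list
    ch_pos: np.ndarray
    reference: str = "unknown"

    def __post_init__(self):
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("montage length must equal channel count")


@dataclass
class HEPSet:
    """R-peak-locked epochs (trial x channel x time) with per-trial metadata."""

    data: np.ndarray
    times: np.ndarray           # s relative to the R peak
    meta: pd.DataFrame          # columns: peak_s, state, condition, participant
    ch_names: list
    fs: float
    residualized: bool = False

    def __post_init__(self):
        if self.data.shape[0] != len(self.meta):
            raise ValueError("metadata rows must match trial count")

    def select(self, **labels) -> "HEPSet":
        mask = np.ones(len(self.meta), dtype=bool)
        for col, val in labels.items():
            mask &= self.meta[col].to_numpy() == val
        return HEPSet(self.data[mask], self.times, self.meta.loc[mask].reset_index(drop=True),
                      self.ch_names, self.fs, self.residualized)

    def average(self) -> np.ndarray:
        return self.data.mean(axis=0)


def _regress_out_sinusoid(data: np.ndarray, fs: float, freq: float) -> np.ndarray:
    n = data.shape[1]
    t = np.arange(n) / fs
    X = np.column_stack([np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)])
    beta, *_ = np.linalg.lstsq(X, data.T, rcond=None)
    return data - (X @ beta).T


def preprocess_eeg(
    raw: EEGRecording,
    band=(0.5, 50.0),
    line_freq: float = 50.0,
    target_fs: float = TARGET_FS,
) -> EEGRecording:
    """Downsample to 250 Hz, band-pass 0.5-50 Hz (zero phase), remove the
    power-line sinusoid by regression, and apply an average reference."""
    if raw.fs < target_fs:
        raise ValueError(f"fs={raw.fs} < required {target_fs} Hz")
    data = np.asarray(raw.data, dtype=float)
    fs = raw.fs
    if fs != target_fs:
        up, down = int(target_fs), int(fs)
        data = signal.resample_poly(data, up, down, axis=1)
        fs = target_fs
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)
    data = _regress_out_sinusoid(data, fs, line_freq)
    data = data - data.mean(axis=0, keepdims=True)
    return EEGRecording(data=data, fs=fs, ch_names=list(raw.ch_names),
                        ch_pos=raw.ch_pos, reference="average")


def state_of_time(t: float, epochs) -> str:
    for e in epochs:
        if e.t_start <= t < e.t_end:
            return e.state
    return "none"


def epoch_hep(
    eeg: EEGRecording,
    peak_times,
    epochs=(),
    condition: str = "",
    participant: str = "",
    tmin: float = EPOCH_TMIN,
    tmax: float = EPOCH_TMAX,
) -> HEPSet:
    """One epoch per usable R peak, tagged with the containing state.

    Peaks whose epoch would cross a recording edge are dropped.  Peaks not
    inside any attentional-state window are tagged ``"none"`` (selectable
    later).
    """
    fs = eeg.fs
    n = eeg.data.shape[1]
    i0, i1 = int(round(tmin * fs)), int(round(tmax * fs))
    times = np.arange(i0, i1 + 1) / fs
    rows, trials = [], []
    for pk in np.asarray(peak_times, dtype=float):
        c = int(round(pk * fs))
        if c + i0 < 0 or c + i1 >= n:
            continue
        trials.append(eeg.data[:, c + i0 : c + i1 + 1])
        rows.append(dict(peak_s=pk, state=state_of_time(pk, epochs),
                         condition=condition, participant=participant))
    if not trials:
        logger.warning("no usable R peaks for HEP epoching")
        data = np.empty((0, eeg.data.shape[0], times.size))
    else:
        data = np.stack(trials)
    meta = pd.DataFrame(rows, columns=["peak_s", "state", "condition", "participant"])
    return HEPSet(data=data, times=times, meta=meta, ch_names=list(eeg.ch_names), fs=fs)


def inclusion_filter(mw_counts: dict, min_reports: int = MIN_MW_REPORTS) -> list:
    """Participants with at least ``min_reports`` mind-wandering reports."""
    kept = [p for p, c in mw_counts.items() if c >= min_reports]
    excluded = sorted(set(mw_counts) - set(kept))
    if excluded:
        logger.info("excluded from HEP analyses (<%d reports): %s", min_reports, excluded)
    if not kept:
        raise ValueError("no participants meet the report-count inclusion rule")
    return kept


def baseline_means(hep: HEPSet, window=BASELINE_WINDOW) -> np.ndarray:
    """Trial x channel mean voltage over the baseline window."""
    sel = (hep.times >= window[0]) & (hep.times <= window[1])
    return hep.data[:, :, sel].mean(axis=2)


def _condition_design(labels: np.ndarray) -> np.ndarray:
    """Sum-to-zero contrast columns for a categorical label vector."""
    levels = sorted(pd.unique(labels))
    k = len(levels)
    if k < 2:
        return np.empty((labels.size, 0))
    cols = []
    for lev in levels[:-1]:
        c = np.where(labels == lev, 1.0, 0.0)
        c[labels == levels[-1]] = -1.0
        cols.append(c)
    return np.column_stack(cols)


def baseline_regress(hep: HEPSet, condition_col: str = "state") -> HEPSet:
    """Residualize HEP epochs against the baseline-window mean.

    Per channel (the baseline covariate is channel-specific) a single design
    solves all time points at once; the returned waveforms have the fitted
    contribution of the baseline main effect and its interaction with the
    condition removed, while intercept and condition effects are retained.
    Rank-deficient covariates (e.g. a constant baseline) are dropped with a
    log message.
    """
    n_tr, n_ch, n_t = hep.data.shape
    if n_tr < 2:
        raise ValueError("need at least 2 trials for baseline regression")
    labels = hep.meta[condition_col].to_numpy()
    C = _condition_design(labels)
    b_all = baseline_means(hep)

    out = hep.data.copy()
    for ch in range(n_ch):
        b = b_all[:, ch]
        bc = b - b.mean()
        if np.allclose(bc, 0.0):
            logger.info("constant baseline on channel %s; nothing to remove", hep.ch_names[ch])
            continue
        # retain only the condition variation orthogonal to the baseline
        # covariate, so any condition difference explainable by baseline
        # differences is removed along with the baseline terms and the
        # residual waveforms are exactly uncorrelated with the baseline
        if C.shape[1]:
            Cc = C - C.mean(axis=0, keepdims=True)
            C_perp = Cc - np.outer(bc, bc @ Cc) / (bc @ bc)
        else:
            C_perp = C
        nuis = [bc[:, None]]
        if C_perp.shape[1]:
            nuis.append(bc[:, None] * C_perp)
        Xn = np.column_stack(nuis)
        X = np.column_stack([np.ones(n_tr), C_perp, Xn])
        k_keep = 1 + C_perp.shape[1]
        Y = hep.data[:, ch, :]                      # trials x time
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        out[:, ch, :] = Y - Xn @ beta[k_keep:]
    return HEPSet(data=out, times=hep.times, meta=hep.meta.copy(),
                  ch_names=hep.ch_names, fs=hep.fs, residualized=True)
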