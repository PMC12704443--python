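"""Morlet time-frequency power and its two summaries.

Power is computed on a 2-40 Hz grid with the number of wavelet cycles
growing linearly from 3 at 2 Hz (default slope 0.5 cycles/Hz).  Two views
feed the statistics: (i) time-averaged channel x frequency power per
attentional-state epoch, for the cluster permutation tests; and (ii) a
continuous band-power time course over -9.4..-0.5 s before each
mind-wandering report (edge-trimmed so no retained sample sits within one
wavelet half-length of the analysis window border), which is the input of
the change-point model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from mne.time_frequency import tfr_array_morlet

logger = logging.getLogger(__name__)

FREQ_MIN, FREQ_MAX = 2.0, 40.0
BASE_CYCLES = 3.0
CYCLE_SLOPE = 0.5          # cycles per Hz above 2 Hz
COURSE_WINDOW = (9.4, 0.5)  # s before report: course spans [-9.4, -0.5]
BANDS = {"theta": (2.0, 7.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0),
         "gamma": (30.0, 40.0)}


def default_freqs(fmin: float = FREQ_MIN, fmax: float = FREQ_MAX, step: float = 1.0):
    return np.arange(fmin, fmax + 1e-9, step)


def n_cycles_for(freqs, slope: float = CYCLE_SLOPE) -> np.ndarray:
    return BASE_CYCLES + slope * (np.asarray(freqs, dtype=float) - FREQ_MIN)


def wavelet_half_length_s(freq: float, slope: float = CYCLE_SLOPE) -> float:
    """Half the effective wavelet support (~5 Gaussian SDs of the envelope)."""
    c = BASE_CYCLES + slope * (freq - FREQ_MIN)
    sigma_t = c / (2.0 * np.pi * freq)
    return 5.0 * sigma_t


@dataclass
class TFRPower:
    """Channel x frequency x time spectral power (µV²)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    ch_names: list

    def band_mean(self, band) -> np.ndarray:
        lo, hi = BANDS[band] if isinstance(band, str) else band
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        if not sel.any():
            raise ValueError(f"no grid frequencies inside band {band}")
        return self.power[:, sel, :].mean(axis=1)


def morlet_tfr(
    data: np.ndarray,
    fs: float,
    freqs=None,
    cycle_slope: float = CYCLE_SLOPE,
) -> TFRPower:
    """Complex-Morlet power of a (channel x sample) signal segment.

    Raises if the segment is shorter than the longest wavelet, naming the
    offending frequency.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")
    ncyc = n_cycles_for(freqs, cycle_slope)
    longest = ncyc[0] / freqs[0]
    n_t = data.shape[1]
    for f, c in zip(freqs, ncyc):
        if c / f * fs > n_t:
            raise ValueError(
                f"segment of {n_t / fs:.2f} s shorter than the {f:g} Hz wavelet "
                f"({c / f:.2f} s)"
            )
    power = tfr_array_morlet(
        data[np.newaxis], sfreq=fs, freqs=freqs, n_cycles=ncyc, output="power",
        zero_mean=True,
    )[0]
    times = np.arange(n_t) / fs
    return TFRPower(power=power, freqs=freqs, times=times,
                    ch_names=[f"ch{i}" for i in range(data.shape[0])])


def state_power(
    eeg_data: np.ndarray,
    fs: float,
    epochs,
    freqs=None,
    pad_s: float | None = None,
    cycle_slope: float = CYCLE_SLOPE,
) -> pd.DataFrame:
    """Time-averaged channel x frequency power per attentional-state epoch.

    Each epoch is cut with symmetric padding of one wavelet half-length at
    the lowest frequency, decomposed, and averaged over the unpadded part
    only, yielding one power value per channel and frequency per trial.
    Returns a long frame: epoch_idx, state, condition, participant, channel,
    freq, power.
    """
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if pad_s is None:
        pad_s = wavelet_half_length_s(freqs[0], cycle_slope)
    n = eeg_data.shape[1]
    rows = []
    for i, e in enumerate(epochs):
        i0 = int(round((e.t_start - pad_s) * fs))
        i1 = int(round((e.t_end + pad_s) * fs))
        if i0 < 0 or i1 > n:
            logger.info("epoch %d lacks wavelet padding; skipped", i)
            continue
        tfr = morlet_tfr(eeg_data[:, i0:i1], fs, freqs, cycle_slope)
        t = tfr.times + i0 / fs
        keep = (t >= e.t_start) & (t < e.t_end)
        mean_p = tfr.power[:, :, keep].mean(axis=2)     # channel x freq
        for ch in range(mean_p.shape[0]):
            for fi, f in enumerate(freqs):
                rows.append(dict(epoch_idx=i, state=e.state, condition=e.condition,
                                 participant=e.participant, channel=ch, freq=f,
                                 power=mean_p[ch, fi]))
    return pd.DataFrame(rows)


def state_power_matrix(df: pd.DataFrame, state: str, n_channels: int, freqs) -> np.ndarray:
    """Participant-mean channel x frequency matrix for one state."""
    sub = df[df["state"] == state]
    piv = sub.groupby(["channel", "freq"])["power"].mean()
    out = np.full((n_channels, len(freqs)), np.nan)
    for (ch, f), v in piv.items():
        out[int(ch), int(np.searchsorted(freqs, f))] = v
    return out


def prereport_power_course(
    eeg_data: np.ndarray,
    fs: float,
    report_times,
    band="alpha",
    channel: int | None = None,
    step: float = 0.1,
    window=COURSE_WINDOW,
    freqs=None,
    cycle_slope: float = CYCLE_SLOPE,
) -> tuple[np.ndarray, np.ndarray]:
    """Band-power time course before each report, averaged over reports.

    Returns ``(grid_s_before_report, course)`` where the grid runs from
    window[0] down to window[1] seconds before the report in ``step``
    increments, and ``course`` is the report-averaged band power (single
    channel if ``channel`` is given, else the channel mean).  Reports whose
    padded analysis window does not fit in the recording are dropped.
    """
    if freqs is None:
        lo, hi = BANDS[band] if isinstance(band, str) else band
        freqs = np.arange(np.ceil(lo), np.floor(hi) + 1e-9, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    pad = wavelet_half_length_s(freqs[0], cycle_slope)
    w0, w1 = window
    grid = np.round(np.arange(w0, w1 - 1e-9, -step), 10)
    n = eeg_data.shape[1]
    data = eeg_data if channel is None else eeg_data[channel : channel + 1]

    courses = []
    for r in np.asarray(report_times, dtype=float):
        i0 = int(round((r - w0 - pad) * fs))
        i1 = int(round((r - w1 + pad) * fs))
        if i0 < 0 or i1 > n:
            logger.info("report at %.1f s not fully covered; dropped", r)
            continue
        tfr = morlet_tfr(data[:, i0:i1], fs, freqs, cycle_slope)
        bp = tfr.power.mean(axis=(0, 1))            # mean over channels+band
        t_abs = i0 / fs + tfr.times
        idx = np.round((r - grid - i0 / fs) * fs).astype(int)
        if idx.min() < 0 or idx.max() >= t_abs.size:
            continue
        courses.append(bp[idx])
    if not courses:
        raise ValueError("no report fully covered by the recording")
    return grid, np.mean(courses, axis=0)
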