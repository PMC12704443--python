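"""On-disk containers: one HDF5 file per recording plus TSV/JSON sidecars.

The HDF5 container bundles the synchronized signals (with sampling-rate
attributes), the montage, the event table and the ground-truth record (as a
JSON string attribute), so any pipeline stage can be rerun from a single
file.  Events and epochs are also written as TSV for quick inspection.
EEG supplied as EDF can be read through :func:`read_edf_eeg` (mne backend).
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .synth import SimRecording


def _truth_to_json(truth: dict) -> str:
    out = {}
    for k, v in truth.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, pd.DataFrame):
            out[k] = v.to_dict(orient="list")
        else:
            out[k] = v
    return json.dumps(out)


def save_recording(path, rec: SimRecording) -> None:
    with h5py.File(path, "w") as f:
        sig = f.create_group("signals")
        sig.create_dataset("eeg", data=rec.eeg, compression=None)
        sig.create_dataset("ecg", data=rec.ecg)
        sig.create_dataset("resp_chest", data=rec.resp_chest)
        sig.create_dataset("resp_abdomen", data=rec.resp_abdomen)
        sig["eeg"].attrs["fs"] = rec.fs_eeg
        for name in ("ecg", "resp_chest", "resp_abdomen"):
            sig[name].attrs["fs"] = rec.fs_physio
        f.attrs["condition"] = rec.condition
        f.attrs["ch_names"] = json.dumps(list(rec.ch_names))
        f.create_dataset("ch_pos", data=rec.ch_pos)
        ev = f.create_group("events")
        ev.create_dataset("onset_s", data=rec.events["onset_s"].to_numpy(float))
        for col in ("type", "condition", "participant"):
            ev.create_dataset(col, data=rec.events[col].astype(str).to_numpy(),
                              dtype=h5py.string_dtype())
        f.attrs["truth"] = _truth_to_json(rec.truth)


def load_recording(path) -> SimRecording:
    with h5py.File(path, "r") as f:
        sig = f["signals"]
        events = pd.DataFrame(
            {
                "onset_s": sig.file["events/onset_s"][()],
                "type": [s.decode() for s in sig.file["events/type"][()]],
                "condition": [s.decode() for s in sig.file["events/condition"][()]],
                "participant": [s.decode() for s in sig.file["events/participant"][()]],
            }
        )
        truth = json.loads(f.attrs["truth"])
        for k, v in truth.items():
            if isinstance(v, list):
                truth[k] = np.asarray(v)
        return SimRecording(
            eeg=sig["eeg"][()],
            ecg=sig["ecg"][()],
            resp_chest=sig["resp_chest"][()],
            resp_abdomen=sig["resp_abdomen"][()],
            events=events,
            truth=truth,
            ch_names=json.loads(f.attrs["ch_names"]),
            ch_pos=f["ch_pos"][()],
            fs_eeg=float(sig["eeg"].attrs["fs"]),
            fs_physio=float(sig["ecg"].attrs["fs"]),
            condition=str(f.attrs["condition"]),
        )


def save_hepset(path, hs) -> None:
    """Persist a HEPSet (epochs + metadata) as HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=hs.data)
        f.create_dataset("times", data=hs.times)
        f.attrs["fs"] = hs.fs
        f.attrs["residualized"] = hs.residualized
        f.attrs["ch_names"] = json.dumps(list(hs.ch_names))
        g = f.create_group("meta")
        g.create_dataset("peak_s", data=hs.meta["peak_s"].to_numpy(float))
        for col in ("state", "condition", "participant"):
            g.create_dataset(col, data=hs.meta[col].astype(str).to_numpy(),
                             dtype=h5py.string_dtype())


def load_hepset(path):
    from .hep import HEPSet

    with h5py.File(path, "r") as f:
        meta = pd.DataFrame({
            "peak_s": f["meta/peak_s"][()],
            "state": [s.decode() for s in f["meta/state"][()]],
            "condition": [s.decode() for s in f["meta/condition"][()]],
            "participant": [s.decode() for s in f["meta/participant"][()]],
        })
        return HEPSet(data=f["data"][()], times=f["times"][()], meta=meta,
                      ch_names=json.loads(f.attrs["ch_names"]),
                      fs=float(f.attrs["fs"]),
                      residualized=bool(f.attrs["residualized"]))


def write_montage_tsv(path, ch_names, ch_pos) -> None:
    pd.DataFrame({"channel": ch_names,
                  "x": np.asarray(ch_pos)[:, 0],
                  "y": np.asarray(ch_pos)[:, 1]}).to_csv(path, sep="\t",
                                                         index=False)


def read_edf_eeg(path):
    """Read an EDF recording into (data µV, fs, channel names) via mne."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
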