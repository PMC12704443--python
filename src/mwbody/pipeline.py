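"""File-based pipeline: simulate -> preprocess/label -> analyses -> report.

Each stage reads its upstream artifacts from ``config.outdir`` and writes
its own outputs there together with a provenance sidecar (config hash,
seed, package version), so any stage can be rerun or tested in isolation.
Missing upstream artifacts raise an error naming the stage to run first.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, changepoint, study, synth
from .events import epochs_to_frame, write_events_tsv
from .io import load_recording, save_recording

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "label", "respiration", "cardiac", "hep",
          "tfa", "cluster", "changepoint", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "mwbody_out"
    seed: int = 0
    n_participants: int = 6
    duration: float = 300.0          # s per session
    n_mw_reports: int = 8
    n_channels: int = 16
    min_reports_hep: int = 4         # scaled-down inclusion rule for small runs
    n_perm: int = 500
    mcmc_chains: int = 4
    mcmc_iter: int = 1500
    mcmc_burnin: int = 500
    mcmc_thin: int = 2
    cp_band: str = "alpha"
    cp_condition: str = "BF"
    cp_step: float = 0.5             # s; course decimated so that neighboring
                                     # steps carry ~independent noise
    inhalation_offsets: int = 6

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _provenance(cfg: PipelineConfig, stage: str) -> None:
    meta = dict(stage=stage, config_hash=cfg.hash(), seed=cfg.seed,
                version=__version__)
    (_out(cfg) / f"{stage}.provenance.json").write_text(json.dumps(meta, indent=2))


def _require(cfg: PipelineConfig, relpath: str, producer: str) -> Path:
    p = _out(cfg) / relpath
    if not p.exists():
        raise PipelineError(
            f"missing artifact '{relpath}': run the '{producer}' stage first"
        )
    return p


def _load_study(cfg: PipelineConfig):
    recdir = _require(cfg, "recordings", "simulate")
    out = []
    files = sorted(recdir.glob("p*_BF.h5"))
    if not files:
        raise PipelineError("no recordings found: run the 'simulate' stage first")
    for bf in files:
        sf = bf.with_name(bf.name.replace("_BF", "_SF"))
        if not sf.exists():
            raise PipelineError(f"missing SF pair for {bf.name}")
        out.append({"BF": load_recording(bf), "SF": load_recording(sf)})
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> None:
    recdir = _out(cfg) / "recordings"
    recdir.mkdir(exist_ok=True)
    recs = synth.simulate_study(
        cfg.n_participants, seed=cfg.seed, duration=cfg.duration,
        n_mw_reports=cfg.n_mw_reports, n_channels=cfg.n_channels,
    )
    for i, pair in enumerate(recs):
        pid = pair["BF"].events["participant"].iloc[0]
        for cond in ("BF", "SF"):
            save_recording(recdir / f"{pid}_{cond}.h5", pair[cond])
            write_events_tsv(pair[cond].events,
                             recdir / f"{pid}_{cond}_events.tsv")
    logger.info("simulated %d participants into %s", len(recs), recdir)


def stage_preprocess(cfg: PipelineConfig) -> None:
    """Write cleaned signals (preprocessed EEG, filtered ECG, clean belts)
    as inspectable derived artifacts.

    Analysis stages recompute preprocessing from the raw recordings
    deterministically, so these files are for inspection and external use
    rather than a hand-off.
    """
    import h5py

    from . import cardiac, respiration
    from .hep import EEGRecording, preprocess_eeg

    data = _load_study(cfg)
    drv = _out(cfg) / "derived"
    drv.mkdir(exist_ok=True)
    for pair in data:
        for cond in ("BF", "SF"):
            rec = pair[cond]
            pid = rec.events["participant"].iloc[0]
            clean = preprocess_eeg(EEGRecording(rec.eeg, rec.fs_eeg,
                                                rec.ch_names, rec.ch_pos))
            with h5py.File(drv / f"{pid}_{cond}_clean.h5", "w") as f:
                f.create_dataset("eeg_clean", data=clean.data)
                f["eeg_clean"].attrs["fs"] = clean.fs
                f.create_dataset(
                    "ecg_filtered",
                    data=cardiac.filter_ecg(rec.ecg, rec.fs_physio))
                for name, trace in (("resp_chest", rec.resp_chest),
                                    ("resp_abdomen", rec.resp_abdomen)):
                    f.create_dataset(
                        f"{name}_clean",
                        data=respiration.preprocess_resp(trace, rec.fs_physio))
    from .io import write_montage_tsv

    write_montage_tsv(_out(cfg) / "montage.tsv", data[0]["BF"].ch_names,
                      data[0]["BF"].ch_pos)


def stage_label(cfg: PipelineConfig) -> None:
    data = _load_study(cfg)
    frames = []
    for pair in data:
        for cond in ("BF", "SF"):
            frames.append(epochs_to_frame(study.recording_epochs(pair[cond])))
    pd.concat(frames, ignore_index=True).to_csv(
        _out(cfg) / "epochs.tsv", sep="\t", index=False
    )


def stage_respiration(cfg: PipelineConfig) -> None:
    data = _load_study(cfg)
    cycles, tests = study.analyze_respiration(
        data, offsets=range(cfg.inhalation_offsets), seed=cfg.seed
    )
    cycles.to_csv(_out(cfg) / "resp_cycles.tsv", sep="\t", index=False)
    for cond, df in tests.items():
        df.to_csv(_out(cfg) / f"inhalation_rate_{cond}.tsv", sep="\t", index=False)


def stage_cardiac(cfg: PipelineConfig) -> None:
    data = _load_study(cfg)
    rr_state, rr_second = study.analyze_cardiac(data)
    rr_state.to_csv(_out(cfg) / "rr_by_state.tsv", sep="\t", index=False)
    rr_second.to_csv(_out(cfg) / "rr_by_second.tsv", sep="\t", index=False)


def stage_hep(cfg: PipelineConfig) -> None:
    data = _load_study(cfg)
    waves, kept = study.analyze_hep(data, min_reports=cfg.min_reports_hep)
    import h5py

    with h5py.File(_out(cfg) / "hep_waves.h5", "w") as f:
        f.attrs["participants"] = json.dumps(kept)
        f.attrs["ch_pos"] = data[0]["BF"].ch_pos.tolist()
        for (cond, state), arr in waves.items():
            f.create_dataset(f"{cond}/{state}", data=arr)


def stage_tfa(cfg: PipelineConfig) -> None:
    data = _load_study(cfg)
    power = study.analyze_state_power(data)
    power.to_csv(_out(cfg) / "state_power.tsv", sep="\t", index=False)
    grid, courses = study.band_courses(data, band=cfg.cp_band,
                                       cond=cfg.cp_condition)
    rows = []
    for i, course in enumerate(courses):
        for g, v in zip(grid, course):
            rows.append(dict(participant=i, s_before_report=g, power=v))
    pd.DataFrame(rows).to_csv(_out(cfg) / "band_course.tsv", sep="\t", index=False)


def stage_cluster(cfg: PipelineConfig) -> None:
    import h5py

    p = _require(cfg, "hep_waves.h5", "hep")
    results = {}
    with h5py.File(p, "r") as f:
        ch_pos = np.asarray(f.attrs["ch_pos"])
        waves = {}
        for cond in f:
            for state in f[cond]:
                waves[(cond, state)] = f[f"{cond}/{state}"][()]
    for cond in ("BF", "SF"):
        key_a, key_b = (cond, "aware"), (cond, "MW")
        if key_a not in waves or key_b not in waves:
            continue
        res = study.hep_state_contrast(waves, cond, "aware", "MW", ch_pos,
                                       n_perm=cfg.n_perm, seed=cfg.seed)
        results[f"hep_aware_vs_mw_{cond}"] = [
            dict(stat=c.stat, sign=c.sign, p=c.p, n_points=int(len(c.points)))
            for c in res.clusters
        ]
        from .cluster import membership_frame

        membership_frame(res).to_csv(
            _out(cfg) / f"cluster_mask_hep_{cond}.tsv", sep="\t", index=False)
    (_out(cfg) / "cluster_results.json").write_text(json.dumps(results, indent=2))


def stage_changepoint(cfg: PipelineConfig) -> None:
    p = _require(cfg, "band_course.tsv", "tfa")
    df = pd.read_csv(p, sep="\t")
    piv = df.pivot(index="participant", columns="s_before_report", values="power")
    piv = piv[sorted(piv.columns, reverse=True)]       # step 0 furthest back
    grid = np.asarray(piv.columns, dtype=float)
    fine_dt = float(abs(np.diff(grid).mean()))
    stride = max(1, int(round(cfg.cp_step / fine_dt)))
    data = changepoint.CPData(Y=piv.to_numpy()[:, ::stride],
                              step_dt=fine_dt * stride,
                              t0_offset=float(grid[0]))
    model = changepoint.build_model(data)
    post = changepoint.fit_mcmc(
        model, chains=cfg.mcmc_chains, n_iter=cfg.mcmc_iter,
        burnin=cfg.mcmc_burnin, thin=cfg.mcmc_thin, seed=cfg.seed,
    )
    summ = changepoint.summarize(post, seed=cfg.seed)
    summ["tau_mass"] = np.asarray(summ["tau_mass"]).tolist()
    (_out(cfg) / "changepoint.json").write_text(json.dumps(summ, indent=2))


def stage_report(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    report = {"config_hash": cfg.hash(), "version": __version__}
    for name in ("cluster_results.json", "changepoint.json"):
        p = out / name
        if p.exists():
            report[name.replace(".json", "")] = json.loads(p.read_text())
    for name in ("resp_cycles.tsv", "rr_by_state.tsv"):
        p = out / name
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            report[name.replace(".tsv", "_rows")] = int(len(df))
    (out / "report.json").write_text(json.dumps(report, indent=2))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "label": stage_label,
    "respiration": stage_respiration,
    "cardiac": stage_cardiac,
    "hep": stage_hep,
    "tfa": stage_tfa,
    "cluster": stage_cluster,
    "changepoint": stage_changepoint,
    "report": stage_report,
}


def run_stage(stage: str, cfg: PipelineConfig) -> None:
    """Run one named stage; writes artifacts plus a provenance sidecar."""
    if stage not in _STAGE_FUNCS:
        raise PipelineError(f"unknown stage '{stage}'; choose from {STAGES}")
    logger.info("running stage %s", stage)
    _STAGE_FUNCS[stage](cfg)
    _provenance(cfg, stage)


def run_all(cfg: PipelineConfig) -> None:
    for stage in STAGES:
        run_stage(stage, cfg)
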