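"""Spectral power by attentional state and the continuous pre-report band
power courses that feed the change-point model.

Expected pattern (injected): alpha (and beta) power is lower in the aware
state than during MW, because the generator bends the band envelopes
downward a few seconds before each report.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mwbody.pipeline import PipelineConfig, _load_study
from mwbody.study import analyze_state_power, band_courses, state_power_arrays
from mwbody import cluster
from mwbody.timefreq import default_freqs

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "study"


def main():
    cfg = PipelineConfig.from_yaml(OUT / "config.yaml")
    data = _load_study(cfg)
    freqs = default_freqs()

    power = analyze_state_power(data, freqs=freqs)
    # persist a compact band-level summary (the full channel x frequency
    # table is recomputed on demand)
    bands = pd.cut(power["freq"], bins=[2, 7, 13, 30, 40],
                   labels=["theta", "alpha", "beta", "gamma"],
                   include_lowest=True)
    (power.assign(band=bands)
     .groupby(["participant", "condition", "state", "band"], observed=True)
     ["power"].mean().reset_index()
     .to_csv(OUT / "state_power_bands.tsv", sep="\t", index=False))
    alpha = power[(power.freq >= 8) & (power.freq <= 13)]
    print("mean alpha power by state:")
    print(alpha.groupby(["condition", "state"])["power"].mean().round(1).unstack())

    # cluster test on channel x frequency maps: MW vs aware within BF
    n_ch = data[0]["BF"].eeg.shape[0]
    adj = cluster.adjacency_from_positions(data[0]["BF"].ch_pos)
    (mw, aware), pids = state_power_arrays(power, "BF", ["MW", "aware"],
                                           n_ch, freqs)
    res = cluster.permutation_test(mw, aware, adj, n_perm=cfg.n_perm,
                                   seed=cfg.seed)
    sig = res.significant
    print(f"\nBF MW vs aware channel-frequency test: {len(sig)} significant "
          f"clusters over {len(pids)} participants")
    for c in sorted(sig, key=lambda c: c.p)[:4]:
        fr = freqs[[min(p[1] for p in c.points), max(p[1] for p in c.points)]]
        print(f"  sign={c.sign:+d} sum-t={c.stat:9.1f} p={c.p:.4f} "
              f"freqs {fr[0]:.0f}-{fr[1]:.0f} Hz")

    for band in ("alpha", "beta"):
        grid, courses = band_courses(data, band=band, cond=cfg.cp_condition)
        rows = [dict(participant=i, s_before_report=g, power=v)
                for i, course in enumerate(courses)
                for g, v in zip(grid, course)]
        pd.DataFrame(rows).to_csv(OUT / f"band_course_{band}.tsv", sep="\t",
                                  index=False)
        print(f"{band}: course matrix {courses.shape}, "
              f"mean power {np.mean(courses):.1f} µV²")


if __name__ == "__main__":
    main()
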