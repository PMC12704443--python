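"""Respiration: cycle counts by condition and inhalation rate before
mind-wandering reports versus a resampled baseline.

Expected pattern: breathing is slower in the breathing-focused (BF)
condition, and (because BF presses are locked to exhalation ends while the
report follows the press) the respiratory phase around the report deviates
from the participant's baseline inhalation rate.
"""

from pathlib import Path

from scipy import stats

from mwbody.pipeline import PipelineConfig, _load_study
from mwbody.study import analyze_respiration

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "study"


def main():
    cfg = PipelineConfig.from_yaml(OUT / "config.yaml")
    data = _load_study(cfg)
    cycles, tests = analyze_respiration(data, offsets=range(0, 6), seed=cfg.seed)
    cycles.to_csv(OUT / "resp_cycles.tsv", sep="\t", index=False)

    wide = cycles.pivot(index="participant", columns="condition", values="n_cycles")
    t, p = stats.ttest_rel(wide["BF"], wide["SF"])
    print("respiratory cycles per session:")
    print(wide.agg(["mean", "std"]).round(1))
    print(f"paired t({len(wide) - 1}) = {t:.2f}, p = {p:.4f} (BF slower)")

    for cond, df in tests.items():
        df.to_csv(OUT / f"inhalation_rate_{cond}.tsv", sep="\t", index=False)
        print(f"\n{cond}: inhalation rate by seconds before report")
        print(df[["offset_s", "mean_rate", "mean_baseline", "t", "p", "d"]]
              .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
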