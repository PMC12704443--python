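"""Cardiac chronometry: RR intervals by attentional state and by second
before the mind-wandering report.

Expected pattern (injected): heart rate is faster in the focus state than
during MW and the transition to awareness, and accelerates in the final
second before the report.
"""

from pathlib import Path

from mwbody.pipeline import PipelineConfig, _load_study
from mwbody.study import analyze_cardiac

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "study"


def main():
    cfg = PipelineConfig.from_yaml(OUT / "config.yaml")
    data = _load_study(cfg)
    rr_state, rr_second = analyze_cardiac(data)
    rr_state.to_csv(OUT / "rr_by_state.tsv", sep="\t", index=False)
    rr_second.to_csv(OUT / "rr_by_second.tsv", sep="\t", index=False)

    print("mean RR interval (s) by attentional state:")
    print(rr_state.groupby(["condition", "state"])["mean_rr_s"]
          .mean().round(3).unstack())
    print("\nmean RR interval (s) by second before report:")
    print(rr_second.groupby(["condition", "second_label"])["rr_s"]
          .mean().round(3).unstack())


if __name__ == "__main__":
    main()
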