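#!/usr/bin/env python
"""Shuffle control: destroy trial order, refit the prediction model, and check
that the prediction-deviation slope vanishes and its p-values are uniform."""

import json
from pathlib import Path

from goalplane.pipeline import RunConfig, run_analysis

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    report = run_analysis(
        RunConfig(input_path=str(OUT / "trials.csv"), n_shuffles=100, seed=1)
    )
    s = report.shuffle
    summary = {"n_shuffles": s["n_shuffles"], "mean_slope": s["mean_slope"],
               "mean_p": s["mean_p"]}
    (OUT / "shuffle_control.json").write_text(json.dumps(summary, indent=2))
    print(f"mean shuffled slope {s['mean_slope']:+.4f}, mean p {s['mean_p']:.3f} "
          f"(calibrated null: slope ~ 0, p ~ 0.5)")
    print(f"wrote {OUT/'shuffle_control.json'}")
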