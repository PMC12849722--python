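#!/usr/bin/env python
"""Apply the exclusion cascade per participant and derive the trial-pair
metrics; summarises how many trials each rule removed."""

from pathlib import Path

import pandas as pd

from goalplane.metrics import metrics_frame
from goalplane.pipeline import read_trials
from goalplane.prep import apply_exclusions

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    groups = read_trials(OUT / "trials.csv")
    rows, metric_frames = [], []
    for pid, df in groups.items():
        retained, rep = apply_exclusions(df)
        rows.append(dict(participant_id=pid, **{
            k: getattr(rep, k) for k in (
                "n_input", "n_invalid_flight", "n_outlier", "n_first_of_block",
                "n_post_exclusion_successors", "n_retained")},
            retained_fraction=rep.retained_fraction))
        m = metrics_frame(retained, 950.0)
        m.insert(0, "participant_id", pid)
        metric_frames.append(m)
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "exclusion_summary.csv", index=False)
    pd.concat(metric_frames, ignore_index=True).to_csv(OUT / "trial_metrics.csv", index=False)
    print(f"mean retained fraction: {summary.retained_fraction.mean():.3f}")
    print(f"total excluded as outliers (+successors): "
          f"{summary.n_outlier.sum()} (+{summary.n_post_exclusion_successors.sum()})")
    print(f"wrote {OUT/'exclusion_summary.csv'} and {OUT/'trial_metrics.csv'}")
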