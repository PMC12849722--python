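#!/usr/bin/env python
"""Per-participant fits: prediction-model slopes, signed history slopes, and
mean directional updating, checked against the simulator's ground truth."""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from goalplane.fits import fit_participant
from goalplane.metrics import metrics_frame
from goalplane.pipeline import read_trials
from goalplane.prep import apply_exclusions

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    groups = read_trials(OUT / "trials.csv")
    fits = []
    for pid, df in groups.items():
        retained, rep = apply_exclusions(df)
        f = fit_participant(retained, metrics_frame(retained, 950.0))
        row = dataclasses.asdict(f)
        row["aq"] = df["aq"].iloc[0]
        fits.append(row)
    table = pd.DataFrame(fits)
    table.to_csv(OUT / "participant_fits.csv", index=False)
    truth = pd.read_csv(OUT / "ground_truth.csv")
    merged = table.merge(truth, on="participant_id", suffixes=("", "_true"))
    r_alpha = np.corrcoef(merged.alpha_mean, merged.carry_gain)[0, 1]
    print(f"{int(table.usable.sum())}/{len(table)} participants usable")
    print(f"mean alpha {table.alpha_mean.mean():.3f}; "
          f"corr(alpha, true carry gain) = {r_alpha:.2f}")
    print(f"mean beta_resp {table.beta_resp_signed.mean():.3f} "
          f"(true inertia {truth.inertia.iloc[0]:.2f})")
    print(f"wrote {OUT/'participant_fits.csv'}")
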