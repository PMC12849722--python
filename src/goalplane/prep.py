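"""Exclusion cascade producing the analysis-ready trial set per participant.

Three fixed passes, applied in order to one participant's trials:

1. validity — drop trials whose ball rolled on the floor or left the goal
   (``valid_flight`` false) and the immediately following trial of the same
   block (its history is contaminated);
2. outliers — on the remainder, drop trials whose response error lies more
   than ``sd_mult`` (default 2.5) SDs from the participant's mean response
   error, again together with the immediate within-block successor;
3. first-of-block — drop every trial with ``trial == 1`` (no preceding trial).

A trial removable for several reasons is tallied once, by the earliest pass.
Successor removals from passes 1 and 2 are tallied together. Exclusion gaps
break trial pairing downstream (:func:`pair_retained` only yields originally
consecutive retained trials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExclusionReport", "apply_exclusions", "pair_retained"]


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_invalid_flight: int
    n_outlier: int
    n_first_of_block: int
    n_post_exclusion_successors: int
    n_retained: int
    usable: bool = True

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0

    def __post_init__(self) -> None:
        removed = (
            self.n_invalid_flight
            + self.n_outlier
            + self.n_first_of_block
            + self.n_post_exclusion_successors
        )
        if removed != self.n_input - self.n_retained:
            raise ValueError("exclusion counts do not partition the removals")


def _successors(df: pd.DataFrame, mask: np.ndarray) -> np.ndarray:
    """Mask of immediate within-block successors of the masked trials."""
    block = df["block"].to_numpy()
    trial = df["trial"].to_numpy()
    succ = np.zeros(len(df), dtype=bool)
    # rows are in (block, trial) order within a participant table, but look up
    # by index to stay robust to prior removals
    key = {(b, t): i for i, (b, t) in enumerate(zip(block, trial))}
    for i in np.flatnonzero(mask):
        j = key.get((block[i], trial[i] + 1))
        if j is not None:
            succ[j] = True
    return succ


def apply_exclusions(
    trials: pd.DataFrame, sd_mult: float = 2.5
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Run the cascade on one participant's trials.

    Returns the retained rows (original order) and an :class:`ExclusionReport`.
    With fewer than 3 trials surviving the validity pass the outlier SD is
    undefined and the participant is flagged unusable (empty retained set).
    """
    if trials["participant_id"].nunique() > 1:
        raise ValueError("apply_exclusions operates on a single participant")
    n_input = len(trials)
    if n_input == 0:
        return trials.copy(), ExclusionReport(0, 0, 0, 0, 0, 0, usable=False)
    df = trials.reset_index(drop=True)

    # pass 1: invalid flights + their immediate successors
    invalid = ~df["valid_flight"].to_numpy(dtype=bool)
    succ1 = _successors(df, invalid) & ~invalid
    n_invalid = int(invalid.sum())
    df1 = df.loc[~(invalid | succ1)].reset_index(drop=True)

    if len(df1) < 3:
        report = ExclusionReport(
            n_input, n_invalid, 0, 0, int(succ1.sum()),
            n_input - n_invalid - int(succ1.sum()), usable=False,
        )
        return df1.iloc[0:0], report

    # pass 2: response-error outliers (per-participant mean/SD, pooled blocks)
    err = np.hypot(
        df1["resp_x"].to_numpy() - df1["bx_before"].to_numpy(),
        df1["resp_y"].to_numpy() - df1["by_before"].to_numpy(),
    )
    mu, sd = err.mean(), err.std(ddof=1)
    outlier = np.abs(err - mu) > sd_mult * sd
    succ2 = _successors(df1, outlier) & ~outlier
    df2 = df1.loc[~(outlier | succ2)].reset_index(drop=True)

    # pass 3: literal first trial of every block
    first = df2["trial"].to_numpy() == 1
    retained = df2.loc[~first].reset_index(drop=True)

    report = ExclusionReport(
        n_input=n_input,
        n_invalid_flight=n_invalid,
        n_outlier=int(outlier.sum()),
        n_first_of_block=int(first.sum()),
        n_post_exclusion_successors=int(succ1.sum()) + int(succ2.sum()),
        n_retained=len(retained),
    )
    return retained, report


def pair_retained(trials: pd.DataFrame) -> list[tuple[int, int]]:
    """Positional (prev, curr) pairs of originally consecutive retained trials.

    Pairs require the same block and ``curr.trial == prev.trial + 1``;
    exclusion gaps therefore break pairing.
    """
    block = trials["block"].to_numpy()
    trial = trials["trial"].to_numpy()
    if len(trials) < 2:
        return []
    ok = (block[1:] == block[:-1]) & (trial[1:] == trial[:-1] + 1)
    prev = np.flatnonzero(ok)
    return list(zip(prev.tolist(), (prev + 1).tolist()))
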