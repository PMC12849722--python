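"""Per-trial serial-dependence metrics on the goal plane.

All quantities live in a 2D goal-plane frame: X is lateral (positive to the
kicker's right), Y is vertical (positive up), units are meters. Every
history metric relates the current trial *n* to the immediately preceding
trial *n − 1* of the same block:

* ``response_error`` — Euclidean distance between the localization response
  and the ball's last-seen position.
* ``delta_prev`` — the previous trial's reappearance displacement
  ``B_after(n−1) − B_before(n−1)``.
* ``prior_landing`` — the current last-seen position shifted by
  ``delta_prev``: the landing expected if the last perturbation repeated.
* ``prediction_deviation`` — distance between the response and the
  prior-informed landing.
* ``alpha`` — signed projection of the current response offset onto
  ``delta_prev``; 1 = full carryover, 0 = none, < 0 = repulsion. Undefined
  when the previous displacement is the zero vector.
* ``stimulus_proximity`` / ``response_proximity`` — distances from the
  current response to the previous post-reappearance stimulus / previous
  response (non-negative covariates).
* signed horizontal terms ``dx_prev``, ``errx_prev``, ``errx_curr`` used by
  the signed history regressions.

A trial's ``condition`` labels the *previous* trial's distortion: ``neutral``
(zero force), ``max`` (largest magnitude, either sign), ``mid`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "TrialMetrics",
    "response_error",
    "directional_alpha",
    "history_metrics",
    "condition_label",
    "metrics_frame",
]


@dataclass(frozen=True)
class TrialRecord:
    """One kick: goal-plane positions before/after reappearance and response."""

    participant_id: str
    block: int
    trial: int
    force_cN: float
    b_before: tuple[float, float]
    b_after: tuple[float, float]
    response: tuple[float, float]
    valid_flight: bool = True

    def __post_init__(self) -> None:
        for name in ("b_before", "b_after", "response"):
            v = getattr(self, name)
            if len(v) != 2 or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 2-vector, got {v!r}")
        if self.block < 1 or self.trial < 1:
            raise ValueError("block and trial indices are 1-based positive integers")


@dataclass(frozen=True)
class TrialMetrics:
    """Derived quantities for a consecutive (prev, curr) trial pair."""

    response_error: float
    delta_prev: tuple[float, float]
    prior_landing: tuple[float, float]
    prediction_deviation: float
    alpha: Optional[float]
    stimulus_proximity: float
    response_proximity: float
    dx_prev: float
    errx_prev: float
    errx_curr: float
    condition: str
    has_history: bool = True


def _dist(a, b) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def response_error(trial: TrialRecord) -> float:
    """Euclidean goal-plane distance between the response and the last-seen position."""
    return _dist(trial.response, trial.b_before)


def condition_label(force: float, max_force: float) -> str:
    """Label a distortion force: neutral (0), max (|force| = max_force), else mid."""
    if force == 0:
        return "neutral"
    if abs(force) == abs(max_force):
        return "max"
    return "mid"


def _check_consecutive(curr: TrialRecord, prev: TrialRecord) -> None:
    if curr.participant_id != prev.participant_id:
        raise ValueError("trials belong to different participants")
    if curr.block != prev.block:
        raise ValueError("trials belong to different blocks")
    if curr.trial != prev.trial + 1:
        raise ValueError(
            f"trials are not consecutive (prev trial {prev.trial}, curr {curr.trial})"
        )


def directional_alpha(curr: TrialRecord, prev: TrialRecord) -> Optional[float]:
    """Signed projection of the current response offset onto the previous displacement.

    alpha = ((L_n − B_before(n)) · ΔDistortion_{n−1}) / |ΔDistortion_{n−1}|²,
    defined only when the previous displacement is nonzero; returns ``None``
    otherwise (such pairs are excluded from averages, never counted as 0).
    """
    _check_consecutive(curr, prev)
    dx = prev.b_after[0] - prev.b_before[0]
    dy = prev.b_after[1] - prev.b_before[1]
    denom = dx * dx + dy * dy
    if denom == 0.0:
        return None
    off_x = curr.response[0] - curr.b_before[0]
    off_y = curr.response[1] - curr.b_before[1]
    return float((off_x * dx + off_y * dy) / denom)


def history_metrics(
    curr: TrialRecord, prev: TrialRecord, max_force: float
) -> TrialMetrics:
    """All pairwise metrics for consecutive retained trials of one block.

    Pure in the two records: reads nothing but its arguments. ``max_force``
    is the largest configured distortion magnitude, needed only for the
    condition label of the previous trial.
    """
    _check_consecutive(curr, prev)
    delta = (prev.b_after[0] - prev.b_before[0], prev.b_after[1] - prev.b_before[1])
    prior = (curr.b_before[0] + delta[0], curr.b_before[1] + delta[1])
    return TrialMetrics(
        response_error=response_error(curr),
        delta_prev=delta,
        prior_landing=prior,
        prediction_deviation=_dist(curr.response, prior),
        alpha=directional_alpha(curr, prev),
        stimulus_proximity=_dist(curr.response, prev.b_after),
        response_proximity=_dist(curr.response, prev.response),
        dx_prev=delta[0],
        errx_prev=prev.response[0] - prev.b_before[0],
        errx_curr=curr.response[0] - curr.b_before[0],
        condition=condition_label(prev.force_cN, max_force),
    )


# ---------------------------------------------------------------------------
# vectorized metrics over a retained trial table

_POS_COLS = ["bx_before", "by_before", "bx_after", "by_after", "resp_x", "resp_y"]


def metrics_frame(
    trials: pd.DataFrame,
    max_force: float,
    pairs: Optional[Sequence[tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Metric table for consecutive retained trial pairs of one participant.

    ``trials`` uses the pipeline trial-table schema (one participant). By
    default pairs are rows that were originally consecutive within a block
    (``trial`` differs by 1); exclusion gaps break pairing. Explicit
    positional ``pairs`` override this (used by the shuffle control, which
    treats a permuted sequence as consecutive).

    Agrees with :func:`history_metrics` pair by pair; ``alpha`` is NaN where
    undefined (zero previous displacement).
    """
    t = trials.reset_index(drop=True)
    if pairs is None:
        same_block = t["block"].to_numpy()[1:] == t["block"].to_numpy()[:-1]
        consec = t["trial"].to_numpy()[1:] == t["trial"].to_numpy()[:-1] + 1
        keep = same_block & consec
        prev_idx = np.flatnonzero(keep)
        curr_idx = prev_idx + 1
    else:
        arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
        prev_idx, curr_idx = arr[:, 0], arr[:, 1]

    p = t.iloc[prev_idx]
    c = t.iloc[curr_idx]
    dx = p["bx_after"].to_numpy() - p["bx_before"].to_numpy()
    dy = p["by_after"].to_numpy() - p["by_before"].to_numpy()
    prior_x = c["bx_before"].to_numpy() + dx
    prior_y = c["by_before"].to_numpy() + dy
    resp_x = c["resp_x"].to_numpy()
    resp_y = c["resp_y"].to_numpy()
    off_x = resp_x - c["bx_before"].to_numpy()
    off_y = resp_y - c["by_before"].to_numpy()
    denom = dx * dx + dy * dy
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(denom > 0, (off_x * dx + off_y * dy) / np.where(denom > 0, denom, 1.0), np.nan)

    prev_force = p["force_cN"].to_numpy()
    condition = np.where(
        prev_force == 0,
        "neutral",
        np.where(np.abs(prev_force) == abs(max_force), "max", "mid"),
    )
    return pd.DataFrame(
        {
            "response_error": np.hypot(off_x, off_y),
            "dx_prev": dx,
            "dy_prev": dy,
            "prediction_deviation": np.hypot(resp_x - prior_x, resp_y - prior_y),
            "alpha": alpha,
            "stimulus_proximity": np.hypot(
                resp_x - p["bx_after"].to_numpy(), resp_y - p["by_after"].to_numpy()
            ),
            "response_proximity": np.hypot(
                resp_x - p["resp_x"].to_numpy(), resp_y - p["resp_y"].to_numpy()
            ),
            "errx_prev": p["resp_x"].to_numpy() - p["bx_before"].to_numpy(),
            "errx_curr": off_x,
            "condition": condition,
            "abs_displacement": np.hypot(dx, dy),
        }
    )
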