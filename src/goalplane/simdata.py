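"""Synthetic cohorts for the goal-plane prediction task.

The simulator emulates the statistical structure the trial-history analysis
assumes, with known per-participant ground truth so estimator recovery can be
tested. Each participant kicks ``n_blocks × trials_per_block`` balls at a
``goal_width × goal_height`` goal plane. On every trial a lateral distortion
force (cN) drawn from ``force_levels`` — never repeated more than twice
consecutively — shifts the reappearance position by ``k = force_to_meters``
meters per cN (purely lateral; vertical distortion is zero).

Response generation, per block (trial 1 of a block carries no history):

    Err_x[n] = a_eff[n] * Δx[n−1] + r_i * Err_x[n−1] + ε_x
    Err_y[n] =                      r_i * Err_y[n−1] + ε_y
    a_eff[n] = a_i * (1 − f_i * 1[|F[n−1]| = max level])
    response[n] = B_before[n] + Err[n],   ε ~ Normal(0, noise_sd_i²)

so ``a_i`` (carry gain) is the ground truth for the directional updating
index α, ``f_i`` (flexibility) is the fractional down-weighting of carryover
after a maximal distortion, and ``r_i`` (inertia) is the ground truth for the
signed response-history slope β_Resp. Trait linkage is linear in z-scored
AQ with clipping: ``a_i = clip(a0 + gamma_carry·z, 0, 1.5)``,
``f_i = clip(f0 − gamma_flex·z, 0, 1)``; gradients of zero give a null
cohort. Invalid flights are independent Bernoulli flags, not physics.

Reproducibility: participant ``i`` uses ``SeedSequence([master_seed, i])``
(profile draws use ``SeedSequence([master_seed, 2**20])``), so cohorts are
byte-identical under a fixed ``master_seed`` and participants independent.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

__all__ = [
    "SimCohortConfig",
    "ParticipantProfile",
    "distortion_sequence",
    "build_cohort_profiles",
    "simulate_trials",
    "simulate_cohort",
]

_PROFILE_STREAM = 2**20  # seed-sequence counter reserved for profile draws


@dataclass(frozen=True)
class SimCohortConfig:
    """Cohort-level generative parameters (defaults emulate the task)."""

    n_participants: int = 42
    n_blocks: int = 5
    trials_per_block: int = 25
    force_levels: tuple[float, ...] = (-950.0, -475.0, 0.0, 475.0, 950.0)
    force_to_meters: float = 0.004  # max force -> 3.8 m lateral shift
    goal_width: float = 20.0
    goal_height: float = 5.7
    aq_mean: float = 17.0
    aq_sd: float = 6.0
    gamma_carry: float = -0.1  # carry-gain change per SD of AQ
    gamma_flex: float = 0.15  # flexibility change per SD of AQ
    base_carry: float = 0.6
    base_flex: float = 0.3
    base_inertia: float = 0.2
    noise_sd: float = 0.3
    kick_sd_x: float = 2.5
    kick_sd_y: float = 1.0
    p_invalid: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.force_levels)
        object.__setattr__(self, "force_levels", levels)
        if len(set(levels)) < 2:
            raise ValueError("need at least two distinct force levels")
        if 0.0 not in levels or sorted(levels) != sorted(-v for v in levels):
            raise ValueError("force_levels must be symmetric about 0 and include 0")
        if self.trials_per_block < 3:
            raise ValueError("trials_per_block must be >= 3")
        if not (0 <= self.p_invalid < 0.2):
            raise ValueError("p_invalid must be in [0, 0.2)")
        if self.force_to_meters <= 0:
            raise ValueError("force_to_meters must be positive")
        if self.goal_width <= 0 or self.goal_height <= 0:
            raise ValueError("goal dimensions must be positive")
        if self.aq_sd <= 0:
            raise ValueError("aq_sd must be positive")
        if not 0 <= self.base_flex <= 1:
            raise ValueError("base_flex must lie in [0, 1]")
        if abs(self.base_inertia) >= 1:
            raise ValueError("base_inertia must satisfy |r| < 1")

    @property
    def max_force(self) -> float:
        return max(abs(v) for v in self.force_levels)

    @classmethod
    def from_yaml(cls, path) -> "SimCohortConfig":
        """Load a config from a YAML mapping; missing keys take defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "force_levels" in raw:
            raw["force_levels"] = tuple(raw["force_levels"])
        return cls(**raw)


@dataclass(frozen=True)
class ParticipantProfile:
    """Ground-truth generative parameters of one simulated participant."""

    participant_id: str
    aq: int
    carry_gain: float  # a_i, ground truth for alpha
    flex: float  # f_i in [0, 1]
    inertia: float  # r_i, |r| < 1, ground truth for beta_resp
    noise_sd: float
    seed: tuple[int, int]
    expert: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.aq <= 50:
            raise ValueError("aq must lie in [0, 50]")
        if not 0 <= self.carry_gain <= 1.5:
            raise ValueError("carry_gain must lie in [0, 1.5]")
        if not 0 <= self.flex <= 1:
            raise ValueError("flex must lie in [0, 1]")
        if abs(self.inertia) >= 1:
            raise ValueError("inertia must satisfy |r| < 1")


def distortion_sequence(n: int, levels, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` forces from ``levels``, never repeating a level 3× in a row.

    Each draw is uniform over the admissible levels (all of them, unless the
    last two draws were equal, in which case that level is excluded), so
    marginal frequencies approach uniform for long sequences.
    """
    levels = np.asarray(sorted(set(np.asarray(levels, dtype=float).tolist())))
    if n < 1:
        raise ValueError("n must be >= 1")
    if levels.size < 2:
        raise ValueError("need at least two distinct levels")
    out = np.empty(n)
    for i in range(n):
        if i >= 2 and out[i - 1] == out[i - 2]:
            admissible = levels[levels != out[i - 1]]
        else:
            admissible = levels
        out[i] = admissible[rng.integers(admissible.size)]
    return out


def build_cohort_profiles(config: SimCohortConfig) -> list[ParticipantProfile]:
    """Draw trait-linked profiles; deterministic given ``master_seed``."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.master_seed, _PROFILE_STREAM])
    )
    aq_raw = rng.normal(config.aq_mean, config.aq_sd, size=config.n_participants)
    aq = np.clip(np.round(aq_raw), 0, 50).astype(int)
    z = (aq - config.aq_mean) / config.aq_sd
    a = np.clip(config.base_carry + config.gamma_carry * z, 0.0, 1.5)
    f = np.clip(config.base_flex - config.gamma_flex * z, 0.0, 1.0)
    width = len(str(config.n_participants))
    return [
        ParticipantProfile(
            participant_id=f"S{i + 1:0{width}d}",
            aq=int(aq[i]),
            carry_gain=float(a[i]),
            flex=float(f[i]),
            inertia=config.base_inertia,
            noise_sd=config.noise_sd,
            seed=(config.master_seed, i),
        )
        for i in range(config.n_participants)
    ]


def simulate_trials(
    profile: ParticipantProfile, config: SimCohortConfig
) -> pd.DataFrame:
    """Simulate one participant's trial table (pipeline schema, 1-based indices)."""
    rng = np.random.default_rng(np.random.SeedSequence(list(profile.seed)))
    k = config.force_to_meters
    nb, nt = config.n_blocks, config.trials_per_block
    half_w = config.goal_width / 2.0
    y_mu = config.goal_height / 2.0 - 1.35

    frames = []
    for b in range(1, nb + 1):
        forces = distortion_sequence(nt, config.force_levels, rng)
        bx = np.clip(rng.normal(0.0, config.kick_sd_x, nt), -half_w, half_w)
        by = np.clip(rng.normal(y_mu, config.kick_sd_y, nt), 0.0, config.goal_height)
        dx = k * forces  # reappearance shift, purely lateral
        eps_x = rng.normal(0.0, profile.noise_sd, nt)
        eps_y = rng.normal(0.0, profile.noise_sd, nt)
        a_eff = np.empty(nt)
        a_eff[0] = 0.0  # first trial of a block has no history term
        a_eff[1:] = profile.carry_gain * (
            1.0 - profile.flex * (np.abs(forces[:-1]) == config.max_force)
        )
        drive = eps_x.copy()
        drive[1:] += a_eff[1:] * dx[:-1]
        err_x = lfilter([1.0], [1.0, -profile.inertia], drive)
        err_y = lfilter([1.0], [1.0, -profile.inertia], eps_y)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": profile.participant_id,
                    "block": b,
                    "trial": np.arange(1, nt + 1),
                    "force_cN": forces,
                    "bx_before": bx,
                    "by_before": by,
                    "bx_after": bx + dx,
                    "by_after": by,
                    "resp_x": bx + err_x,
                    "resp_y": by + err_y,
                    "valid_flight": rng.random(nt) >= config.p_invalid,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["aq"] = profile.aq
    df["expert"] = profile.expert
    return df


def simulate_cohort(
    config: SimCohortConfig,
    profiles: Optional[list[ParticipantProfile]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns ``(trials, truth)``: the concatenated trial table and a
    ground-truth side table (one row per participant) for recovery tests.
    """
    if profiles is None:
        profiles = build_cohort_profiles(config)
    trials = pd.concat(
        [simulate_trials(p, config) for p in profiles], ignore_index=True
    )
    truth = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in profiles],
            "aq": [p.aq for p in profiles],
            "carry_gain": [p.carry_gain for p in profiles],
            "flex": [p.flex for p in profiles],
            "inertia": [p.inertia for p in profiles],
            "noise_sd": [p.noise_sd for p in profiles],
            "expert": [p.expert for p in profiles],
        }
    )
    return trials, truth
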