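"""Trial-table I/O and end-to-end orchestration.

Trial tables are UTF-8 CSV with header::

    participant_id,block,trial,force_cN,bx_before,by_before,bx_after,
    by_after,resp_x,resp_y,valid_flight,aq,expert

positions in meters in the goal-plane frame (X lateral, Y vertical), 1-based
block/trial indices, ``valid_flight`` boolean, ``aq`` the participant's trait
score and ``expert`` an optional expertise flag.

:func:`run_analysis` executes metrics → exclusions → per-participant fits →
group inference and returns a :class:`RunReport` that serializes to a single
JSON document (plus the per-participant fit table as CSV). Reports are
bit-identical across runs with the same config and inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .fits import (
    MIN_PAIRS,
    ParticipantFit,
    fit_participant,
    shuffle_control,
)
from .group_inference import (
    correlate,
    holm_adjust,
    jarque_bera,
    omnibus_group_tests,
    ancova_adjusted_comparison,
    partial_correlation,
    quartile_groups,
    ttest_with_bf,
)
from .metrics import metrics_frame
from .prep import apply_exclusions
from .simdata import SimCohortConfig, simulate_cohort

__all__ = [
    "TRIAL_COLUMNS",
    "DEFAULT_FORCE_LEVELS",
    "read_trials",
    "write_trials",
    "RunConfig",
    "RunReport",
    "run_analysis",
]

DEFAULT_FORCE_LEVELS = (-950.0, -475.0, 0.0, 475.0, 950.0)

TRIAL_COLUMNS = [
    "participant_id",
    "block",
    "trial",
    "force_cN",
    "bx_before",
    "by_before",
    "bx_after",
    "by_after",
    "resp_x",
    "resp_y",
    "valid_flight",
    "aq",
    "expert",
]

_NUMERIC = ["force_cN", "bx_before", "by_before", "bx_after", "by_after", "resp_x", "resp_y"]


class SchemaError(ValueError):
    """Trial table violates the documented schema."""


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path, force_levels=DEFAULT_FORCE_LEVELS) -> dict[str, pd.DataFrame]:
    """Read and validate a trial table, grouped by participant.

    Checks: header completeness, finite numeric fields, known force levels
    (pass ``force_levels=None`` to skip), and per-(participant, block) trial
    indices that are consecutive from 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 2  # header + 1-based
            raise SchemaError(f"non-numeric value in column {col!r} near line {row}")
        df[col] = vals.astype(float)
    df["valid_flight"] = df["valid_flight"].astype(bool)
    df["expert"] = df["expert"].astype(bool)
    if force_levels is not None:
        allowed = set(float(v) for v in force_levels)
        bad = ~df["force_cN"].isin(allowed)
        if bad.any():
            raise ValueError(
                f"unknown force level {df.loc[bad.idxmax(), 'force_cN']!r} "
                f"at line {int(bad.idxmax()) + 2}"
            )
    groups: dict[str, pd.DataFrame] = {}
    for pid, sub in df.groupby("participant_id", sort=False):
        for (b,), blk in sub.groupby(["block"]):
            t = blk["trial"].to_numpy()
            expect = np.arange(1, len(t) + 1)
            if not np.array_equal(t, expect):
                first_bad = int(np.flatnonzero(t != expect[: len(t)])[0]) if len(t) else 0
                raise SchemaError(
                    f"participant {pid} block {b}: trial indices not consecutive "
                    f"from 1 (row {int(blk.index[first_bad]) + 2})"
                )
        groups[str(pid)] = sub.reset_index(drop=True)
    return groups


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; defaults mirror the analysis conventions."""

    input_path: Optional[str] = None
    sim: Optional[SimCohortConfig] = None
    outlier_sd: float = 2.5
    min_pairs: int = MIN_PAIRS
    n_shuffles: int = 0
    bf_method: str = "jzs"
    seed: int = 0
    force_levels: tuple[float, ...] = DEFAULT_FORCE_LEVELS

    def __post_init__(self) -> None:
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")
        if self.n_shuffles < 0:
            raise ValueError("n_shuffles must be >= 0")
        if self.input_path is None and self.sim is None:
            raise ValueError("either input_path or a simulation config is required")


@dataclass
class RunReport:
    config: dict
    version: str
    exclusions: dict[str, dict]
    fit_table: pd.DataFrame
    group_results: dict
    shuffle: Optional[dict] = None

    def to_json(self, **kwargs) -> str:
        payload = {
            "version": self.version,
            "config": self.config,
            "exclusions": self.exclusions,
            "participant_fits": self.fit_table.to_dict(orient="records"),
            "group_results": self.group_results,
            "shuffle_control": self.shuffle,
        }
        return json.dumps(payload, default=_json_default, indent=2, **kwargs)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.fit_table.to_csv(out / "participant_fits.csv", index=False)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _corr(res) -> dict:
    return dataclasses.asdict(res)


def run_analysis(config: RunConfig) -> RunReport:
    """Full pipeline: load or simulate trials, fit participants, run group stats."""
    if config.input_path is not None:
        groups = read_trials(config.input_path, config.force_levels)
        force_levels = config.force_levels
    else:
        trials, _ = simulate_cohort(config.sim)
        force_levels = config.sim.force_levels
        groups = {
            str(pid): sub.reset_index(drop=True)
            for pid, sub in trials.groupby("participant_id", sort=False)
        }
    max_force = max(abs(v) for v in force_levels)

    exclusions: dict[str, dict] = {}
    fits: list[ParticipantFit] = []
    meta: dict[str, dict] = {}
    retained_frames: dict[str, pd.DataFrame] = {}
    for pid, df in groups.items():
        retained, report = apply_exclusions(df, config.outlier_sd)
        exclusions[pid] = dataclasses.asdict(report) | {
            "retained_fraction": report.retained_fraction
        }
        if not report.usable:
            fits.append(ParticipantFit(pid, usable=False, n_pairs=0))
            continue
        m = metrics_frame(retained, max_force)
        fits.append(fit_participant(retained, m, config.min_pairs))
        retained_frames[pid] = retained
        meta[pid] = {
            "aq": float(df["aq"].iloc[0]),
            "expert": bool(df["expert"].iloc[0]),
        }

    fit_table = pd.DataFrame([dataclasses.asdict(f) for f in fits])
    fit_table["aq"] = [meta.get(f.participant_id, {}).get("aq", np.nan) for f in fits]
    fit_table["expert"] = [
        meta.get(f.participant_id, {}).get("expert", False) for f in fits
    ]
    usable = fit_table[fit_table["usable"]].reset_index(drop=True)
    if len(usable) == 0:
        raise RuntimeError(
            "no usable participants after exclusions: "
            + json.dumps(exclusions, default=_json_default)
        )

    group_results: dict = {}
    nonexp = usable[~usable["expert"]].reset_index(drop=True)
    base = nonexp if len(nonexp) >= 8 else usable

    # --- AQ correlations (non-expert sample)
    aq = base["aq"].to_numpy()
    if np.ptp(aq) > 0 and len(base) >= 4:
        group_results["aq_distribution"] = dataclasses.asdict(jarque_bera(aq))
        corrs = {}
        for key, col in [
            ("prediction_deviation", "mean_prediction_deviation"),
            ("beta_pred", "beta_pred"),
            ("alpha", "alpha_mean"),
            ("beta_stim_signed", "beta_stim_signed"),
            ("beta_resp_signed", "beta_resp_signed"),
            ("precision", "precision"),
        ]:
            y = base[col].to_numpy()
            ok = np.isfinite(y)
            if ok.sum() >= 4 and np.ptp(y[ok]) > 0:
                corrs[key] = _corr(correlate(aq[ok], y[ok], bf_method=config.bf_method))
        group_results["aq_correlations"] = corrs

        # partial correlations for alpha, controlling nuisance summaries
        ok = np.isfinite(base["alpha_mean"].to_numpy())
        if ok.sum() >= 8:
            sub = base[ok]
            partials = {}
            for name, cov in [
                ("displacement", "mean_abs_displacement"),
                ("precision", "precision"),
                ("accuracy", "accuracy"),
            ]:
                r, p = partial_correlation(
                    sub["aq"].to_numpy(), sub["alpha_mean"].to_numpy(),
                    [sub[cov].to_numpy()],
                )
                partials[name] = {"r": r, "p": p}
            group_results["aq_alpha_partial"] = partials

        # --- extreme-group contrasts (Q1 vs Q4 on AQ)
        ga = quartile_groups(aq, ids=base["participant_id"].to_numpy())
        lo = base[base["participant_id"].isin(ga.low_ids)]
        hi = base[base["participant_id"].isin(ga.high_ids)]
        group_results["aq_groups"] = {
            "scheme": ga.scheme,
            "thresholds": list(ga.thresholds),
            "n_low": len(lo),
            "n_high": len(hi),
        }
        if len(lo) >= 2 and len(hi) >= 2 and not ga.degenerate:
            contrasts = {}
            for key in ("beta_pred", "alpha_mean", "beta_stim_signed", "beta_resp_signed"):
                a, b = lo[key].dropna().to_numpy(), hi[key].dropna().to_numpy()
                if len(a) >= 2 and len(b) >= 2:
                    contrasts[key] = dataclasses.asdict(
                        ttest_with_bf(a, b, mode="independent", name=f"Q1 vs Q4 {key}")
                    )
            names = list(contrasts)
            adj = holm_adjust([contrasts[k]["p"] for k in names])
            for k, pa in zip(names, adj):
                contrasts[k]["p_holm"] = float(pa)
            group_results["quartile_contrasts"] = contrasts

            # one-sample attraction/repulsion tests per group
            onesample = {}
            for gname, gdf in (("low", lo), ("high", hi)):
                for key in ("beta_stim_signed", "beta_resp_signed"):
                    v = gdf[key].dropna().to_numpy()
                    if len(v) >= 2 and np.ptp(v) > 0:
                        onesample[f"{gname}_{key}"] = dataclasses.asdict(
                            ttest_with_bf(v, mode="one_sample", name=f"{gname} {key} vs 0")
                        )
            group_results["one_sample_history"] = onesample

        # --- distortion-split 2x2 (median split for group sizes, mixed design)
        md = quartile_groups(aq, ids=base["participant_id"].to_numpy(), scheme="median")
        glabel = np.where(base["participant_id"].isin(md.low_ids), "low", "high")
        anovas = {}
        candidates = [
            ("beta_pred", ("beta_pred_neutral", "beta_pred_max")),
            ("beta_pred", ("beta_pred_mid", "beta_pred_max")),
            ("alpha", ("alpha_mid", "alpha_max")),
        ]
        for key, (c_lo, c_hi) in candidates:
            if key in anovas:
                continue  # first usable cell pairing wins (neutral, else mid)
            both = np.isfinite(base[c_lo].to_numpy()) & np.isfinite(base[c_hi].to_numpy())
            if both.sum() >= 8:
                sub = base[both]
                gl = glabel[both]
                vals = np.concatenate([sub[c_lo].to_numpy(), sub[c_hi].to_numpy()])
                conds = np.array(["low_distortion"] * both.sum() + ["max"] * both.sum())
                subj = np.concatenate([sub["participant_id"]] * 2)
                try:
                    res = omnibus_group_tests(
                        vals, np.concatenate([gl, gl]), conds, subject_ids=subj
                    )
                    anovas[key] = {k: dataclasses.asdict(v) for k, v in res.items()}
                except ValueError:
                    pass
        group_results["distortion_anovas"] = anovas

    # --- expert subgroup, when present
    experts = usable[usable["expert"]].reset_index(drop=True)
    if len(experts) >= 2 and len(nonexp) >= 8:
        exp_res: dict = {}
        for key in ("beta_pred", "beta_resp_signed", "beta_stim_signed"):
            v = experts[key].dropna().to_numpy()
            if len(v) >= 2 and np.ptp(v) > 0:
                exp_res[f"{key}_vs_0"] = dataclasses.asdict(
                    ttest_with_bf(v, mode="one_sample", name=f"experts {key} vs 0")
                )
        ga = quartile_groups(nonexp["aq"].to_numpy(), ids=nonexp["participant_id"].to_numpy())
        lo = nonexp[nonexp["participant_id"].isin(ga.low_ids)]
        hi = nonexp[nonexp["participant_id"].isin(ga.high_ids)]
        labels = np.array(["low"] * len(lo) + ["high"] * len(hi) + ["expert"] * len(experts))
        stacked = pd.concat([lo, hi, experts], ignore_index=True)
        for key in ("accuracy", "precision"):
            vals = stacked[key].to_numpy()
            try:
                res = omnibus_group_tests(vals, labels)
                exp_res[key] = {k: dataclasses.asdict(v) for k, v in res.items()}
            except ValueError:
                pass
        ok = np.isfinite(stacked["alpha_mean"].to_numpy())
        if ok.sum() > len(set(labels)) + 5:
            try:
                res = ancova_adjusted_comparison(
                    stacked["alpha_mean"].to_numpy()[ok],
                    labels[ok],
                    [
                        stacked["accuracy"].to_numpy()[ok],
                        stacked["precision"].to_numpy()[ok],
                        stacked["mean_abs_displacement"].to_numpy()[ok],
                    ],
                )
                exp_res["alpha_ancova"] = {k: dataclasses.asdict(v) for k, v in res.items()}
            except ValueError:
                pass
        group_results["experts"] = exp_res

    # --- shuffle control
    shuffle_summary = None
    if config.n_shuffles > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 777]))
        per = {}
        slopes, pvals = [], []
        for pid, retained in retained_frames.items():
            try:
                s = shuffle_control(
                    retained, max_force, config.n_shuffles, rng, config.min_pairs
                )
            except ValueError:
                continue
            per[pid] = {"mean_slope": s.mean_slope, "mean_p": s.mean_p}
            slopes.append(s.slopes)
            pvals.append(s.pvalues)
        if per:
            shuffle_summary = {
                "n_shuffles": config.n_shuffles,
                "mean_slope": float(np.concatenate(slopes).mean()),
                "mean_p": float(np.concatenate(pvals).mean()),
                "participants": per,
            }

    cfg_echo = dataclasses.asdict(config)
    if config.sim is not None:
        cfg_echo["sim"] = dataclasses.asdict(config.sim)
    return RunReport(
        config=cfg_echo,
        version=__version__,
        exclusions=exclusions,
        fit_table=fit_table,
        group_results=group_results,
        shuffle=shuffle_summary,
    )
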