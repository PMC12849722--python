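"""Per-participant regression fits, α aggregation, partial residuals, shuffle control.

The central fit is the three-predictor "prediction model"

    ResponseError_n = β0 + β_StimHist·StimulusProximity_n
                        + β_RespHist·ResponseProximity_n
                        + β_Pred·PredictionDeviation_n + ε,

fit per participant by OLS on the retained consecutive trial pairs.
β_Pred > 0 means responses are more accurate the closer they stay to the
prior-informed landing, i.e. the prior is relied upon. Signed history slopes
come from simple regressions of the current signed lateral error on the
previous lateral displacement (β_Stim) or the previous signed error
(β_Resp). All fits can be restricted to pairs whose previous trial was
neutral or maximal distortion.

The shuffle control permutes a participant's retained trials, recomputes
every history-dependent predictor from the permuted order, and refits the
prediction model; with serial structure destroyed the β_Pred p-values should
be uniform (mean ≈ 0.5) and the mean slope ≈ 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import metrics_frame

__all__ = [
    "RankDeficientError",
    "OLSFit",
    "PredictionModelFit",
    "PartialResidualSet",
    "ShuffleSummary",
    "ParticipantFit",
    "ols",
    "fit_prediction_model",
    "fit_simple_prediction",
    "fit_signed_history",
    "partial_residuals",
    "mean_alpha",
    "participant_summary",
    "shuffle_control",
    "fit_participant",
]

MIN_PAIRS = 10  # fewer pairs than this and a slope is not trusted

PREDICTORS = ["stimulus_proximity", "response_proximity", "prediction_deviation"]


class RankDeficientError(ValueError):
    """Design matrix is rank deficient (e.g. duplicated predictor columns)."""


@dataclass(frozen=True)
class OLSFit:
    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    residuals: np.ndarray
    df_resid: int

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])


def ols(X: np.ndarray, y: np.ndarray, names: tuple[str, ...]) -> OLSFit:
    """Ordinary least squares with classical (normal-theory) inference.

    Lean numpy implementation used thousands of times by the shuffle and
    null-calibration loops; agrees with statsmodels to numerical precision.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than parameters ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficientError("rank-deficient design matrix")
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dfr = n - p
    s2 = float(resid @ resid) / dfr
    se = np.sqrt(np.diag(np.linalg.inv(xtx)) * s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dfr)
    return OLSFit(tuple(names), beta, se, pvals, resid, dfr)


@dataclass(frozen=True)
class PredictionModelFit:
    """Three-predictor model coefficients plus what partial residuals need."""

    beta0: float
    beta_stimhist: float
    beta_resphist: float
    beta_pred: float
    pvalues: dict[str, float]
    n: int
    _ols: OLSFit = field(repr=False)
    _X: np.ndarray = field(repr=False)


def _filter(metrics: pd.DataFrame, condition: Optional[str]) -> pd.DataFrame:
    if condition is not None:
        if condition not in ("neutral", "mid", "max"):
            raise ValueError(f"unknown condition filter {condition!r}")
        metrics = metrics[metrics["condition"] == condition]
    return metrics


def _model_rows(metrics: pd.DataFrame, condition: Optional[str]) -> pd.DataFrame:
    """Rows eligible for prediction-model fits.

    Pairs whose previous displacement is exactly the zero vector are dropped:
    for them the prior-informed landing coincides with the last-seen position
    and PredictionDeviation ≡ ResponseError, a tautological row (the same
    |Δ| > 0 eligibility that guards α).
    """
    m = _filter(metrics, condition)
    if "abs_displacement" in m.columns:
        m = m[m["abs_displacement"].to_numpy() > 0]
    return m


def fit_prediction_model(
    metrics: pd.DataFrame,
    condition: Optional[str] = None,
    min_pairs: int = MIN_PAIRS,
) -> PredictionModelFit:
    """OLS of response error on [1, stimulus prox., response prox., prediction dev.].

    Fit on eligible pairs only (nonzero previous displacement).
    """
    m = _model_rows(metrics, condition)
    if len(m) < min_pairs:
        raise ValueError(f"only {len(m)} pairs, need >= {min_pairs}")
    X = np.column_stack(
        [np.ones(len(m))] + [m[c].to_numpy() for c in PREDICTORS]
    )
    res = ols(X, m["response_error"].to_numpy(), ("intercept", *PREDICTORS))
    return PredictionModelFit(
        beta0=res.coef("intercept"),
        beta_stimhist=res.coef("stimulus_proximity"),
        beta_resphist=res.coef("response_proximity"),
        beta_pred=res.coef("prediction_deviation"),
        pvalues={k: res.pvalue(k) for k in res.names},
        n=len(m),
        _ols=res,
        _X=X,
    )


def fit_simple_prediction(
    metrics: pd.DataFrame,
    condition: Optional[str] = None,
    min_pairs: int = MIN_PAIRS,
) -> float:
    """Simple-regression slope of response error on prediction deviation alone."""
    m = _model_rows(metrics, condition)
    if len(m) < min_pairs:
        raise ValueError(f"only {len(m)} pairs, need >= {min_pairs}")
    X = np.column_stack([np.ones(len(m)), m["prediction_deviation"].to_numpy()])
    return ols(X, m["response_error"].to_numpy(), ("intercept", "prediction_deviation")).beta[1]


def fit_signed_history(
    metrics: pd.DataFrame,
    which: str,
    condition: Optional[str] = None,
    min_pairs: int = MIN_PAIRS,
) -> float:
    """Signed history slope: errx_curr on dx_prev (stimulus) or errx_prev (response)."""
    if which not in ("stimulus", "response"):
        raise ValueError("which must be 'stimulus' or 'response'")
    m = _filter(metrics, condition)
    if len(m) < min_pairs:
        raise ValueError(f"only {len(m)} pairs, need >= {min_pairs}")
    x = m["dx_prev" if which == "stimulus" else "errx_prev"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the history predictor")
    X = np.column_stack([np.ones(len(m)), x])
    return ols(X, m["errx_curr"].to_numpy(), ("intercept", which)).beta[1]


@dataclass(frozen=True)
class PartialResidualSet:
    predictor: str
    values: np.ndarray
    slope: float


def partial_residuals(fit: PredictionModelFit, predictor: str) -> PartialResidualSet:
    """r_partial = residuals + β̂_x·X for one predictor of the prediction model.

    Regressing the values back on the predictor recovers β̂_x exactly; the
    values may be negative despite non-negative distances (residual centering).
    """
    if predictor not in PREDICTORS:
        raise ValueError(f"{predictor!r} is not a predictor of the model")
    j = fit._ols.names.index(predictor)
    return PartialResidualSet(
        predictor=predictor,
        values=fit._ols.residuals + fit._ols.beta[j] * fit._X[:, j],
        slope=float(fit._ols.beta[j]),
    )


def mean_alpha(metrics: pd.DataFrame, condition: Optional[str] = None) -> float:
    """Mean of defined α over eligible pairs (neutral-previous pairs contribute none)."""
    a = _filter(metrics, condition)["alpha"].to_numpy()
    a = a[~np.isnan(a)]
    if a.size == 0:
        raise ValueError("no eligible pairs with defined alpha")
    return float(a.mean())


def participant_summary(
    retained: pd.DataFrame, metrics: pd.DataFrame
) -> tuple[float, float, float]:
    """(accuracy, precision, mean |displacement|) of one participant.

    Accuracy is the mean and precision the SD of the response error over
    retained trials; displacement magnitude is averaged over pairs.
    """
    if len(retained) < 2:
        raise ValueError("need at least 2 retained trials")
    err = np.hypot(
        retained["resp_x"].to_numpy() - retained["bx_before"].to_numpy(),
        retained["resp_y"].to_numpy() - retained["by_before"].to_numpy(),
    )
    return (
        float(err.mean()),
        float(err.std(ddof=1)),
        float(metrics["abs_displacement"].mean()) if len(metrics) else 0.0,
    )


@dataclass(frozen=True)
class ShuffleSummary:
    n_shuffles: int
    slopes: np.ndarray
    pvalues: np.ndarray

    @property
    def mean_slope(self) -> float:
        return float(self.slopes.mean())

    @property
    def mean_p(self) -> float:
        return float(self.pvalues.mean())


def shuffle_control(
    retained: pd.DataFrame,
    max_force: float,
    n_shuffles: int,
    rng: np.random.Generator,
    min_pairs: int = MIN_PAIRS,
) -> ShuffleSummary:
    """Permutation null for β_Pred.

    Each shuffle permutes the retained trials uniformly (block boundaries
    ignored), recomputes all history predictors from the permuted order, and
    refits the prediction model.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    n = len(retained)
    if n - 1 < min_pairs:
        raise ValueError("too few retained trials for the shuffle control")
    adjacent = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    slopes = np.empty(n_shuffles)
    pvals = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(n)
        shuffled = retained.iloc[perm].reset_index(drop=True)
        m = metrics_frame(shuffled, max_force, pairs=adjacent)
        fit = fit_prediction_model(m, min_pairs=min_pairs)
        slopes[s] = fit.beta_pred
        pvals[s] = fit.pvalues["prediction_deviation"]
    return ShuffleSummary(n_shuffles, slopes, pvals)


@dataclass(frozen=True)
class ParticipantFit:
    """All per-participant measures entering group-level inference."""

    participant_id: str
    usable: bool
    n_pairs: int
    # three-predictor model, overall
    beta0: float = np.nan
    beta_stimhist: float = np.nan
    beta_resphist: float = np.nan
    beta_pred: float = np.nan
    beta_pred_p: float = np.nan
    # simple-regression variant of the prediction slope
    beta_pred_simple: float = np.nan
    # signed history slopes
    beta_stim_signed: float = np.nan
    beta_resp_signed: float = np.nan
    # directional updating
    alpha_mean: float = np.nan
    # mean distance from the prior-informed landing
    mean_prediction_deviation: float = np.nan
    # per-condition variants (previous-trial condition)
    beta_pred_neutral: float = np.nan
    beta_pred_mid: float = np.nan
    beta_pred_max: float = np.nan
    beta_pred_simple_neutral: float = np.nan
    beta_pred_simple_max: float = np.nan
    beta_stim_signed_neutral: float = np.nan
    beta_stim_signed_max: float = np.nan
    beta_resp_signed_neutral: float = np.nan
    beta_resp_signed_max: float = np.nan
    alpha_neutral: float = np.nan  # undefined by construction; kept for symmetry
    alpha_max: float = np.nan
    alpha_mid: float = np.nan
    # summaries
    accuracy: float = np.nan
    precision: float = np.nan
    mean_abs_displacement: float = np.nan


def _maybe(fn, *args, **kwargs) -> float:
    try:
        return float(fn(*args, **kwargs))
    except (ValueError, RankDeficientError):
        return float("nan")


def fit_participant(
    trials_retained: pd.DataFrame,
    metrics: pd.DataFrame,
    min_pairs: int = MIN_PAIRS,
) -> ParticipantFit:
    """Compute every per-participant measure from retained trials + metrics."""
    pid = str(trials_retained["participant_id"].iloc[0]) if len(trials_retained) else "?"
    n_pairs = len(metrics)
    if n_pairs < min_pairs:
        return ParticipantFit(pid, usable=False, n_pairs=n_pairs)
    try:
        full = fit_prediction_model(metrics, min_pairs=min_pairs)
    except (ValueError, RankDeficientError):
        return ParticipantFit(pid, usable=False, n_pairs=n_pairs)
    acc, prec, disp = participant_summary(trials_retained, metrics)
    return ParticipantFit(
        participant_id=pid,
        usable=True,
        n_pairs=n_pairs,
        beta0=full.beta0,
        beta_stimhist=full.beta_stimhist,
        beta_resphist=full.beta_resphist,
        beta_pred=full.beta_pred,
        beta_pred_p=full.pvalues["prediction_deviation"],
        beta_pred_simple=_maybe(fit_simple_prediction, metrics, min_pairs=min_pairs),
        beta_stim_signed=_maybe(fit_signed_history, metrics, "stimulus", min_pairs=min_pairs),
        beta_resp_signed=_maybe(fit_signed_history, metrics, "response", min_pairs=min_pairs),
        alpha_mean=_maybe(mean_alpha, metrics),
        mean_prediction_deviation=float(metrics["prediction_deviation"].mean()),
        beta_pred_neutral=_maybe(
            lambda: fit_prediction_model(metrics, "neutral", min_pairs).beta_pred
        ),
        beta_pred_mid=_maybe(
            lambda: fit_prediction_model(metrics, "mid", min_pairs).beta_pred
        ),
        beta_pred_max=_maybe(
            lambda: fit_prediction_model(metrics, "max", min_pairs).beta_pred
        ),
        beta_pred_simple_neutral=_maybe(
            fit_simple_prediction, metrics, "neutral", min_pairs
        ),
        beta_pred_simple_max=_maybe(fit_simple_prediction, metrics, "max", min_pairs),
        beta_stim_signed_neutral=_maybe(
            fit_signed_history, metrics, "stimulus", "neutral", min_pairs
        ),
        beta_stim_signed_max=_maybe(
            fit_signed_history, metrics, "stimulus", "max", min_pairs
        ),
        beta_resp_signed_neutral=_maybe(
            fit_signed_history, metrics, "response", "neutral", min_pairs
        ),
        beta_resp_signed_max=_maybe(
            fit_signed_history, metrics, "response", "max", min_pairs
        ),
        alpha_max=_maybe(mean_alpha, metrics, "max"),
        alpha_mid=_maybe(mean_alpha, metrics, "mid"),
        accuracy=acc,
        precision=prec,
        mean_abs_displacement=disp,
    )
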