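"""Model comparison: linking model outputs to VAS and BIC Bayes factors.

Three candidate per-rating predictors of the VAS pain report are
compared by ordinary least squares:

* **M1 (temperature)** — the window-mean stimulus temperature expressed
  as drive (temp - plateau) at the rating time;
* **M2 (dynamic)** — the deterministic second-order model's aggregated
  pain state;
* **M3 (phasic)** — the Bayesian filter's aggregated phasic estimate.

Each regression is VAS ~ intercept + slope * predictor, pooled over
participants (participant structure is the business of the mixed-model
analysis, not of this stage).  Models are ranked by BIC and compared by
the BIC approximation of the Bayes factor, BF_ab = exp((BIC_b - BIC_a)/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .aggregate import RATING_LABELS, aggregate_at_schedule
from .bayesian import BayesParams, phasic_at_ratings, run_filter
from .deterministic import DynParams, aggregate_at_ratings, simulate_dynamic
from .errors import FittingError, InputError
from .stimulus import RatingSchedule, StimulusTrace

__all__ = [
    "MODEL_NAMES",
    "LinearLink",
    "RegressionFit",
    "ModelComparison",
    "predict_vas",
    "fit_regression",
    "bayes_factor_from_bic",
    "condition_predictors",
    "compare_models",
]

MODEL_NAMES = ("M1_temperature", "M2_dynamic", "M3_phasic")


@dataclass(frozen=True)
class LinearLink:
    """Affine map from model drive units to the VAS.

    The rating scale is anchored so that VAS = 50 corresponds to the
    45 °C plateau (zero drive); ``slope`` converts one drive unit
    (°C-equivalent) into VAS points.
    """

    anchor: float = 50.0
    slope: float = 30.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.anchor) and math.isfinite(self.slope)):
            raise InputError("link parameters must be finite")


def predict_vas(
    model_aggregates: np.ndarray, link: LinearLink, clip: bool = False
) -> np.ndarray:
    """Map aggregated model values to VAS predictions.

    Clipping to [0, 100] is applied only when a reportable rating is
    produced (``clip=True``), never during fitting.
    """
    agg = np.asarray(model_aggregates, dtype=float)
    if not np.all(np.isfinite(agg)):
        raise InputError("model aggregates must be finite")
    vas = link.anchor + link.slope * agg
    return np.clip(vas, 0.0, 100.0) if clip else vas


@dataclass
class RegressionFit:
    """OLS fit of VAS on one model predictor with Gaussian ML criteria."""

    model: str
    n_obs: int
    n_params: int
    intercept: float
    slope: float
    slope_se: float
    sigma: float
    loglik: float
    aic: float
    bic: float

    def to_dict(self) -> dict:
        return {
            "model": self.model, "n": self.n_obs, "k": self.n_params,
            "intercept": self.intercept, "slope": self.slope,
            "sigma": self.sigma, "loglik": self.loglik,
            "aic": self.aic, "bic": self.bic,
        }


def fit_regression(
    vas: np.ndarray, predictor: np.ndarray, model: str = ""
) -> RegressionFit:
    """OLS of VAS on a predictor; AIC/BIC with k = 3 (intercept, slope,
    residual variance) at the Gaussian maximum likelihood."""
    y = np.asarray(vas, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if len(y) != len(x):
        raise InputError("vas and predictor must be aligned")
    n = len(y)
    if n < 3:
        raise InputError("need at least 3 observations")
    if np.std(x) == 0:
        raise FittingError("predictor has zero variance; slope is unidentified")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    k = 3
    ll = float(res.llf)  # Gaussian log-likelihood at the MLE (sigma^2 = RSS/n)
    sigma2 = float(res.ssr / n)
    return RegressionFit(
        model=model,
        n_obs=n,
        n_params=k,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        sigma=float(np.sqrt(sigma2)),
        loglik=ll,
        aic=2 * k - 2 * ll,
        bic=k * np.log(n) - 2 * ll,
    )


def bayes_factor_from_bic(bic_a: float, bic_b: float) -> tuple[float, float]:
    """Bayes factor of model a over model b from their BICs.

    Returns ``(bf, log_bf)``; ``bf`` is ``inf`` when the log Bayes
    factor overflows the float range (the log value is always exact).
    """
    log_bf = 0.5 * (bic_b - bic_a)
    try:
        bf = math.exp(log_bf)
    except OverflowError:
        bf = math.inf
    return bf, log_bf


@dataclass
class ModelComparison:
    """Per-model regression criteria and the pairwise log-BF matrix."""

    fits: dict[str, RegressionFit]
    log_bf: pd.DataFrame = field(repr=False)

    def bf(self, a: str, b: str) -> float:
        lb = float(self.log_bf.loc[a, b])
        try:
            return math.exp(lb)
        except OverflowError:
            return math.inf

    @property
    def preferred(self) -> str:
        return min(self.fits, key=lambda m: self.fits[m].bic)

    def to_dict(self) -> dict:
        return {
            "models": {m: f.to_dict() for m, f in self.fits.items()},
            "log_bf": {a: {b: float(self.log_bf.loc[a, b])
                           for b in self.log_bf.columns}
                       for a in self.log_bf.index},
            "preferred": self.preferred,
        }


def condition_predictors(
    traces: Mapping[str, StimulusTrace],
    dyn_params: DynParams,
    bayes_params: BayesParams,
    schedule: RatingSchedule,
) -> dict[str, pd.DataFrame]:
    """Per-condition, per-rating values of the three model predictors.

    Returns ``{condition: DataFrame indexed by R0..R3 with columns
    M1_temperature, M2_dynamic, M3_phasic}`` in drive units.  Each
    observer runs once per condition; predictors are shared by all
    trials of that condition.
    """
    out: dict[str, pd.DataFrame] = {}
    for cond, trace in traces.items():
        plateau = trace.protocol.plateau_temp if trace.protocol else 45.0
        m1 = aggregate_at_schedule(trace.time, trace.temp - plateau, schedule)
        m2 = aggregate_at_ratings(simulate_dynamic(trace, dyn_params), schedule)
        m3 = phasic_at_ratings(run_filter(trace, bayes_params), schedule)
        out[cond] = pd.DataFrame(
            {"M1_temperature": m1, "M2_dynamic": m2, "M3_phasic": m3},
            index=list(RATING_LABELS),
        )
    return out


def compare_models(
    ratings: pd.DataFrame,
    traces: Mapping[str, StimulusTrace],
    dyn_params: DynParams,
    bayes_params: BayesParams,
    schedule: RatingSchedule,
    timings: tuple[str, ...] = RATING_LABELS,
) -> ModelComparison:
    """Fit the three candidate regressions on a long-format rating table.

    ``ratings`` needs columns ``condition``, ``timing`` and ``vas``;
    every rated condition must have a matching trace.  All three models
    are fit on exactly the same observations.
    """
    required = {"condition", "timing", "vas"}
    if not required.issubset(ratings.columns):
        raise InputError(f"ratings table must contain columns {sorted(required)}")
    rows = ratings[ratings["timing"].isin(timings)].reset_index(drop=True)
    missing = set(rows["condition"]) - set(traces)
    if missing:
        raise InputError(f"no stimulus trace for condition(s): {sorted(missing)}")
    preds = condition_predictors(traces, dyn_params, bayes_params, schedule)
    X = np.empty((len(rows), len(MODEL_NAMES)))
    for i, (cond, timing) in enumerate(zip(rows["condition"], rows["timing"])):
        X[i] = preds[cond].loc[timing, list(MODEL_NAMES)].to_numpy()
    y = rows["vas"].to_numpy(dtype=float)
    fits = {
        m: fit_regression(y, X[:, j], model=m) for j, m in enumerate(MODEL_NAMES)
    }
    ns = {f.n_obs for f in fits.values()}
    assert len(ns) == 1, "models must be fit on identical observations"
    log_bf = pd.DataFrame(
        [[0.5 * (fits[b].bic - fits[a].bic) for b in MODEL_NAMES] for a in MODEL_NAMES],
        index=list(MODEL_NAMES),
        columns=list(MODEL_NAMES),
    )
    return ModelComparison(fits=fits, log_bf=log_bf)
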