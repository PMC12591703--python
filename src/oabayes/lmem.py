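"""Model-naïve statistics: random-intercept linear mixed models.

The behavioural analysis asks whether the T3-phase pain ratings (R1-R3)
depend on rating timing, on the presence of the high-frequency
disturbance, and on which disturbance sequence was played, while
absorbing stable between-participant differences in reported intensity
into a participant-level random intercept.

Factor codings (sum-to-zero, half-unit contrasts):

* timing:   R1 = -0.5, R2 = 0, R3 = +0.5
* stimulus: conventional = -0.5, high-frequency disturbance = +0.5
* sequence: sequence #1 = -0.5, sequence #2 = +0.5 (undefined and
  excluded for conventional trials)

The model is ``vas ~ 1 + terms`` with a Gaussian random intercept per
participant, fit by maximum likelihood with the fixed effects profiled
out by generalized least squares and the variance-ratio
``psi = sigma_b^2 / sigma_e^2`` optimized numerically.  Inference uses
residual-type degrees of freedom ``df = n - p - (g - 1)`` and two-sided
t tests; effect sizes are Cohen's d = 2 t / sqrt(df).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InputError

__all__ = [
    "TIMING_CODES",
    "STIMULUS_CODES",
    "SEQUENCE_CODES",
    "code_factors",
    "t3_view",
    "sequence_view",
    "LmemFit",
    "fit_random_intercept",
    "cohens_d",
]

TIMING_CODES = {"R1": -0.5, "R2": 0.0, "R3": 0.5}
STIMULUS_CODES = {
    "conventional": -0.5,
    "noise_seq1": 0.5,
    "noise_seq2": 0.5,
}
SEQUENCE_CODES = {"noise_seq1": -0.5, "noise_seq2": 0.5}

_CONDITIONS = ("constant", "conventional", "noise_seq1", "noise_seq2")
_TIMINGS = ("R0", "R1", "R2", "R3")


def code_factors(raw: pd.DataFrame) -> pd.DataFrame:
    """Attach numeric factor codes to a long-format rating table.

    ``raw`` needs columns ``participant``, ``trial``, ``condition``,
    ``timing`` and ``vas``.  Unknown condition or timing labels raise.
    Sequence codes are missing (NaN) on non-noise trials.
    """
    required = {"participant", "trial", "condition", "timing", "vas"}
    if not required.issubset(raw.columns):
        raise InputError(f"rating table must contain columns {sorted(required)}")
    bad_cond = set(raw["condition"]) - set(_CONDITIONS)
    if bad_cond:
        raise InputError(f"unknown condition label(s): {sorted(bad_cond)}")
    bad_time = set(raw["timing"]) - set(_TIMINGS)
    if bad_time:
        raise InputError(f"unknown timing label(s): {sorted(bad_time)}")
    out = raw.copy()
    out["timing_code"] = out["timing"].map(TIMING_CODES)
    out["stimulus_code"] = out["condition"].map(STIMULUS_CODES)
    out["sequence_code"] = out["condition"].map(SEQUENCE_CODES)
    return out


def t3_view(table: pd.DataFrame) -> pd.DataFrame:
    """R1-R3 rows of OA-stimulus trials (timing x stimulus analysis)."""
    keep = table["timing"].isin(("R1", "R2", "R3")) & table["condition"].isin(
        ("conventional", "noise_seq1", "noise_seq2")
    )
    return table[keep].reset_index(drop=True)


def sequence_view(table: pd.DataFrame) -> pd.DataFrame:
    """R1-R3 rows of noise trials only (timing x sequence analysis)."""
    keep = table["timing"].isin(("R1", "R2", "R3")) & table["condition"].isin(
        ("noise_seq1", "noise_seq2")
    )
    return table[keep].reset_index(drop=True)


@dataclass
class LmemFit:
    """Fitted random-intercept model."""

    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: float
    p: np.ndarray
    cohen_d: np.ndarray
    sigma_b2: float
    sigma_e2: float
    loglik: float
    n_obs: int
    n_groups: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "se": self.se,
                "t": self.t,
                "df": self.df,
                "p": self.p,
                "cohen_d": self.cohen_d,
            },
            index=self.terms,
        )

    def __getitem__(self, term: str) -> pd.Series:
        return self.summary().loc[term]

    def to_dict(self) -> dict:
        return {
            "terms": {
                term: {
                    "estimate": float(self.estimates[i]),
                    "se": float(self.se[i]),
                    "t": float(self.t[i]),
                    "p": float(self.p[i]),
                    "cohen_d": float(self.cohen_d[i]),
                }
                for i, term in enumerate(self.terms)
            },
            "df": float(self.df),
            "sigma_b2": self.sigma_b2,
            "sigma_e2": self.sigma_e2,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }


def _design_matrix(table: pd.DataFrame, fixed_terms: list[str]) -> np.ndarray:
    """Intercept plus the named columns; 'a:b' denotes a product term."""
    cols = [np.ones(len(table))]
    for term in fixed_terms:
        parts = term.split(":")
        col = np.ones(len(table))
        for part in parts:
            if part not in table.columns:
                raise InputError(f"unknown fixed-effect column {part!r}")
            col = col * table[part].to_numpy(dtype=float)
        cols.append(col)
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise InputError("design matrix contains missing values")
    return X


def _profile_ml(
    psi: float, X: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profiled ML at variance ratio psi = sigma_b^2 / sigma_e^2.

    For the random-intercept model V = sigma_e^2 (I + psi Z Z'); per
    group V_g^{-1} = (I - w J)/sigma_e^2 with w = psi / (1 + n_g psi),
    so all GLS quantities reduce to group sums.  Returns
    (-2 loglik, beta, cov_beta_unscaled, sigma_e^2_ML).
    """
    n, p = X.shape
    uniq, idx = np.unique(groups, return_inverse=True)
    ng = np.bincount(idx)
    w = psi / (1.0 + ng * psi)
    # group sums of X and y
    Sx = np.zeros((len(uniq), p))
    Sy = np.zeros(len(uniq))
    np.add.at(Sx, idx, X)
    np.add.at(Sy, idx, y)
    A = X.T @ X - (Sx * w[:, None]).T @ Sx          # X' V^-1 X * sigma_e^2
    b = X.T @ y - Sx.T @ (w * Sy)                   # X' V^-1 y * sigma_e^2
    yy = y @ y - w @ (Sy * Sy)                      # y' V^-1 y * sigma_e^2
    beta = np.linalg.solve(A, b)
    rss = yy - 2 * beta @ b + beta @ A @ beta
    rss = max(rss, 1e-300)
    sigma_e2 = rss / n
    logdet = n * math.log(sigma_e2) + float(np.log1p(ng * psi).sum())
    m2ll = n * math.log(2 * math.pi) + logdet + n
    return m2ll, beta, np.linalg.inv(A), sigma_e2


def fit_random_intercept(
    table: pd.DataFrame,
    fixed_terms: list[str],
    response: str = "vas",
    group: str = "participant",
) -> LmemFit:
    """Fit ``response ~ 1 + fixed_terms + (1 | group)`` by ML.

    ``fixed_terms`` are column names of coded factors; ``"a:b"`` adds
    the product (interaction) of two coded columns.  The variance ratio
    is optimized by bounded scalar search; a boundary estimate of zero
    between-participant variance is allowed and reduces to OLS.
    """
    y = table[response].to_numpy(dtype=float)
    groups = table[group].to_numpy()
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise InputError("need at least 2 participants for a random intercept")
    if counts.min() < 2:
        raise InputError("each participant needs at least 2 observations")
    X = _design_matrix(table, fixed_terms)
    n, p = X.shape

    res = optimize.minimize_scalar(
        lambda log_psi: _profile_ml(math.exp(log_psi), X, y, groups)[0],
        bounds=(-30.0, 15.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    psi = math.exp(res.x)
    m2ll_psi = res.fun
    # the boundary psi = 0 is outside the log parametrization; take it
    # when it does at least as well
    m2ll_0, *_ = _profile_ml(0.0, X, y, groups)
    if m2ll_0 <= m2ll_psi + 1e-10:
        psi = 0.0
    m2ll, beta, Ainv, sigma_e2 = _profile_ml(psi, X, y, groups)
    cov_beta = sigma_e2 * Ainv
    se = np.sqrt(np.diag(cov_beta))
    t = beta / se
    g = len(uniq)
    df = n - p - (g - 1)
    if df <= 0:
        raise InputError("non-positive residual degrees of freedom")
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    d = np.array([cohens_d(ti, df) for ti in t])
    terms = ["intercept", *fixed_terms]
    return LmemFit(
        terms=terms,
        estimates=beta,
        se=se,
        t=t,
        df=float(df),
        p=pvals,
        cohen_d=d,
        sigma_b2=float(psi * sigma_e2),
        sigma_e2=float(sigma_e2),
        loglik=float(-0.5 * m2ll),
        n_obs=n,
        n_groups=g,
    )


def cohens_d(t: float, df: float) -> float:
    """Effect size d = 2 t / sqrt(df) for a mixed-model fixed effect."""
    if df <= 0:
        raise InputError("df must be > 0")
    return 2.0 * float(t) / math.sqrt(df)
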