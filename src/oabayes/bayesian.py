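"""Recursive Bayesian integration model of pain perception.

Perceived pain is modelled as the output of an online estimator that
tracks two latent components of the noxious drive ``u = temp - 45``:

* a **tonic** component ``x``: a slow random walk carrying the sustained
  stimulus level, and
* a **phasic** component ``dx``: an AR(1) transient with per-step decay
  ``a`` that captures rapid departures from the tonic level.

The observation at each step is ``u_k = x_k + dx_k + noise``.  Under
linear-Gaussian assumptions the posterior is computed exactly by a
two-state Kalman filter; the phasic posterior mean is the model of
subjective pain.  After the 47 -> 45 °C offset the tonic estimate is
still elevated, so the phasic estimate is driven below zero (the OA
undershoot) and then relaxes back at rate ``a``.

The observation variance ``r`` is estimated online from exponentially
weighted squared innovations.  A high-frequency disturbance in the
stimulus inflates the innovation variance, the estimated ``r`` grows,
the Kalman gain shrinks, and the filter stops chasing the disturbance:
the phasic estimate relaxes toward zero faster and becomes nearly
independent of the particular disturbance sequence.  This adaptive-gain
mechanism is how the model reproduces both the attenuation of OA by
noise and its insensitivity to the exact noise sequence.

:func:`grid_bayes_oracle` provides an independent brute-force check: the
same recursive Bayes computation on a dense 2-D grid over the state
space, with no Kalman algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aggregate import aggregate_at_schedule
from .errors import (
    ConfigurationError,
    InputError,
    NumericalError,
    OracleResolutionError,
)
from .stimulus import RatingSchedule, StimulusTrace

__all__ = [
    "BayesParams",
    "FilterState",
    "FilterTrace",
    "kf_predict",
    "kf_update",
    "run_filter",
    "phasic_at_ratings",
    "grid_bayes_oracle",
    "steady_state_covariance",
]

_H = np.array([1.0, 1.0])


@dataclass(frozen=True)
class BayesParams:
    """Parameters of the tonic/phasic filter (all per step).

    ``phasic_decay``: AR(1) coefficient ``a`` of the phasic state;
    ``1 / (rate * (1 - a))`` is its time constant in seconds.
    ``q_tonic`` / ``q_phasic``: process variances of the tonic random
    walk and the phasic innovation.
    ``r_obs0``: initial observation variance; ``r_min``: floor of the
    adaptive estimate; ``beta_adapt``: weight of the exponential window
    used to track the innovation variance (0 disables adaptation).
    ``center_innovations``: estimate the variance around a running
    innovation mean (default), so a persistent bias — an unabsorbed
    stimulus step — is not mistaken for observation noise; ``False``
    uses the raw squared innovation instead.
    ``innovation_clip``: gate (winsorize) each squared innovation at
    ``clip^2`` times the predicted innovation variance S before it
    enters the variance estimate, so a single surprise step (a stimulus
    edge) cannot inflate the noise estimate, while sustained
    fluctuations ratchet it up; ``inf`` disables gating.
    ``step_rate_hz``: filter step rate (matched to the trace grid).
    ``prior_var_tonic`` / ``prior_var_phasic``: initial state variances.
    """

    phasic_decay: float = 0.90
    q_tonic: float = 1e-6
    q_phasic: float = 8e-4
    r_obs0: float = 0.065
    r_min: float = 2e-4
    beta_adapt: float = 0.07
    step_rate_hz: float = 3.0
    prior_var_tonic: float = 1.0
    prior_var_phasic: float = 1.0
    center_innovations: bool = True
    innovation_clip: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.phasic_decay < 1.0):
            raise ConfigurationError("phasic_decay must be in (0, 1)")
        for name in ("q_tonic", "q_phasic", "r_obs0",
                     "prior_var_tonic", "prior_var_phasic"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.r_min <= 0:
            raise ConfigurationError("r_min must be > 0")
        if not (0.0 <= self.beta_adapt <= 1.0):
            raise ConfigurationError("beta_adapt must be in [0, 1]")
        if self.innovation_clip <= 0:
            raise ConfigurationError("innovation_clip must be > 0")
        if self.step_rate_hz <= 0:
            raise ConfigurationError("step_rate_hz must be > 0")

    @property
    def F(self) -> np.ndarray:
        return np.array([[1.0, 0.0], [0.0, self.phasic_decay]])

    @property
    def Q(self) -> np.ndarray:
        return np.diag([self.q_tonic, self.q_phasic])


@dataclass
class FilterState:
    """Posterior state: mean [tonic, phasic], 2x2 covariance, adaptive r."""

    mean: np.ndarray
    cov: np.ndarray
    r_hat: float
    e_bar: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        self.check_psd()

    def check_psd(self, tol: float = 1e-10) -> None:
        sym = 0.5 * (self.cov + self.cov.T)
        eig = np.linalg.eigvalsh(sym)
        if eig.min() < -tol:
            raise NumericalError(
                f"state covariance is not PSD (min eigenvalue {eig.min():.3e})"
            )

    @property
    def tonic(self) -> float:
        return float(self.mean[0])

    @property
    def phasic(self) -> float:
        return float(self.mean[1])


@dataclass
class FilterTrace:
    """Per-step filter output along a stimulus trace."""

    time: np.ndarray
    tonic_mean: np.ndarray
    phasic_mean: np.ndarray
    gain: np.ndarray          # (n, 2): tonic and phasic Kalman gains
    innovation: np.ndarray
    r_hat: np.ndarray
    input_u: np.ndarray
    params: Optional[BayesParams] = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "tonic_mean": self.tonic_mean,
                "phasic_mean": self.phasic_mean,
                "gain_tonic": self.gain[:, 0],
                "gain_phasic": self.gain[:, 1],
                "innovation": self.innovation,
                "r_hat": self.r_hat,
            }
        )


def kf_predict(state: FilterState, params: BayesParams) -> FilterState:
    """One prediction step: tonic persists, phasic decays by ``a``;
    process noise is added to both variances.  ``r_hat`` is unchanged."""
    state.check_psd()
    F = params.F
    mean = F @ state.mean
    cov = F @ state.cov @ F.T + params.Q
    cov = 0.5 * (cov + cov.T)
    return FilterState(mean=mean, cov=cov, r_hat=state.r_hat, e_bar=state.e_bar)


def kf_update(
    state: FilterState, obs: float, params: BayesParams
) -> tuple[FilterState, float, np.ndarray]:
    """One measurement update with observation model ``u = tonic + phasic``.

    Returns ``(posterior, innovation, gain)``.  After the state update
    the observation variance estimate is refreshed from the innovation
    stream: ``r <- max(r_min, (1-beta) r + beta (de^2 - H P H'))``,
    the excess of the realized innovation variability over what the
    state uncertainty alone explains.  With ``center_innovations`` the
    innovation is first centered on its exponentially weighted running
    mean (``de = e - e_bar``): only the fluctuating part of the
    innovation counts as noise, while a sustained bias is left for the
    state to absorb.  With ``center_innovations=False`` the raw
    innovation is used (``de = e``).
    """
    H = _H
    cov_pred = state.cov
    e = float(obs - H @ state.mean)
    s = float(H @ cov_pred @ H + state.r_hat)
    if s <= 0:
        raise NumericalError(f"innovation variance is non-positive ({s:.3e})")
    K = cov_pred @ H / s
    mean = state.mean + K * e
    # Joseph form for numerical robustness
    ImKH = np.eye(2) - np.outer(K, H)
    cov = ImKH @ cov_pred @ ImKH.T + np.outer(K, K) * state.r_hat
    cov = 0.5 * (cov + cov.T)
    beta = params.beta_adapt
    r_new = state.r_hat
    e_bar = state.e_bar
    if beta > 0:
        de = e - e_bar if params.center_innovations else e
        de2 = min(de * de, params.innovation_clip**2 * s)
        r_new = (1.0 - beta) * state.r_hat + beta * (de2 - float(H @ cov_pred @ H))
        r_new = max(params.r_min, r_new)
        e_bar = (1.0 - beta) * e_bar + beta * e
    return FilterState(mean=mean, cov=cov, r_hat=r_new, e_bar=e_bar), e, K


def initial_state(params: BayesParams, u0: float) -> FilterState:
    """Prior at trial onset: tonic at the initial drive, phasic at zero."""
    return FilterState(
        mean=np.array([u0, 0.0]),
        cov=np.diag([params.prior_var_tonic, params.prior_var_phasic]),
        r_hat=params.r_obs0,
    )


def run_filter(
    trace: StimulusTrace,
    params: BayesParams,
    plateau_temp: Optional[float] = None,
) -> FilterTrace:
    """Run the filter over a stimulus trace.

    Observations are ``u_k = temp_k - plateau_temp`` so the 45 °C
    plateau maps to zero drive and VAS 50.  The trace's own protocol
    supplies ``plateau_temp`` when not given.

    The recursion starts when the stimulus first reaches the plateau
    (end of the initial ramp): the 32 °C baseline lies far below the
    heat-pain threshold, where a linear drive ``temp - 45`` is not a
    meaningful nociceptive signal, and the rating scale is anchored to
    the plateau percept.  Samples before that point report the initial
    state (zero tonic and phasic estimates).

    The filter steps at ``params.step_rate_hz`` — the perceptual
    evidence-accumulation rate, slower than the 30 Hz physical sampling
    — by taking every m-th temperature sample as an observation
    (m = trace rate / step rate).  Between steps the returned arrays
    hold the last state (zero-order hold), so the output stays on the
    trace's own time grid.
    """
    if plateau_temp is None:
        plateau_temp = (
            trace.protocol.plateau_temp if trace.protocol is not None else 45.0
        )
    u = np.asarray(trace.temp, dtype=float) - plateau_temp
    n = len(u)
    trace_rate = 1.0 / trace.dt
    m = max(1, int(round(trace_rate / params.step_rate_hz)))
    pre = np.isin(np.asarray(trace.phase), ("baseline", "ramp_up"))
    start = int(pre.sum()) if pre.any() else 0
    if start >= n:
        raise InputError("trace has no samples at or beyond the plateau")
    state = initial_state(params, u[start])
    tonic = np.full(n, state.tonic)
    phasic = np.full(n, state.phasic)
    gains = np.zeros((n, 2))
    innov = np.zeros(n)
    r_hats = np.full(n, state.r_hat)
    for k in range(start, n, m):
        try:
            state = kf_predict(state, params)
            state, e, K = kf_update(state, u[k], params)
        except NumericalError as err:
            raise NumericalError(f"filter failed at step {k}: {err}") from err
        stop = min(k + m, n)
        tonic[k:stop] = state.tonic
        phasic[k:stop] = state.phasic
        gains[k:stop] = K
        innov[k:stop] = e
        r_hats[k:stop] = state.r_hat
    return FilterTrace(
        time=np.asarray(trace.time, dtype=float),
        tonic_mean=tonic,
        phasic_mean=phasic,
        gain=gains,
        innovation=innov,
        r_hat=r_hats,
        input_u=u,
        params=params,
    )


def phasic_at_ratings(ftrace: FilterTrace, schedule: RatingSchedule) -> np.ndarray:
    """Window-mean phasic pain estimate at the R0-R3 rating times."""
    return aggregate_at_schedule(ftrace.time, ftrace.phasic_mean, schedule)


# ---------------------------------------------------------------------
# independent verification tools
# ---------------------------------------------------------------------

def steady_state_covariance(
    params: BayesParams, tol: float = 1e-12, max_iter: int = 200_000
) -> np.ndarray:
    """Fixed point of the predicted-covariance Riccati recursion.

    Iterates P <- F[(I - KH) P]F' + Q with K computed from fixed
    observation variance ``r_obs0`` until convergence.  Used as an
    independent target for the filter's converged covariance.
    """
    F, Q, H, r = params.F, params.Q, _H, params.r_obs0
    P = np.eye(2)
    for _ in range(max_iter):
        s = float(H @ P @ H + r)
        K = P @ H / s
        P_post = (np.eye(2) - np.outer(K, H)) @ P
        P_next = F @ P_post @ F.T + Q
        if np.abs(P_next - P).max() < tol:
            return P_next
        P = P_next
    raise NumericalError("Riccati iteration did not converge")


def grid_bayes_oracle(
    observations: Sequence[float],
    params: BayesParams,
    prior_mean: Optional[np.ndarray] = None,
    prior_var: Optional[np.ndarray] = None,
    grid_half_width: float = 3.0,
    grid_step: float = 0.02,
) -> np.ndarray:
    """Brute-force recursive Bayes on a dense (tonic, phasic) grid.

    Represents the joint posterior as a 2-D histogram, propagates it
    with discretized Gaussian transition kernels and multiplies by the
    Gaussian likelihood of each observation; returns the (n, 2) array of
    posterior means per step.  Only valid with ``beta_adapt = 0`` (the
    observation variance must stay fixed) and on short sequences.
    """
    if params.beta_adapt != 0:
        raise ConfigurationError("grid oracle requires beta_adapt = 0")
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 1 or len(obs) == 0:
        raise InputError("observations must be a non-empty 1-D sequence")
    if len(obs) > 50:
        raise InputError("grid oracle is restricted to sequences of <= 50 steps")
    sd_t = np.sqrt(params.q_tonic)
    sd_p = np.sqrt(params.q_phasic)
    min_sd = min(sd for sd in (sd_t, sd_p, np.sqrt(params.r_obs0)) if sd > 0)
    if grid_step > min_sd:
        raise OracleResolutionError(
            f"grid step {grid_step} is coarser than the smallest kernel SD "
            f"({min_sd:.4f}); refine the grid"
        )
    x = np.arange(-grid_half_width, grid_half_width + grid_step / 2, grid_step)
    if prior_mean is None:
        prior_mean = np.zeros(2)
    if prior_var is None:
        prior_var = np.array([params.prior_var_tonic, params.prior_var_phasic])
    prior_mean = np.asarray(prior_mean, dtype=float)
    prior_var = np.asarray(prior_var, dtype=float)

    def gauss(z: np.ndarray, var: float) -> np.ndarray:
        return np.exp(-0.5 * z * z / var)

    # independent Gaussian prior over the grid
    post = np.outer(
        gauss(x - prior_mean[0], prior_var[0]),
        gauss(x - prior_mean[1], prior_var[1]),
    )
    post /= post.sum()

    # transition kernels: columns are distributions over the new state
    # given each old grid state
    Kt = gauss(x[:, None] - x[None, :], params.q_tonic) if sd_t > 0 else np.eye(len(x))
    Kp = gauss(
        x[:, None] - params.phasic_decay * x[None, :], params.q_phasic
    ) if sd_p > 0 else None
    if Kp is None:
        # deterministic decay: nearest-grid-point mapping
        Kp = np.zeros((len(x), len(x)))
        idx = np.argmin(np.abs(x[:, None] - params.phasic_decay * x[None, :]), axis=0)
        Kp[idx, np.arange(len(x))] = 1.0
    Kt = Kt / Kt.sum(axis=0, keepdims=True)
    Kp = Kp / Kp.sum(axis=0, keepdims=True)

    means = np.empty((len(obs), 2))
    for k, y in enumerate(obs):
        post = Kt @ post @ Kp.T               # predict
        lik = gauss(y - (x[:, None] + x[None, :]), params.r_obs0)
        post = post * lik                     # update
        total = post.sum()
        if total <= 0 or not np.isfinite(total):
            raise OracleResolutionError(
                f"posterior mass vanished at step {k}; widen or refine the grid"
            )
        post /= total
        means[k, 0] = float((post.sum(axis=1) * x).sum())
        means[k, 1] = float((post.sum(axis=0) * x).sum())
        edge = post[0, :].sum() + post[-1, :].sum() + post[:, 0].sum() + post[:, -1].sum()
        if edge > 1e-5:
            raise OracleResolutionError(
                f"posterior mass reached the grid edge at step {k}; widen the grid"
            )
    return means
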