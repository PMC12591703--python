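"""Window-mean aggregation of simulated signals at rating times.

Ratings probe the preceding stretch of experience, so every model signal
is summarized as the mean over a window of length ``window_s`` ending at
the rating (beep) time.  A zero-length window degenerates to the single
sample nearest the rating time.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .stimulus import RatingSchedule

__all__ = ["window_mean", "aggregate_at_schedule", "RATING_LABELS"]

RATING_LABELS = ("R0", "R1", "R2", "R3")


def window_mean(
    time: np.ndarray, values: np.ndarray, end_time: float, window_s: float
) -> float:
    """Mean of ``values`` over the window ``[end_time - window_s, end_time]``.

    Sample times are matched with half-sample tolerance so that rating
    times falling exactly on grid points behave predictably.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    dt = time[1] - time[0] if len(time) > 1 else 0.0
    tol = dt / 2
    if end_time - window_s < time[0] - tol or end_time > time[-1] + tol:
        raise InputError(
            f"aggregation window [{end_time - window_s:.3f}, {end_time:.3f}] "
            f"extends outside the trace span [{time[0]:.3f}, {time[-1]:.3f}]"
        )
    if window_s == 0:
        return float(values[np.argmin(np.abs(time - end_time))])
    mask = (time >= end_time - window_s - tol) & (time <= end_time + tol)
    return float(values[mask].mean())


def aggregate_at_schedule(
    time: np.ndarray, values: np.ndarray, schedule: RatingSchedule
) -> np.ndarray:
    """Window means at the R0, R1, R2, R3 rating times (in that order)."""
    return np.array(
        [
            window_mean(time, values, t, schedule.window_s)
            for t in schedule.rating_times.values()
        ]
    )
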