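"""Synthetic experimental design and rating data.

The study design being emulated: each participant completes 2
familiarization trials with the constant 45 °C stimulus, followed by 8
test trials — 4 conventional OA stimuli and 2 presentations each of the
two noise OA sequences.  The first test trial is always conventional;
the remaining 7 are presented in a seeded random order.  Pain is rated
at four beeps per trial (R0 during T2; R1/R2/R3 at 5/10/15 s into T3).

Synthetic ratings come from a generative observer: a chosen pain model
(Bayesian filter or deterministic dynamics) is run on each stimulus,
its output aggregated at the rating times and mapped to the VAS through
the affine link (anchor 50 at zero drive).  Participant heterogeneity
is an intercept drawn once per participant; report noise is i.i.d.
Gaussian per rating; ratings are clipped to [0, 100] after noise is
added.  This mirrors exactly the structure the random-intercept LMEM
assumes, so the generator doubles as a ground-truth machine for
statistical calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .aggregate import RATING_LABELS
from .bayesian import BayesParams, phasic_at_ratings, run_filter
from .comparison import LinearLink, predict_vas
from .deterministic import DynParams, aggregate_at_ratings, simulate_dynamic
from .errors import ConfigurationError, InputError
from .stimulus import (
    NoiseSpec,
    Protocol,
    RatingSchedule,
    StimulusTrace,
    build_constant,
    build_conventional,
    build_noise,
    noise_spec_for_sequence,
    rating_schedule,
)

__all__ = [
    "DesignSpec",
    "ObserverSpec",
    "generate_design",
    "build_condition_traces",
    "observer_aggregates",
    "generate_ratings",
    "write_fixture",
    "read_fixture",
]


@dataclass(frozen=True)
class DesignSpec:
    """Trial structure of the experiment (defaults: the study design)."""

    n_participants: int = 22
    n_familiarization: int = 2
    n_test: int = 8
    n_conventional: int = 4
    n_seq1: int = 2
    n_seq2: int = 2
    first_trial_conventional: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("need at least one participant")
        if self.n_conventional + self.n_seq1 + self.n_seq2 != self.n_test:
            raise ConfigurationError(
                "n_conventional + n_seq1 + n_seq2 must equal n_test"
            )
        if self.first_trial_conventional and self.n_conventional < 1:
            raise ConfigurationError(
                "first_trial_conventional requires at least one conventional trial"
            )


@dataclass(frozen=True)
class ObserverSpec:
    """Generative observer for synthetic ratings.

    ``generator`` selects which pain model produces the underlying
    rating pattern; noise SDs are in VAS units.
    """

    generator: str = "bayesian"
    bayes_params: BayesParams = field(default_factory=BayesParams)
    dyn_params: DynParams = field(default_factory=DynParams)
    link: LinearLink = field(default_factory=LinearLink)
    report_noise_sd: float = 10.0
    participant_intercept_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator not in ("bayesian", "deterministic"):
            raise ConfigurationError(f"unknown generator {self.generator!r}")
        if self.report_noise_sd < 0 or self.participant_intercept_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Per-participant trial list: familiarization then ordered test trials.

    Trial order is drawn independently per participant from a generator
    seeded by ``spec.seed``; the same spec always yields the same design.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for part in range(1, spec.n_participants + 1):
        trial = 1
        for _ in range(spec.n_familiarization):
            rows.append((part, trial, "constant", True))
            trial += 1
        pool = (
            ["conventional"] * spec.n_conventional
            + ["noise_seq1"] * spec.n_seq1
            + ["noise_seq2"] * spec.n_seq2
        )
        if spec.first_trial_conventional:
            pool.remove("conventional")
            order = ["conventional"] + list(rng.permutation(pool))
        else:
            order = list(rng.permutation(pool))
        for cond in order:
            rows.append((part, trial, cond, False))
            trial += 1
    return pd.DataFrame(
        rows, columns=["participant", "trial", "condition", "familiarization"]
    )


def build_condition_traces(
    protocol: Optional[Protocol] = None,
    noise_seq1: Optional[NoiseSpec] = None,
    noise_seq2: Optional[NoiseSpec] = None,
) -> dict[str, StimulusTrace]:
    """The four stimulus traces of the paradigm, keyed by condition."""
    protocol = protocol or Protocol()
    noise_seq1 = noise_seq1 or noise_spec_for_sequence(1)
    noise_seq2 = noise_seq2 or noise_spec_for_sequence(2)
    return {
        "constant": build_constant(protocol),
        "conventional": build_conventional(protocol),
        "noise_seq1": build_noise(protocol, noise_seq1, condition="noise_seq1"),
        "noise_seq2": build_noise(protocol, noise_seq2, condition="noise_seq2"),
    }


def observer_aggregates(
    observer: ObserverSpec,
    traces: Mapping[str, StimulusTrace],
    schedule: RatingSchedule,
) -> dict[str, np.ndarray]:
    """Noise-free VAS pattern of the observer per condition at R0-R3."""
    out: dict[str, np.ndarray] = {}
    for cond, trace in traces.items():
        if observer.generator == "bayesian":
            agg = phasic_at_ratings(run_filter(trace, observer.bayes_params), schedule)
        else:
            agg = aggregate_at_ratings(
                simulate_dynamic(trace, observer.dyn_params), schedule
            )
        out[cond] = predict_vas(agg, observer.link)
    return out


def generate_ratings(
    design: pd.DataFrame,
    observer: ObserverSpec,
    protocol: Optional[Protocol] = None,
    noise_seq1: Optional[NoiseSpec] = None,
    noise_seq2: Optional[NoiseSpec] = None,
    window_s: float = 1.0,
) -> pd.DataFrame:
    """Synthetic long-format rating table for a generated design.

    One row per (participant, trial, rating timing); the ``vas`` column
    holds the clipped noisy report, ``vas_true`` the observer's
    noise-free prediction.
    """
    protocol = protocol or Protocol()
    schedule = rating_schedule(protocol, window_s=window_s)
    traces = build_condition_traces(protocol, noise_seq1, noise_seq2)
    patterns = observer_aggregates(observer, traces, schedule)
    rng = np.random.default_rng(observer.seed)
    participants = np.unique(design["participant"])
    intercepts = dict(
        zip(
            participants,
            rng.normal(0.0, observer.participant_intercept_sd, len(participants)),
        )
    )
    rows = []
    for rec in design.itertuples(index=False):
        pattern = patterns[rec.condition]
        noise = rng.normal(0.0, observer.report_noise_sd, len(RATING_LABELS))
        for j, timing in enumerate(RATING_LABELS):
            true = float(pattern[j])
            vas = float(
                np.clip(true + intercepts[rec.participant] + noise[j], 0.0, 100.0)
            )
            rows.append(
                (
                    rec.participant,
                    rec.trial,
                    rec.condition,
                    bool(rec.familiarization),
                    timing,
                    vas,
                    true,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "trial", "condition", "familiarization",
            "timing", "vas", "vas_true",
        ],
    )


def write_fixture(table: pd.DataFrame, path: str | Path) -> None:
    """Write a rating table as canonical CSV (sorted, lossless floats)."""
    required = {"participant", "trial", "timing"}
    if not required.issubset(table.columns):
        raise InputError(f"rating table must contain columns {sorted(required)}")
    out = table.sort_values(["participant", "trial", "timing"], kind="stable")
    out.to_csv(path, index=False)


def read_fixture(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
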