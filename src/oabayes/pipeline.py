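"""End-to-end orchestration: generate, simulate, fit, compare, report.

A single :class:`RunConfig` (buildable from YAML) drives the whole
analysis: stimulus construction, both pain-model simulations, synthetic
rating generation, the two mixed-model analyses and the regression
model comparison.  All stage artifacts are written as CSV/JSON under an
output directory together with a machine-readable ``report.json``.  The
master seed deterministically derives the per-stage seeds, so an
identical config always produces a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .bayesian import BayesParams, run_filter
from .comparison import LinearLink, compare_models
from .deterministic import DynParams, simulate_dynamic
from .errors import ConfigurationError
from .lmem import code_factors, fit_random_intercept, sequence_view, t3_view
from .stimulus import Protocol, noise_spec_for_sequence, rating_schedule
from .synth import (
    DesignSpec,
    ObserverSpec,
    build_condition_traces,
    generate_design,
    generate_ratings,
    write_fixture,
)

__all__ = ["RunConfig", "run_all", "stage_seeds"]

logger = logging.getLogger("oabayes.pipeline")

STIMULUS_TERMS = ["timing_code", "stimulus_code", "timing_code:stimulus_code"]
SEQUENCE_TERMS = ["timing_code", "sequence_code", "timing_code:sequence_code"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run depends on."""

    protocol: Protocol = field(default_factory=Protocol)
    dyn_params: DynParams = field(default_factory=DynParams)
    bayes_params: BayesParams = field(default_factory=BayesParams)
    design: DesignSpec = field(default_factory=DesignSpec)
    observer: ObserverSpec = field(default_factory=ObserverSpec)
    link: LinearLink = field(default_factory=LinearLink)
    window_s: float = 1.0
    run_lmem_stimulus: bool = True
    run_lmem_sequence: bool = True
    run_comparison: bool = True
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {
            "protocol": Protocol,
            "dyn_params": DynParams,
            "bayes_params": BayesParams,
            "design": DesignSpec,
            "observer": ObserverSpec,
            "link": LinearLink,
        }
        kwargs: dict = {}
        for key, val in raw.items():
            if key in sections:
                if key == "observer":
                    val = dict(val)
                    if "bayes_params" in val:
                        val["bayes_params"] = BayesParams(**val["bayes_params"])
                    if "dyn_params" in val:
                        val["dyn_params"] = DynParams(**val["dyn_params"])
                    if "link" in val:
                        val["link"] = LinearLink(**val["link"])
                kwargs[key] = sections[key](**val)
            elif key in (
                "window_s", "run_lmem_stimulus", "run_lmem_sequence",
                "run_comparison", "master_seed",
            ):
                kwargs[key] = val
            else:
                raise ConfigurationError(f"unknown config key {key!r}")
        return cls(**kwargs)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(2)
    return {
        "design": int(state[0] % (2**31)),
        "observer": int(state[1] % (2**31)),
    }


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(_to_jsonable(payload), indent=2, sort_keys=True) + "\n")


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every enabled stage; return the report dict (also written).

    Stage order: stimulus traces -> model simulations -> synthetic
    design and ratings -> LMEM analyses -> model comparison -> report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.master_seed)
    report: dict = {"master_seed": config.master_seed, "stage_seeds": seeds}
    report["config"] = _to_jsonable(config)

    t0 = _time.perf_counter()
    schedule = rating_schedule(config.protocol, window_s=config.window_s)
    traces = build_condition_traces(config.protocol)
    for cond, trace in traces.items():
        trace.to_csv(out / f"trace_{cond}.csv")
    logger.info("stimulus stage done (%.2f s)", _time.perf_counter() - t0)

    t0 = _time.perf_counter()
    for cond in ("conventional", "noise_seq1", "noise_seq2"):
        simulate_dynamic(traces[cond], config.dyn_params).to_frame().to_csv(
            out / f"dyn_{cond}.csv", index=False
        )
        run_filter(traces[cond], config.bayes_params).to_frame().to_csv(
            out / f"filter_{cond}.csv", index=False
        )
    logger.info("simulation stage done (%.2f s)", _time.perf_counter() - t0)

    t0 = _time.perf_counter()
    design_spec = replace(config.design, seed=seeds["design"])
    observer_spec = replace(
        config.observer,
        seed=seeds["observer"],
        bayes_params=config.bayes_params,
        dyn_params=config.dyn_params,
        link=config.link,
    )
    design = generate_design(design_spec)
    ratings = generate_ratings(
        design, observer_spec, protocol=config.protocol, window_s=config.window_s
    )
    write_fixture(ratings, out / "ratings.csv")
    _write_json(
        {"design": design.to_dict(orient="records")}, out / "design.json"
    )
    report["n_ratings"] = int(len(ratings))
    logger.info("synthetic-data stage done (%.2f s)", _time.perf_counter() - t0)

    coded = code_factors(ratings)
    if config.run_lmem_stimulus:
        t0 = _time.perf_counter()
        fit = fit_random_intercept(t3_view(coded), STIMULUS_TERMS)
        _write_json(fit.to_dict(), out / "lmem_stimulus.json")
        report["lmem_stimulus"] = fit.to_dict()
        logger.info("lmem stimulus stage done (%.2f s)", _time.perf_counter() - t0)
    if config.run_lmem_sequence:
        t0 = _time.perf_counter()
        fit = fit_random_intercept(sequence_view(coded), SEQUENCE_TERMS)
        _write_json(fit.to_dict(), out / "lmem_sequence.json")
        report["lmem_sequence"] = fit.to_dict()
        logger.info("lmem sequence stage done (%.2f s)", _time.perf_counter() - t0)
    if config.run_comparison:
        t0 = _time.perf_counter()
        test_rows = ratings[~ratings["familiarization"]]
        cmp = compare_models(
            test_rows,
            {c: traces[c] for c in ("conventional", "noise_seq1", "noise_seq2")},
            config.dyn_params,
            config.bayes_params,
            schedule,
        )
        _write_json(cmp.to_dict(), out / "comparison.json")
        report["comparison"] = cmp.to_dict()
        logger.info("comparison stage done (%.2f s)", _time.perf_counter() - t0)

    _write_json(report, out / "report.json")
    return report
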