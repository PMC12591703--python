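import numpy as np
import pytest

import oabayes as oa


@pytest.fixture(scope="session")
def protocol():
    return oa.Protocol()


@pytest.fixture(scope="session")
def schedule(protocol):
    return oa.rating_schedule(protocol)


@pytest.fixture(scope="session")
def traces(protocol):
    """The four stimulus conditions on the default protocol."""
    return oa.build_condition_traces(protocol)


@pytest.fixture(scope="session")
def dyn_aggregates(traces, schedule):
    """Deterministic-model rating aggregates per condition, default params."""
    params = oa.DynParams()
    return {
        cond: oa.aggregate_at_ratings(oa.simulate_dynamic(tr, params), schedule)
        for cond, tr in traces.items()
    }


@pytest.fixture(scope="session")
def bayes_aggregates(traces, schedule):
    """Bayesian-model phasic aggregates per condition, default params."""
    params = oa.BayesParams()
    return {
        cond: oa.phasic_at_ratings(oa.run_filter(tr, params), schedule)
        for cond, tr in traces.items()
    }


def make_trace(time, temp, phase="T3", condition="constant"):
    """Hand-built trace for unit tests."""
    time = np.asarray(time, dtype=float)
    temp = np.asarray(temp, dtype=float)
    phases = np.full(len(time), phase, dtype=object)
    return oa.StimulusTrace(time, temp, phases, condition=condition)
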