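import math

import numpy as np
import pytest

from coxbf import (
    SimulationSpec,
    SurvivalData,
    rescale_min_time,
    simulate_survival,
)


@pytest.fixture
def toy_distinct():
    """Six subjects, all event times distinct, both groups."""
    return SurvivalData(
        times=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        events=np.array([1, 0, 1, 1, 0, 1]),
        groups=np.array([0, 1, 0, 1, 0, 1]),
    )


@pytest.fixture
def toy_tied():
    """Six subjects with one tied event pair (at t=2)."""
    return SurvivalData(
        times=np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0]),
        events=np.array([1, 1, 1, 0, 1, 0]),
        groups=np.array([0, 1, 0, 1, 0, 1]),
    )


@pytest.fixture
def medium_data():
    """Simulated two-group dataset with a moderate effect and censoring."""
    spec = SimulationSpec(n_control=50, n_experimental=50, beta_true=0.5,
                          baseline_rate=1.0, censor_rate=0.4, seed=20240317)
    return simulate_survival(spec)


@pytest.fixture
def reconstruction_source():
    """A small reconstruction source on the [1, tmax] time scale."""
    spec = SimulationSpec(n_control=30, n_experimental=30, beta_true=0.5,
                          baseline_rate=1.0, censor_rate=0.4, seed=7)
    return rescale_min_time(simulate_survival(spec))


def ref_efron_loglik(times, events, groups, beta):
    """Independent term-by-term evaluation of Efron's log partial likelihood.

    Plain-loop oracle: for each distinct event time with d tied events, the
    denominator at tie position l subtracts the fraction l/d of the tied
    subjects' risk contributions.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        tied = [i for i in range(len(times))
                if times[i] == t and events[i] == 1]
        at_risk = [i for i in range(len(times)) if times[i] >= t]
        d = len(tied)
        s_tied = sum(math.exp(beta * groups[i]) for i in tied)
        s_risk = sum(math.exp(beta * groups[i]) for i in at_risk)
        ll += beta * sum(groups[i] for i in tied)
        for l in range(d):
            ll -= math.log(s_risk - (l / d) * s_tied)
    return ll


def ref_exact_cox_loglik(times, events, groups, beta):
    """Exact Cox log partial likelihood, valid when event times are distinct."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = sum(math.exp(beta * groups[j]) for j in range(len(times))
                   if times[j] >= times[i])
        ll += beta * groups[i] - math.log(risk)
    return ll
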