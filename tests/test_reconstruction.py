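"""Tests for summary-statistics reconstruction and its PSO driver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coxbf import (
    InvalidDataError,
    LossSpec,
    PriorSpec,
    SummaryStats,
    bayes_factor_full,
    compute_observed_stats,
    default_loss_spec,
    fit_cox,
    initialize_dataset,
    km_summary,
    loss,
    reconstruct,
    summary_stats_from_data,
    weight_sweep,
)
from coxbf.reconstruction import _phi

PRIOR = PriorSpec(0.0, 1.0, "two_sided")


# ---------------------------------------------------------------------------
# SummaryStats / LossSpec contracts
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    {"nc": 2, "ne": 2, "vc": 3, "ve": 1, "hr": 1.2},        # vc > nc
    {"nc": 2, "ne": 2, "vc": 1, "ve": 3, "hr": 1.2},        # ve > ne
    {"nc": 2, "ne": 2, "vc": 1, "ve": 1},                   # nothing to match
    {"nc": 2, "ne": 2, "vc": 1, "ve": 1, "hr": 1.2,
     "hr_ci_lower": 1.3, "hr_ci_upper": 1.5},               # CI excludes HR
    {"nc": 0, "ne": 2, "vc": 0, "ve": 1, "hr": 1.2},        # empty group
])
def test_summary_stats_rejects_invalid(kwargs):
    with pytest.raises(InvalidDataError):
        SummaryStats(**kwargs)


@pytest.mark.parametrize("kwargs", [
    {"targets": ("hr",), "weights": (1.0, 2.0)},       # misaligned
    {"targets": ("nonsense",), "weights": (1.0,)},     # unknown target
    {"targets": ("hr",), "weights": (0.0,)},           # no positive weight
    {"targets": (), "weights": ()},                    # empty
])
def test_loss_spec_rejects_invalid(kwargs):
    with pytest.raises(InvalidDataError):
        LossSpec(**kwargs)


def test_default_loss_spec_is_recommended_configuration():
    spec = default_loss_spec()
    assert spec.targets == ("hr", "hr_ci_lower", "hr_ci_upper")
    assert spec.weights == (2.0, 1.0, 1.0)
    assert not spec.uses_km


# ---------------------------------------------------------------------------
# initialize_dataset
# ---------------------------------------------------------------------------

def test_initial_block_structure():
    stats = SummaryStats(nc=2, ne=2, vc=1, ve=1, hr=1.2, tmax=100.0)
    data = initialize_dataset(stats, rng_seed=0)
    assert list(data.events) == [0, 1, 0, 1]
    assert list(data.groups) == [0, 0, 1, 1]
    assert np.all((1.0 <= data.times) & (data.times <= 100.0))


def test_initial_no_events_when_counts_zero():
    stats = SummaryStats(nc=3, ne=3, vc=0, ve=0, hr=1.2)
    data = initialize_dataset(stats, rng_seed=1)
    assert data.events.sum() == 0


def test_initialization_is_deterministic():
    stats = SummaryStats(nc=5, ne=5, vc=3, ve=4, hr=1.2, tmax=50.0)
    a = initialize_dataset(stats, rng_seed=99)
    b = initialize_dataset(stats, rng_seed=99)
    assert np.array_equal(a.times, b.times)
    assert not np.array_equal(a.times, initialize_dataset(stats, 100).times)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def test_loss_hand_example():
    # E = (1.312, 1.136, 1.514), O = (1.5, 1.0, 1.6), w = (2, 1, 1):
    # term-by-term, the squared weighted relative deviations are
    # (0.188/1.312*2)^2, (0.136/1.136)^2, (0.086/1.514)^2
    O = np.array([1.5, 1.0, 1.6])
    E = np.array([1.312, 1.136, 1.514])
    w = np.array([2.0, 1.0, 1.0])
    terms = ((O - E) / E * w) ** 2
    expected = math.log(terms.mean())
    assert expected == pytest.approx(-3.404, abs=5e-4)
    assert _phi(O, E, w, 1e-300) == pytest.approx(expected, rel=1e-12)


def test_perfect_match_is_floored():
    E = np.array([1.312, 1.136, 1.514])
    w = np.array([2.0, 1.0, 1.0])
    assert _phi(E.copy(), E, w, 1e-300) == pytest.approx(math.log(1e-300))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(factor=st.floats(0.1, 10.0))
def test_uniform_weight_scaling_shifts_phi_by_log_square(factor):
    O = np.array([1.5, 1.0, 1.6])
    E = np.array([1.312, 1.136, 1.514])
    w = np.array([2.0, 1.0, 1.0])
    base = _phi(O, E, w, 1e-300)
    shifted = _phi(O, E, w * factor, 1e-300)
    assert shifted == pytest.approx(base + 2 * math.log(factor), abs=1e-9)


def test_loss_at_zero_xi_matches_base_statistics(reconstruction_source):
    stats = summary_stats_from_data(reconstruction_source)
    # use the source itself as the base: xi = 0 reproduces it exactly
    spec = default_loss_spec()
    phi0 = loss(np.zeros(reconstruction_source.n), reconstruction_source,
                stats, spec)
    assert phi0 == pytest.approx(math.log(spec.epsilon_floor), rel=1e-6)


def test_loss_rejects_out_of_bounds_xi(reconstruction_source):
    stats = summary_stats_from_data(reconstruction_source)
    xi = np.zeros(reconstruction_source.n)
    xi[0] = math.log(2000.0)  # beyond log(tmax / Y_0) for default tmax
    with pytest.raises(InvalidDataError):
        loss(xi, reconstruction_source, stats, default_loss_spec())


# ---------------------------------------------------------------------------
# compute_observed_stats
# ---------------------------------------------------------------------------

def test_observed_stats_on_symmetric_data():
    times = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
    events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
    groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    from coxbf import SurvivalData
    data = SurvivalData(times, events, groups)
    O = compute_observed_stats(data, LossSpec(("hr",), (1.0,)))
    assert O[0] == pytest.approx(1.0, abs=1e-8)


def test_observed_stats_delegate_to_fit_and_km(reconstruction_source):
    data = reconstruction_source
    spec = LossSpec(("hr", "hr_ci_lower", "hr_ci_upper", "km_c"),
                    (1.0, 1.0, 1.0, 1.0))
    O = compute_observed_stats(data, spec)
    fit = fit_cox(data)
    assert O[0] == fit.hr and O[1] == fit.ci_lower and O[2] == fit.ci_upper
    mask = data.groups == 0
    km = km_summary(data.times[mask], data.events[mask])
    assert O[3] == km.median


# ---------------------------------------------------------------------------
# reconstruct (shared small run)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_reconstruction(reconstruction_source):
    source = reconstruction_source
    stats = summary_stats_from_data(source)
    result = reconstruct(stats, n_datasets=6, max_iter=150, prior=PRIOR,
                         rng_seed=123)
    return source, stats, result


@pytest.fixture(scope="module")
def reconstruction_source():
    # module-scoped shadow of the function-scoped conftest fixture so the
    # shared reconstruction run can reuse it
    from coxbf import SimulationSpec, rescale_min_time, simulate_survival
    spec = SimulationSpec(n_control=30, n_experimental=30, beta_true=0.5,
                          baseline_rate=1.0, censor_rate=0.4, seed=7)
    return rescale_min_time(simulate_survival(spec))


def test_counts_and_bounds_preserved(small_reconstruction):
    _, stats, result = small_reconstruction
    tmax = 1000.0  # default when stats.tmax is undefined
    for ds in result.datasets:
        ctrl = ds.groups == 0
        assert int(ctrl.sum()) == stats.nc
        assert int((~ctrl).sum()) == stats.ne
        assert int(ds.events[ctrl].sum()) == stats.vc
        assert int(ds.events[~ctrl].sum()) == stats.ve
        assert np.all((1.0 - 1e-9 <= ds.times) & (ds.times <= tmax + 1e-9))


def test_loss_traces_nonincreasing(small_reconstruction):
    _, _, result = small_reconstruction
    for trace in result.loss_traces:
        assert np.all(np.diff(trace) <= 1e-12)


def test_optimum_not_worse_than_zero_xi_start(small_reconstruction):
    """xi = 0 is seeded into the swarm, so the returned loss can never
    exceed the loss of the raw uniform draw."""
    _, stats, result = small_reconstruction
    spec = default_loss_spec()
    for rep, (floss, _) in enumerate(zip(result.losses, result.datasets)):
        base = initialize_dataset(stats, result.seed + rep)
        assert floss <= loss(np.zeros(base.n), base, stats, spec) + 1e-12


def test_reconstructed_hr_matches_target(small_reconstruction):
    _, stats, result = small_reconstruction
    rel_err = np.array([abs(fit_cox(ds).hr - stats.hr) / stats.hr
                        for ds in result.datasets])
    assert np.mean(rel_err <= 0.01) >= 0.9


def test_reconstructed_bf_near_full_data_bf(small_reconstruction):
    source, _, result = small_reconstruction
    full = bayes_factor_full(source, PRIOR).log_bf10
    errors = np.abs(result.log_bf_values - full)
    assert np.median(errors) <= 0.05


def test_reconstruction_is_deterministic(small_reconstruction):
    _, stats, result = small_reconstruction
    again = reconstruct(stats, n_datasets=1, max_iter=150, prior=PRIOR,
                        rng_seed=123)
    assert np.array_equal(again.datasets[0].times, result.datasets[0].times)
    assert again.losses[0] == result.losses[0]
    assert again.bf_distribution[0].bf10 == result.bf_distribution[0].bf10


def test_iterations_respect_stopping_rule(small_reconstruction):
    _, _, result = small_reconstruction
    assert np.all(result.iterations_used <= 150)
    # the trace has one entry per completed iteration plus the start
    for used, trace in zip(result.iterations_used, result.loss_traces):
        assert len(trace) == used + 1


def test_reconstruct_requires_targeted_statistics():
    stats = SummaryStats(nc=5, ne=5, vc=3, ve=3, hr=1.3)  # no CI given
    with pytest.raises(InvalidDataError):
        reconstruct(stats, n_datasets=1, spec=default_loss_spec(),
                    max_iter=10, rng_seed=0)


def test_km_targets_require_tmax(reconstruction_source):
    stats = summary_stats_from_data(reconstruction_source, include_km=True)
    stats = SummaryStats(**{**stats.__dict__, "tmax": None})
    spec = LossSpec(("hr", "km_c"), (1.0, 1.0))
    with pytest.raises(InvalidDataError):
        reconstruct(stats, n_datasets=1, spec=spec, max_iter=10, rng_seed=0)


# ---------------------------------------------------------------------------
# weight_sweep
# ---------------------------------------------------------------------------

def test_weight_sweep_schema_and_pairing(reconstruction_source):
    sets = [LossSpec(("hr", "hr_ci_lower", "hr_ci_upper"), (2, 1, 1)),
            LossSpec(("hr",), (1,))]
    table = weight_sweep(reconstruction_source, sets, n_reps=2, prior=PRIOR,
                         rng_seed=5, max_iter=30)
    assert list(table["targets"]) == ["hr,hr_ci_lower,hr_ci_upper", "hr"]
    assert {"bias", "variance", "log_bf_full", "n_flagged"} <= set(table)
    assert table["log_bf_full"].nunique() == 1
    assert np.isfinite(table["bias"]).all()


def test_weight_sweep_rejects_single_rep(reconstruction_source):
    with pytest.raises(InvalidDataError):
        weight_sweep(reconstruction_source, [default_loss_spec()], n_reps=1)


def test_summary_stats_round_trip(reconstruction_source):
    stats = summary_stats_from_data(reconstruction_source, include_km=True)
    fit = fit_cox(reconstruction_source)
    assert stats.hr == fit.hr
    assert stats.hr_ci_lower == fit.ci_lower
    assert stats.nc + stats.ne == reconstruction_source.n
    assert stats.vc + stats.ve == reconstruction_source.n_events
    assert stats.tmax == reconstruction_source.times.max()
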