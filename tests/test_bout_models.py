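"""Duration distributions, discrete likelihoods, AIC weights, KS and ICDF."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nestmove.bout_models import (
    FAMILIES,
    DurationModel,
    compare_models,
    discrete_log_likelihood,
    fit,
    icdf,
    icdf_at,
    ks_statistic,
    model_cdf,
)
from nestmove.synthetic import sample_durations

GRID = 0.2


def _model(family, **kw):
    defaults = {
        "stretched_exponential": {"lam": 0.5, "beta": 0.7},
        "truncated_power_law": {"mu": 2.0},
        "exponential": {"rate": 1.0},
        "power_law": {"exponent": 2.0},
    }
    x_max = kw.pop("x_max", 100.0 if family == "truncated_power_law" else math.inf)
    params = {**defaults[family], **kw}
    return DurationModel(family, params, x_max=x_max)


@pytest.mark.parametrize("family", FAMILIES)
def test_cdf_is_zero_at_support_start(family):
    m = _model(family)
    assert model_cdf(m, m.x_min) == pytest.approx(0.0, abs=1e-12)


def test_truncated_power_law_cdf_reaches_one_at_xmax():
    m = _model("truncated_power_law", x_max=50.0)
    assert model_cdf(m, 50.0) == pytest.approx(1.0, abs=1e-12)


def test_stretched_exponential_with_beta_one_reduces_to_exponential():
    se = DurationModel("stretched_exponential", {"lam": 0.7, "beta": 1.0})
    ex = DurationModel("exponential", {"rate": 0.7})
    xs = np.arange(0.2, 20.0, 0.2)
    np.testing.assert_allclose(se.cdf(xs), ex.cdf(xs), atol=1e-12)
    data = sample_durations(ex, 500, seed=5)
    assert discrete_log_likelihood(se, data) == pytest.approx(
        discrete_log_likelihood(ex, data), abs=1e-9
    )


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        DurationModel("stretched_exponential", {"lam": 0.5, "beta": 1.4})
    with pytest.raises(ValueError):
        DurationModel("truncated_power_law", {"mu": 0.9}, x_max=10.0)
    with pytest.raises(ValueError):
        DurationModel("truncated_power_law", {"mu": 2.0})  # needs finite x_max
    with pytest.raises(ValueError):
        DurationModel("exponential", {"rate": -1.0})
    with pytest.raises(ValueError):
        DurationModel("unknown", {"rate": 1.0})


def test_single_duration_log_likelihood_matches_closed_form():
    # one bout of one frame under exponential(rate=1): log(1 - exp(-0.2))
    m = _model("exponential", rate=1.0)
    assert discrete_log_likelihood(m, [0.2]) == pytest.approx(
        math.log1p(-math.exp(-0.2)), abs=1e-12
    )


def test_bin_probabilities_sum_to_one_for_truncated_support():
    m = _model("truncated_power_law", mu=1.8, x_max=20.0)
    grid_vals = np.arange(m.x_min, 20.0, GRID)
    assert m.bin_probabilities(grid_vals).sum() == pytest.approx(1.0, abs=1e-9)


def test_log_likelihood_additivity_under_duplication():
    m = _model("stretched_exponential")
    data = sample_durations(m, 300, seed=3)
    once = discrete_log_likelihood(m, data)
    twice = discrete_log_likelihood(m, np.concatenate([data, data]))
    assert twice == pytest.approx(2 * once, rel=1e-12)


def test_off_grid_or_sub_xmin_durations_rejected():
    m = _model("exponential")
    with pytest.raises(ValueError):
        discrete_log_likelihood(m, [0.25])
    with pytest.raises(ValueError):
        discrete_log_likelihood(m, [0.0])


def test_aic_weights_symmetry_and_known_ratio():
    m = _model("exponential")
    data = sample_durations(m, 200, seed=1)
    base = fit(data, "exponential")
    equal = compare_models([base, base])
    assert [w.aic_weight for w in equal] == pytest.approx([0.5, 0.5])
    # delta AIC of 2 -> weights 1/(1+e^-1) and its complement
    from dataclasses import replace

    shifted = replace(base, aic=base.aic + 2.0)
    w = compare_models([base, shifted])
    assert w[0].aic_weight == pytest.approx(0.73106, abs=1e-4)
    assert w[1].aic_weight == pytest.approx(0.26894, abs=1e-4)
    three = compare_models([base, shifted, replace(base, aic=base.aic + 7)])
    assert sum(f.aic_weight for f in three) == pytest.approx(1.0, abs=1e-12)


def test_ks_statistic_vanishes_for_model_generated_data():
    m = _model("stretched_exponential")
    data = sample_durations(m, 10_000, seed=11)
    assert ks_statistic(m, data) < 0.02


def test_ks_statistic_one_for_disjoint_mass():
    # model concentrates (numerically) all mass in the first bin; data sit
    # at twice x_min, so the CDFs disagree maximally
    m = _model("exponential", rate=500.0)
    assert ks_statistic(m, [0.4, 0.4, 0.4]) == pytest.approx(1.0, abs=1e-6)


def test_ks_statistic_invariant_under_duplication():
    m = _model("truncated_power_law")
    data = sample_durations(m, 500, seed=2)
    assert ks_statistic(m, data) == pytest.approx(
        ks_statistic(m, np.concatenate([data, data])), abs=1e-12
    )


def test_icdf_counts_proportion_at_or_above():
    vals, prop = icdf([0.2, 0.2, 0.4])
    np.testing.assert_allclose(vals, [0.2, 0.4])
    np.testing.assert_allclose(prop, [1.0, 1.0 / 3.0])
    v1, p1 = icdf([1.4])
    assert p1[0] == 1.0
    assert icdf_at([0.2, 0.2, 0.4], 0.6) == 0.0  # beyond the maximum


@settings(deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=200), min_size=1, max_size=60))
def test_icdf_is_monotone_and_starts_at_one(frames):
    durations = GRID * np.asarray(frames)
    vals, prop = icdf(durations)
    assert prop[0] == pytest.approx(1.0)
    assert np.all(np.diff(prop) < 1e-12)
    assert np.all(np.diff(vals) > 0)


def test_exponential_data_fitted_as_stretched_gives_beta_near_one():
    data = sample_durations(_model("exponential", rate=1.0), 10_000, seed=4)
    res = fit(data, "stretched_exponential")
    assert res.model.params["beta"] >= 0.95


def test_fit_flags_single_valued_degenerate_data():
    res = fit(np.full(100, 0.2), "truncated_power_law")
    assert res.flagged
    # the collapsed support pins the shape parameter to the search bound
    assert res.model.params["mu"] == pytest.approx(50.0)


def test_fit_requires_minimum_sample_size():
    with pytest.raises(ValueError):
        fit(np.full(10, 0.4), "exponential", min_n=50)


def test_fit_is_deterministic():
    data = sample_durations(_model("stretched_exponential"), 2_000, seed=9)
    a = fit(data, "stretched_exponential")
    b = fit(data, "stretched_exponential")
    assert a.model.params == b.model.params
    assert a.log_likelihood == b.log_likelihood
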