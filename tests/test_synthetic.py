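"""Synthetic walker and cohort generator: determinism, support, structure."""

import numpy as np
import pytest

from nestmove.bout_models import DurationModel
from nestmove.io import ArenaGeometry
from nestmove.kinematics import compute_steps, estimate_threshold
from nestmove.synthetic import (
    CohortSpec,
    SpeciesSpec,
    WalkerParams,
    default_cohort_spec,
    generate_cohort,
    sample_durations,
    simulate_trajectory,
)

SE = lambda lam, beta: DurationModel("stretched_exponential", {"lam": lam, "beta": beta})


def _params(**kw):
    base = dict(
        pause_dist=SE(0.8, 0.8),
        move_dist=SE(0.5, 0.7),
        speed_mean=8.0,
        speed_sd=1.0,
        turn_sd=0.2,
        wall_zone=10.0,
        wall_bias=0.8,
    )
    base.update(kw)
    return WalkerParams(**base)


# ---------------------------------------------------------------- durations


def test_sample_durations_deterministic_and_on_grid():
    m = SE(0.5, 0.7)
    a = sample_durations(m, 1000, seed=3)
    b = sample_durations(m, 1000, seed=3)
    np.testing.assert_array_equal(a, b)
    k = np.round(a / 0.2)
    np.testing.assert_allclose(a, 0.2 * k, atol=1e-9)
    assert a.min() >= 0.2


def test_sample_durations_respects_truncated_support():
    m = DurationModel("truncated_power_law", {"mu": 2.0}, x_max=100.0)
    d = sample_durations(m, 5000, seed=1)
    assert d.min() >= 0.2 and d.max() <= 100.0


def test_sample_durations_empty_and_invalid():
    assert sample_durations(SE(0.5, 0.7), 0, seed=0).size == 0
    with pytest.raises(ValueError):
        sample_durations(SE(0.5, 0.7), -1, seed=0)


def test_sampler_mean_matches_discretized_exponential_expectation():
    # beta=1 stretched exponential is a shifted exponential; the expected
    # grid-discretized mean is computed from the survival function alone
    m = DurationModel("stretched_exponential", {"lam": 0.5, "beta": 1.0})
    d = sample_durations(m, 50_000, seed=21)
    ks = np.arange(1, 500)
    expected = 0.2 * float(np.sum(m.sf(0.2 * ks)))  # E[grid*floor(x/grid)]
    se = d.std(ddof=1) / np.sqrt(d.size)
    assert abs(d.mean() - expected) < 3 * se


@pytest.mark.parametrize("family,params,x_max", [
    ("stretched_exponential", {"lam": 0.5, "beta": 0.7}, np.inf),
    ("truncated_power_law", {"mu": 2.0}, 100.0),
    ("exponential", {"rate": 1.0}, np.inf),
])
def test_sampler_passes_ks_against_generating_cdf(family, params, x_max):
    # discrete one-sample KS with the continuous critical value (conservative
    # on a grid) at alpha = 0.01; 10 of 10 seeded replicates must pass
    m = DurationModel(family, params, x_max=x_max)
    crit = 1.628 / np.sqrt(10_000)
    passes = 0
    for seed in range(10):
        d = np.sort(sample_durations(m, 10_000, seed=100 + seed))
        grid = np.arange(0.2, d[-1] + 0.1, 0.2)
        ecdf = np.searchsorted(d, grid + 0.1) / d.size
        mcdf = 1.0 - m.sf(np.minimum(grid + 0.2, m.x_max))
        passes += np.max(np.abs(ecdf - mcdf)) < crit
    assert passes >= 9


# ---------------------------------------------------------------- walker


def test_simulation_is_seed_deterministic(arena):
    a = simulate_trajectory(_params(), arena, 120, 5, seed=5)
    b = simulate_trajectory(_params(), arena, 120, 5, seed=5)
    np.testing.assert_array_equal(a.positions, b.positions)


def test_stationary_walker_travels_nowhere(arena):
    p = _params(speed_mean=0.0, speed_sd=0.0, pause_step_scale=0.0)
    t = simulate_trajectory(p, arena, 60, 5, seed=1)
    assert np.all(t.positions == 0.0)


def test_full_wall_bias_keeps_walker_in_outer_region(arena):
    p = _params(wall_bias=1.0, wall_zone=12.0, speed_mean=9.0, turn_sd=0.15)
    t = simulate_trajectory(p, arena, 3600, 5, seed=2, start_xy=(69.5, 0.0))
    r = np.hypot(t.positions[:, 0], t.positions[:, 1])
    assert (r >= arena.inner_radius_mm).mean() > 0.9


@pytest.mark.parametrize("seed", [0, 1])
def test_walker_respects_arena_containment(arena, seed):
    t = simulate_trajectory(_params(wall_bias=0.3), arena, 600, 5, seed=seed)
    r = np.hypot(t.positions[:, 0], t.positions[:, 1])
    assert r.max() <= arena.radius_mm


def test_invalid_simulation_inputs_rejected(arena):
    with pytest.raises(ValueError):
        simulate_trajectory(_params(), arena, -5, 5, seed=0)
    with pytest.raises(ValueError):
        simulate_trajectory(_params(), arena, 60, 0, seed=0)
    with pytest.raises(ValueError):
        WalkerParams(SE(0.8, 0.8), SE(0.5, 0.7), speed_mean=5, speed_sd=1, wall_bias=1.5)
    with pytest.raises(ValueError):
        WalkerParams(SE(0.8, 0.8), SE(0.5, 0.7), speed_mean=5, speed_sd=1, pause_step_scale=0.6)


def test_generated_steps_are_bimodal_with_recoverable_threshold(arena):
    # pause mode below 0.5 mm, movement mode above: the kernel-density
    # thresholding stage must find both on a default forager archetype
    sp = default_cohort_spec().species[3]
    t = simulate_trajectory(sp.params, arena, 1200, 5, seed=3)
    thr = estimate_threshold(compute_steps(t).steps, species=sp.name)
    assert 0.0 <= thr.pause_mode_mm < 0.5
    assert thr.move_mode_mm > 0.5
    assert thr.pause_mode_mm < thr.threshold_mm < thr.move_mode_mm


# ---------------------------------------------------------------- cohorts


def test_cohort_size_matches_study_design():
    spec = default_cohort_spec(duration_s=10.0, seed=1)
    trajs, meta = generate_cohort(spec)
    assert len(trajs) == 125  # 50 one-piece + 75 forager workers
    assert meta["nesting_type"].value_counts().to_dict() == {"forager": 75, "one_piece": 50}
    assert meta["individual_id"].is_unique


def test_cohort_metadata_reproducible_byte_for_byte():
    spec = default_cohort_spec(duration_s=10.0, seed=9)
    _, m1 = generate_cohort(spec)
    _, m2 = generate_cohort(spec)
    assert m1.to_csv(index=False) == m2.to_csv(index=False)


def test_zero_colony_sd_leaves_only_sampling_noise_between_colonies(rng):
    # with colony_sd = 0 an ANOVA of per-colony distances within one species
    # should not reject homogeneity
    from scipy.stats import f_oneway

    from nestmove.kinematics import total_distance

    sp = default_cohort_spec().species[1]
    spec = CohortSpec(
        species=[sp], colonies_per_species=4, individuals_per_colony=5,
        colony_sd=0.0, duration_s=240.0, seed=13,
    )
    trajs, meta = generate_cohort(spec)
    dists = {t.individual_id: total_distance(compute_steps(t)) for t in trajs}
    groups = [
        [dists[i] for i in grp["individual_id"]]
        for _, grp in meta.groupby("colony")
    ]
    assert f_oneway(*groups).pvalue > 0.01
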