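"""Step lengths, outlier masking, KDE thresholding and bout segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nestmove.io import Trajectory
from nestmove.kinematics import (
    MOVE,
    PAUSE,
    StepSeries,
    UnimodalStepsError,
    compute_steps,
    estimate_threshold,
    moving_speed,
    pause_proportion,
    remove_outlier_steps,
    segment_bouts,
    total_distance,
)

META = dict(individual_id="w1", species="sp", colony="c1",
            nesting_type="one_piece", body_length_mm=5.0)


def _series(steps, mask=None, dt=0.2):
    steps = np.asarray(steps, dtype=float)
    mask = np.ones(steps.size, bool) if mask is None else np.asarray(mask, bool)
    return StepSeries("w1", steps, mask, dt)


def _mixture_steps(rng, n=20_000, pause_sigma=0.05, move_mu=2.0, move_sigma=0.4):
    half = n // 2
    pauses = np.abs(rng.normal(0.0, pause_sigma, half))
    moves = np.abs(rng.normal(move_mu, move_sigma, n - half))
    return np.concatenate([pauses, moves])


# ---------------------------------------------------------------- steps


def test_step_lengths_are_euclidean_distances():
    traj = Trajectory(**META, frame_interval_s=0.2,
                      positions=np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 4.0]]))
    s = compute_steps(traj)
    np.testing.assert_allclose(s.steps, [5.0, 0.0])
    assert s.valid_mask.all()


def test_step_count_is_positions_minus_one():
    traj = Trajectory(**META, frame_interval_s=0.2, positions=np.zeros((18_000, 2)))
    assert compute_steps(traj).steps.size == 17_999


def test_single_position_rejected():
    traj = Trajectory(**META, frame_interval_s=0.2, positions=np.zeros((1, 2)))
    with pytest.raises(ValueError):
        compute_steps(traj)


# ---------------------------------------------------------------- outliers


def test_outlier_rule_masks_extreme_step():
    steps = np.concatenate([np.ones(99), [50.0]])
    out = remove_outlier_steps(_series(steps))
    assert not out.valid_mask[-1]
    assert out.valid_mask[:99].all()
    # values are retained for audit
    assert out.steps[-1] == 50.0


def test_outlier_rule_keeps_constant_and_mild_series():
    assert remove_outlier_steps(_series(np.ones(50))).valid_mask.all()
    # mean + 2 SD of {1,1,1,1,1.1} is ~1.1 ; nothing exceeds it
    assert remove_outlier_steps(_series([1, 1, 1, 1, 1.1])).valid_mask.all()


def test_total_distance_and_body_length_standardisation():
    s = _series(np.full(10, 2.0))
    assert total_distance(s) == pytest.approx(20.0)
    assert total_distance(s, body_length_mm=5.0) == pytest.approx(4.0)
    masked = _series(np.ones(5), mask=np.zeros(5, bool))
    assert total_distance(masked) == 0.0
    cleaned = remove_outlier_steps(_series(np.concatenate([np.ones(99), [50.0]])))
    assert total_distance(cleaned) == pytest.approx(99.0)


# ---------------------------------------------------------------- threshold


def test_threshold_found_between_mixture_modes(rng):
    thr = estimate_threshold(_mixture_steps(rng), species="mix")
    assert 0.3 < thr.threshold_mm < 1.5
    assert thr.pause_mode_mm < thr.threshold_mm < thr.move_mode_mm
    assert 0.0 <= thr.pause_mode_mm < 0.5
    assert abs(thr.move_mode_mm - 2.0) < 0.3


def test_threshold_scale_equivariance(rng):
    steps = _mixture_steps(rng)
    a = estimate_threshold(steps)
    c = 2.5
    b = estimate_threshold(steps * c)
    # grid resolution limits exactness; allow one grid cell at each scale
    tol = c * steps.max() / 2000 + steps.max() / 2000 * c
    assert b.threshold_mm == pytest.approx(c * a.threshold_mm, abs=3 * tol)
    assert b.move_mode_mm == pytest.approx(c * a.move_mode_mm, abs=3 * tol)


def test_unimodal_inputs_rejected(rng):
    with pytest.raises(UnimodalStepsError):
        estimate_threshold(np.full(500, 2.0))  # constant
    with pytest.raises((UnimodalStepsError, ValueError)):
        estimate_threshold(np.abs(rng.normal(0, 0.05, 5000)))  # pause mass only
    with pytest.raises(ValueError):
        estimate_threshold(np.ones(50))  # too few steps


def test_binned_and_exact_kde_paths_agree(rng):
    steps = _mixture_steps(rng, n=30_000)
    exact = estimate_threshold(steps, max_exact_n=100_000)
    binned = estimate_threshold(steps, max_exact_n=10_000)
    assert binned.threshold_mm == pytest.approx(exact.threshold_mm, abs=0.05)


# ---------------------------------------------------------------- bouts


def test_run_length_encoding_of_labels():
    s = _series([0.1, 0.1, 1.0, 1.0, 1.0, 0.1])
    b = segment_bouts(s, 0.5)
    assert list(b.states) == [PAUSE, MOVE, PAUSE]
    np.testing.assert_allclose(b.durations_s, [0.4, 0.6, 0.2])


def test_step_equal_to_threshold_is_move():
    b = segment_bouts(_series([0.5]), 0.5)
    assert list(b.states) == [MOVE]


def test_bouts_split_at_invalid_steps():
    s = _series([0.1] * 5, mask=[True, True, False, True, True])
    b = segment_bouts(s, 0.5)
    assert list(b.states) == [PAUSE, PAUSE]
    np.testing.assert_allclose(b.durations_s, [0.4, 0.4])


def test_resegmenting_reconstructed_labels_is_idempotent():
    s = _series([0.1, 0.1, 1.0, 0.1, 1.0, 1.0])
    b = segment_bouts(s, 0.5)
    rebuilt = np.concatenate(
        [np.full(n, 1.0 if st == MOVE else 0.1) for st, n in zip(b.states, b.n_frames)]
    )
    b2 = segment_bouts(_series(rebuilt), 0.5)
    np.testing.assert_array_equal(b.states, b2.states)
    np.testing.assert_array_equal(b.n_frames, b2.n_frames)


@settings(deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=3, allow_nan=False), min_size=1, max_size=80),
    st.integers(min_value=0, max_value=2**31 - 1),
)
def test_frame_conservation_across_bouts_and_invalid_steps(steps, mask_seed):
    steps = np.asarray(steps)
    mask = np.random.default_rng(mask_seed).random(steps.size) > 0.2
    b = segment_bouts(_series(steps, mask=mask), 0.7)
    assert b.n_frames.sum() + (~mask).sum() == steps.size


# ---------------------------------------------------------------- summaries


def test_pause_proportion_balanced_and_empty():
    s = _series([0.1, 0.1, 1.0, 1.0])
    assert pause_proportion(segment_bouts(s, 0.5)) == pytest.approx(0.5)
    empty = segment_bouts(_series([0.1], mask=[False]), 0.5)
    assert np.isnan(pause_proportion(empty))


def test_moving_speed_unit_conversion_and_missing():
    s = _series(np.full(10, 1.0))
    assert moving_speed(s, 0.5) == pytest.approx(5.0)  # 1 mm / 0.2 s
    assert np.isnan(moving_speed(s, 2.0))  # nothing above threshold
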