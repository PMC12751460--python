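"""Simulate one forager worker, find its pause/move threshold, segment bouts.

The walker alternates pause and move bouts in a 140 mm arena; the kernel
density of its step lengths is bimodal, and the valley between the pause
mode (near 0 mm) and the movement mode (> 0.5 mm) is the species threshold.
"""

import numpy as np

import nestmove as nm

spec = nm.default_cohort_spec()
forager = spec.species[3]  # "forager_b" archetype
traj = nm.simulate_trajectory(
    forager.params, spec.arena, duration_s=3600, fps=5, seed=42, species=forager.name
)

steps = nm.remove_outlier_steps(nm.compute_steps(traj))
thr = nm.estimate_threshold(steps.valid_steps, species=forager.name)
bouts = nm.segment_bouts(steps, thr.threshold_mm)

print(f"frames: {traj.n_frames}, steps: {steps.steps.size}")
print(f"pause mode {thr.pause_mode_mm:.3f} mm, movement mode {thr.move_mode_mm:.3f} mm")
print(f"threshold (density valley): {thr.threshold_mm:.3f} mm")
print(f"bouts: {bouts.n_bouts} "
      f"(move: {(bouts.states == 'move').sum()}, pause: {(bouts.states == 'pause').sum()})")
print(f"pause proportion: {nm.pause_proportion(bouts):.3f}")
print(f"moving speed: {nm.moving_speed(steps, thr.threshold_mm):.2f} mm/s")
print(f"traveled distance: {nm.total_distance(steps) / 1000:.1f} m in 60 min")
# The threshold separates the two behavioural modes; everything downstream
# (bout durations, pause proportion, speed) is conditional on it.
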