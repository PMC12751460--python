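"""Wall-following and inner-crossing geometry for the two nesting archetypes.

The arena is split into equal-area inner/outer regions by the circle of
radius 70/sqrt(2) mm.  Foragers hug the wall and cross the centre directly
(high straightness); one-piece nesters wander the centre slowly.
"""

import nestmove as nm

spec = nm.default_cohort_spec()
for sp in (spec.species[0], spec.species[3]):  # one one-piece, one forager
    traj = nm.simulate_trajectory(sp.params, spec.arena, 3600, 5, seed=11, species=sp.name)
    z = nm.inner_bouts(traj)
    print(f"{sp.name} ({sp.nesting_type})")
    print(f"  time in outer region: {100 * z.prop_outer:.1f} %")
    print(f"  inner bouts (>= 1 s): {len(z.bouts)}")
    if len(z.bouts):
        print(f"  mean duration {z.mean_duration_s:.1f} s, path {z.mean_path_mm:.1f} mm, "
              f"chord {z.mean_chord_mm:.1f} mm, SI {z.mean_straightness:.2f}")
# Expect the forager near 100 % outer occupancy with straight (SI ~ 0.9)
# crossings, and the one-piece nester with long, tortuous (low-SI) visits.
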