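"""Equal-area arena zones, wall-zone occupancy and inner-crossing bouts.

The arena floor is split into two regions of identical area: the inner disc
of radius r/sqrt(2) and the outer annulus.  Time spent in the outer annulus
measures thigmotaxis (wall-following).  Crossings of the centre are
characterised through *inner bouts* — maximal runs of consecutive frames
strictly inside the inner circle lasting at least 1.0 s (>= 5 frames at
5 fps) — each scored by duration, path length, chord length between entry
and exit frames, and straightness index SI = chord / path (1 for a perfectly
straight crossing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Trajectory

__all__ = [
    "ZoneSummary",
    "classify_zone",
    "occupancy",
    "inner_bouts",
    "path_chord_straightness",
]

BOUT_METRICS = ("duration_s", "path_mm", "chord_mm", "straightness")


@dataclass(frozen=True)
class ZoneSummary:
    """Per-individual occupancy and inner-bout metrics.

    ``bouts`` has one row per inner bout with columns
    duration_s / path_mm / chord_mm / straightness; the ``mean_*`` fields are
    NaN for individuals with no qualifying inner bout, and
    ``entered_inner`` is False for individuals that never reached the inner
    region at all (the analysis excludes them from bout-metric averages).
    """

    individual_id: str
    prop_outer: float
    entered_inner: bool
    bouts: pd.DataFrame
    mean_duration_s: float
    mean_path_mm: float
    mean_chord_mm: float
    mean_straightness: float


def classify_zone(traj: Trajectory) -> np.ndarray:
    """Boolean per-frame labels: True inside the inner circle (strict r < r_inner).

    Frames exactly on the inner boundary count as outer; the convention is
    arbitrary but fixed (measure-zero for real data).
    """
    r = np.hypot(traj.positions[:, 0], traj.positions[:, 1])
    return r < traj.arena.inner_radius_mm


def occupancy(inner_labels: np.ndarray) -> float:
    """Proportion of frames spent in the outer region."""
    labels = np.asarray(inner_labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("no frames to classify")
    return float(1.0 - labels.mean())


def path_chord_straightness(positions: np.ndarray) -> tuple[float, float, float]:
    """Path length, chord length and SI = chord/path for one position run.

    Invariant under rotation and translation; SI is NaN when the path length
    is zero (no displacement to be straight about).
    """
    pos = np.asarray(positions, dtype=float)
    diffs = np.diff(pos, axis=0)
    path = float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())
    chord = float(np.hypot(*(pos[-1] - pos[0])))
    si = chord / path if path > 0 else float("nan")
    return path, chord, si


def inner_bouts(
    traj: Trajectory,
    inner_labels: np.ndarray | None = None,
    step_valid_mask: np.ndarray | None = None,
    min_duration_s: float = 1.0,
) -> ZoneSummary:
    """Score inner-region crossings of at least ``min_duration_s``.

    Entry and exit points are the first and last frames *inside* the inner
    circle (no boundary interpolation).  A bout's path uses the raw steps
    within the bout, but bouts containing a step masked as a tracking
    artefact are discarded: the artefact invalidates the crossing geometry.
    """
    if inner_labels is None:
        inner_labels = classify_zone(traj)
    inner_labels = np.asarray(inner_labels, dtype=bool)
    if inner_labels.size != traj.n_frames:
        raise ValueError("inner_labels must have one entry per frame")
    min_frames = math.ceil(min_duration_s / traj.frame_interval_s - 1e-9)

    padded = np.concatenate(([False], inner_labels, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive

    rows = []
    for s, e in zip(starts, ends):
        n = e - s
        if n < min_frames:
            continue
        if step_valid_mask is not None and not np.all(step_valid_mask[s : e - 1]):
            continue
        path, chord, si = path_chord_straightness(traj.positions[s:e])
        rows.append((n * traj.frame_interval_s, path, chord, si))

    bouts = pd.DataFrame(rows, columns=list(BOUT_METRICS))
    means = bouts.mean() if len(bouts) else pd.Series(
        {m: float("nan") for m in BOUT_METRICS}
    )
    return ZoneSummary(
        individual_id=traj.individual_id,
        prop_outer=occupancy(inner_labels),
        entered_inner=bool(inner_labels.any()),
        bouts=bouts,
        mean_duration_s=float(means["duration_s"]),
        mean_path_mm=float(means["path_mm"]),
        mean_chord_mm=float(means["chord_mm"]),
        mean_straightness=float(means["straightness"]),
    )
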