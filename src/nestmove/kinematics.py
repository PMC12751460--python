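"""Step lengths, artefact removal, pause/move thresholding and bout segmentation.

The analysis works on *step lengths*: Euclidean displacements of the tracked
body centre between successive frames, in mm.  Pooled per species, step
lengths are bimodal — a near-zero pause mode (within 0-0.5 mm) and a movement
mode (largest local density maximum above 0.5 mm).  The pause/move threshold
is the kernel-density valley between the two modes; steps below it are
labelled pause, steps at or above it move.  Maximal runs of identically
labelled steps become bouts whose durations feed the duration-model fits.

Steps larger than (mean + 2 SD), computed per individual, are tracking
artefacts (animals climbing the arena wall and tumbling back) and are masked
before pooling; bouts are split, never bridged, across masked steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gaussian_kde

from .io import Trajectory

__all__ = [
    "StepSeries",
    "ThresholdResult",
    "BoutSequence",
    "UnimodalStepsError",
    "compute_steps",
    "remove_outlier_steps",
    "estimate_threshold",
    "segment_bouts",
    "total_distance",
    "pause_proportion",
    "moving_speed",
]

PAUSE, MOVE = "pause", "move"


class UnimodalStepsError(ValueError):
    """Raised when the pooled step-length density has no pause/move valley."""


@dataclass(frozen=True)
class StepSeries:
    """Per-individual step lengths with a validity mask (False = artefact)."""

    individual_id: str
    steps: np.ndarray
    valid_mask: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps, dtype=float)
        mask = np.asarray(self.valid_mask, dtype=bool)
        if steps.ndim != 1 or steps.size == 0:
            raise ValueError("steps must be a non-empty 1-D array")
        if mask.shape != steps.shape:
            raise ValueError("valid_mask must match steps in shape")
        if np.any(steps < 0):
            raise ValueError("step lengths cannot be negative")
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "valid_mask", mask)
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def valid_steps(self) -> np.ndarray:
        return self.steps[self.valid_mask]


@dataclass(frozen=True)
class ThresholdResult:
    """Species-level pause/move threshold with the two density modes."""

    species: str
    threshold_mm: float
    pause_mode_mm: float
    move_mode_mm: float
    grid_mm: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        if not (self.pause_mode_mm < self.threshold_mm < self.move_mode_mm):
            raise ValueError("threshold must lie strictly between the two modes")
        if not (0.0 <= self.pause_mode_mm < 0.5):
            raise ValueError("pause mode must lie in [0, 0.5) mm")
        if not self.move_mode_mm > 0.5:
            raise ValueError("movement mode must exceed 0.5 mm")


@dataclass(frozen=True)
class BoutSequence:
    """Run-length encoding of the pause/move label sequence.

    ``states`` holds "pause"/"move" per bout, ``n_frames`` the run lengths
    (masked steps break runs and belong to no bout), and
    ``durations_s = n_frames * frame_interval_s``.
    """

    individual_id: str
    states: np.ndarray
    n_frames: np.ndarray
    frame_interval_s: float
    threshold_mm: float

    @property
    def durations_s(self) -> np.ndarray:
        return self.n_frames * self.frame_interval_s

    def durations_for(self, state: str) -> np.ndarray:
        return self.durations_s[self.states == state]

    @property
    def n_bouts(self) -> int:
        return int(self.states.size)


def compute_steps(traj: Trajectory) -> StepSeries:
    """Euclidean distance between consecutive positions (n-1 steps, all valid)."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 positions to compute steps")
    diffs = np.diff(traj.positions, axis=0)
    steps = np.hypot(diffs[:, 0], diffs[:, 1])
    return StepSeries(
        individual_id=traj.individual_id,
        steps=steps,
        valid_mask=np.ones(steps.size, dtype=bool),
        frame_interval_s=traj.frame_interval_s,
    )


def remove_outlier_steps(series: StepSeries) -> StepSeries:
    """Mask steps above mean + 2 SD, both computed on the raw per-individual steps.

    Masked values are retained for audit but excluded from every downstream
    sum, pooled density and bout label.
    """
    mean = float(series.steps.mean())
    sd = float(series.steps.std(ddof=0))
    cutoff = mean + 2.0 * sd
    return replace(series, valid_mask=series.valid_mask & (series.steps <= cutoff))


def _silverman_bandwidth(x: np.ndarray) -> float:
    # classic 1-D Silverman factor as used by scipy: (3n/4)^(-1/5) * std
    return float((3.0 * x.size / 4.0) ** (-0.2) * x.std(ddof=1))


def estimate_threshold(
    steps,
    species: str = "",
    grid_points: int = 2001,
    max_exact_n: int = 50_000,
    n_bins: int = 4096,
) -> ThresholdResult:
    """Find the pause/move threshold as the KDE valley between the two modes.

    A Gaussian kernel with Silverman's bandwidth is evaluated on a fixed grid
    from 0 to the maximum step at ``grid_points`` points.  Samples larger
    than ``max_exact_n`` are first binned into ``n_bins`` weighted points
    (the bandwidth is still computed on the raw sample), which keeps the
    evaluation cost independent of sample size.  If no movement mode above
    0.5 mm exists, or the valley is not a genuine interior minimum, the input
    is rejected as unimodal rather than silently thresholded.
    """
    x = np.asarray(steps, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError("need at least 100 pooled steps to estimate a threshold")
    if x.std(ddof=1) == 0:
        raise UnimodalStepsError(f"{species or 'sample'}: constant step lengths")
    bw = _silverman_bandwidth(x)

    if x.size > max_exact_n:
        hist, edges = np.histogram(x, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 0
        sample, weights = centers[keep], hist[keep].astype(float)
        wmean = np.average(sample, weights=weights)
        wstd = np.sqrt(np.average((sample - wmean) ** 2, weights=weights))
        kde = gaussian_kde(sample, weights=weights, bw_method=bw / wstd)
    else:
        kde = gaussian_kde(x, bw_method=bw / x.std(ddof=1))

    grid = np.linspace(0.0, float(x.max()), grid_points)
    density = kde(grid)

    pause_region = grid < 0.5
    if not pause_region.any():
        raise UnimodalStepsError(f"{species or 'sample'}: no grid support below 0.5 mm")
    pause_idx = int(np.argmax(density[pause_region]))

    interior = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    local_max = np.flatnonzero(interior) + 1
    move_candidates = local_max[grid[local_max] > 0.5]
    if move_candidates.size == 0:
        raise UnimodalStepsError(f"{species or 'sample'}: no movement mode above 0.5 mm")
    move_idx = int(move_candidates[np.argmax(density[move_candidates])])

    between = slice(pause_idx + 1, move_idx)
    if between.stop <= between.start:
        raise UnimodalStepsError(f"{species or 'sample'}: modes not separated on the grid")
    valley_idx = pause_idx + 1 + int(np.argmin(density[between]))
    valley = density[valley_idx]
    if not (valley < density[pause_idx] * (1 - 1e-9) and valley < density[move_idx] * (1 - 1e-9)):
        raise UnimodalStepsError(f"{species or 'sample'}: no interior density minimum between modes")

    return ThresholdResult(
        species=species,
        threshold_mm=float(grid[valley_idx]),
        pause_mode_mm=float(grid[pause_idx]),
        move_mode_mm=float(grid[move_idx]),
        grid_mm=grid,
        density=density,
    )


def segment_bouts(series: StepSeries, threshold_mm: float) -> BoutSequence:
    """Run-length encode pause (< threshold) / move (>= threshold) labels.

    Masked steps carry no label: runs are broken, never merged, across them,
    because an artefactual displacement gives no evidence the behavioural
    state continued.
    """
    if not threshold_mm > 0:
        raise ValueError("threshold must be positive")
    labels = np.where(series.steps >= threshold_mm, 1, 0)
    labels[~series.valid_mask] = -1

    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    run_labels = labels[starts]
    keep = run_labels >= 0
    states = np.where(run_labels[keep] == 1, MOVE, PAUSE)
    return BoutSequence(
        individual_id=series.individual_id,
        states=states,
        n_frames=(ends - starts)[keep],
        frame_interval_s=series.frame_interval_s,
        threshold_mm=float(threshold_mm),
    )


def total_distance(series: StepSeries, body_length_mm: float | None = None) -> float:
    """Sum of valid step lengths in mm; in body lengths if a body size is given."""
    dist = float(series.valid_steps.sum())
    if body_length_mm is None:
        return dist
    if not body_length_mm > 0:
        raise ValueError("body_length_mm must be positive")
    return dist / body_length_mm


def pause_proportion(bouts: BoutSequence) -> float:
    """Pause frames over all labelled frames (NaN if nothing was labelled)."""
    total = int(bouts.n_frames.sum())
    if total == 0:
        return float("nan")
    return float(bouts.n_frames[bouts.states == PAUSE].sum() / total)


def moving_speed(series: StepSeries, threshold_mm: float) -> float:
    """Mean of valid steps at or above the threshold, converted to mm/s.

    The recorded quantity is mm per frame interval; dividing by the frame
    interval makes the unit explicit.  NaN (an explicit missing value, not 0)
    when the individual never crossed the threshold.
    """
    moves = series.valid_steps
    moves = moves[moves >= threshold_mm]
    if moves.size == 0:
        return float("nan")
    return float(moves.mean() / series.frame_interval_s)
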