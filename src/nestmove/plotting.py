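"""Plain diagnostic plots: step-length density with threshold, bout ICDFs."""

from __future__ import annotations

import numpy as np

from .bout_models import icdf
from .kinematics import ThresholdResult


def plot_step_density(result: ThresholdResult, ax=None):
    """Kernel density of pooled step lengths with modes and threshold marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.grid_mm, result.density, color="k", lw=1)
    ax.axvline(result.threshold_mm, color="r", ls="--", label=f"threshold {result.threshold_mm:.2f} mm")
    ax.axvline(result.pause_mode_mm, color="b", ls=":", label="pause mode")
    ax.axvline(result.move_mode_mm, color="g", ls=":", label="movement mode")
    ax.set_xlabel("step length (mm)")
    ax.set_ylabel("density")
    ax.set_title(result.species or "pooled steps")
    ax.legend(frameon=False)
    return ax


def plot_icdf(durations_by_label: dict[str, np.ndarray], ax=None):
    """Log-log inverse CDFs (proportion of bouts >= duration) per label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, durations in durations_by_label.items():
        vals, prop = icdf(durations)
        ax.loglog(vals, prop, drawstyle="steps-post", label=label)
    ax.set_xlabel("bout duration (s)")
    ax.set_ylabel("P(duration >= x)")
    ax.legend(frameon=False)
    return ax
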