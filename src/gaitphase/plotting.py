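"""Quick-look figures for session results.

Helpers return the matplotlib Axes so callers can compose panels; none
are needed by the analysis itself.
"""

from __future__ import annotations

import numpy as np

from .events import PeriEventMatrix, SpeedTuning
from .phase import PhaseHistogram

__all__ = ["plot_phase_tuning", "plot_peri_event", "plot_speed_tuning"]


def plot_phase_tuning(hist: PhaseHistogram, ax=None, two_cycles: bool = True):
    """Firing rate versus limb phase, repeated over two cycles for clarity."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = hist.bin_centers_deg
    y = hist.rate_hz
    if two_cycles:
        x = np.concatenate([x, x + 360.0])
        y = np.tile(y, 2)
    ax.plot(x, y, drawstyle="steps-mid")
    ax.set_xlabel("limb phase (deg)")
    ax.set_ylabel("firing rate (Hz)")
    ax.set_xlim(0, 720 if two_cycles else 360)
    return ax


def plot_peri_event(matrix: PeriEventMatrix, ax=None, label: str = "event"):
    """Cross-event mean firing rate around movement starts or stops."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    psth = matrix.rates_hz.mean(axis=0)
    sem = matrix.rates_hz.std(axis=0, ddof=1) / np.sqrt(max(matrix.n_events, 2))
    ax.fill_between(matrix.bin_centers_s, psth - sem, psth + sem, alpha=0.3)
    ax.plot(matrix.bin_centers_s, psth)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel(f"time from {label} (s)")
    ax.set_ylabel("firing rate (Hz)")
    return ax


def plot_speed_tuning(tuning: SpeedTuning, ax=None):
    """Mean firing rate per body-speed bin."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(tuning.bin_centers_mm_s, tuning.rate_hz, marker="o")
    ax.set_xlabel("body speed (mm/s)")
    ax.set_ylabel("firing rate (Hz)")
    return ax
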