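"""Quick-look figures for each assay's primary output.

Each function takes the corresponding result object and an optional
matplotlib Axes, returns the Axes, and leaves styling minimal — these are
QC plots, not publication figures.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .anaphase import SeparationSeries
from .frap import NormalizedTrace
from .growth import GrowthCurve
from .pef import RadialProfile

__all__ = [
    "plot_radial_profile",
    "plot_separation_series",
    "plot_frap_trace",
    "plot_growth_curve",
]


def _axes(ax):
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    return ax


def plot_radial_profile(profile: RadialProfile, ax=None):
    """Mean intensity vs distance from the pole, with the maximum marked."""
    ax = _axes(ax)
    ax.plot(profile.bin_centers_um, profile.mean_intensity, lw=1)
    i = int(np.argmax(profile.mean_intensity))
    ax.axvline(profile.bin_centers_um[i], color="crimson", ls="--", lw=0.8)
    ax.set_xlabel("distance from pole (μm)")
    ax.set_ylabel("mean intensity (a.u.)")
    return ax


def plot_separation_series(series: SeparationSeries, ax=None):
    """Mass (and, when present, pole/centromere) separation vs time."""
    ax = _axes(ax)
    t = series.times_min
    ax.plot(t, series.mass_separation_um, "o-", ms=3, label="chromosome masses")
    for col, label in [("pole_sep_um", "poles"), ("cen_sep_um", "centromeres")]:
        vals = series.table[col].to_numpy()
        if np.isfinite(vals).any():
            ax.plot(t, vals, "s--", ms=3, label=label)
    ax.set_xlabel("time after anaphase onset (min)")
    ax.set_ylabel("separation (μm)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_frap_trace(trace: NormalizedTrace, ax=None):
    """Normalized recovery with the bleach moment marked."""
    ax = _axes(ax)
    ax.plot(trace.times, trace.normalized, "o-", ms=3)
    ax.axvline(trace.times[trace.bleach_index], color="crimson", ls="--", lw=0.8)
    ax.axhline(1.0, color="grey", lw=0.5)
    ax.set_xlabel("time from bleach (s)")
    ax.set_ylabel("fraction of initial intensity")
    return ax


def plot_growth_curve(curve: GrowthCurve, ax=None, log2: bool = True):
    """Counts vs time, log2-scaled by default so exponential growth is a line."""
    ax = _axes(ax)
    ax.plot(curve.times, curve.counts, "o-", ms=3)
    if log2:
        ax.set_yscale("log", base=2)
    ax.set_xlabel("time (hr)")
    ax.set_ylabel("cell count")
    return ax
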