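"""Plot helpers for the standard report figures (matplotlib, Agg-safe)."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_area_profile", "plot_pressure_profile", "plot_breath_trace"]


def plot_area_profile(sections, ax=None, **kwargs):
    """Station areas vs signed label, rostral (+) on the left as convention."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    labels = [s.station_label_mm for s in sections if not s.missing]
    areas = [s.area_mm2 for s in sections if not s.missing]
    ax.plot(labels, areas, marker="o", **kwargs)
    ax.invert_xaxis()
    ax.set_xlabel("station (mm, + rostral of hard palate)")
    ax.set_ylabel("cross-sectional area (mm$^2$)")
    ax.grid(alpha=0.3)
    return ax


def plot_pressure_profile(result, segments=None, ax=None, **kwargs):
    """Pressure along arclength from a 1-D solution, with segment boundaries."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(result.s_mm, result.pressure_pa, **kwargs)
    if segments is not None:
        for s in (segments.s_meatus_merge, segments.s_hard_palate,
                  segments.s_epiglottis):
            ax.axvline(s, color="gray", ls=":", lw=0.8)
    ax.set_xlabel("arclength (mm)")
    ax.set_ylabel("pressure (Pa)")
    ax.grid(alpha=0.3)
    return ax


def plot_breath_trace(trace, window_s=None, ax=None):
    """Flow and volume over (a window of) a breathing trace."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    sel = slice(None)
    if window_s is not None:
        sel = trace.time_s <= window_s
    ax.plot(trace.time_s[sel], trace.flow_ml_s[sel], lw=0.8, label="flow (ml/s)")
    ax.plot(trace.time_s[sel], trace.volume_ml[sel], lw=0.8, label="volume (ml)")
    if np.any(trace.movement[sel]):
        ax.fill_between(trace.time_s[sel], 0, 1, where=trace.movement[sel],
                        transform=ax.get_xaxis_transform(), alpha=0.15,
                        color="red", label="movement")
    ax.set_xlabel("time (s)")
    ax.legend(loc="upper right", fontsize=8)
    return ax
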