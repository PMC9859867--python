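"""Plotting utilities for curves and cohort phase overlays."""
from __future__ import annotations

import numpy as np

from .curves import TimeIntensityCurves
from .phases import NormalizedAVCurve


def plot_tics(curves: TimeIntensityCurves, axes=None):
    """Four-panel subject plot: vessel volumes, CR, enhancement, AV ratio."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 2, figsize=(10, 7), constrained_layout=True)
    (ax_vol, ax_cr), (ax_enh, ax_av) = axes
    t = curves.times_s
    ax_vol.plot(t, curves.vol_contralateral_ml, label="contralateral")
    ax_vol.plot(t, curves.vol_occluded_ml, label="occluded")
    ax_vol.set_ylabel("enhanced vessel volume (mL)")
    ax_vol.legend()
    ax_cr.plot(t, curves.cr_percent)
    ax_cr.set_ylabel("collateral ratio (%)")
    ax_enh.plot(t, curves.arterial_hu, label="arterial")
    ax_enh.plot(t, curves.venous_hu, label="venous")
    ax_enh.set_ylabel("enhancement (HU)")
    ax_enh.legend()
    ax_av.plot(t, curves.av_ratio)
    ax_av.set_ylabel("AV enhancement ratio")
    for ax in (ax_vol, ax_cr, ax_enh, ax_av):
        ax.set_xlabel("time (s)")
        if curves.arrival_s is not None:
            ax.axvline(curves.arrival_s, color="grey", ls=":", lw=0.8)
    return axes


def plot_normalized_cohort(curves_list: list[NormalizedAVCurve],
                           mcta_times: list[tuple[float, float, float]] | None = None,
                           ax=None):
    """Overlay normalized AV-ratio curves aligned at the arterial (ratio) peak.

    Display-only cross-subject alignment: each curve's time axis is shifted
    so its peak sits at 0; optional aligned mCTA times are marked per curve.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    colors = ("tab:red", "tab:green", "tab:blue")
    for i, c in enumerate(curves_list):
        shift = c.t_peak_s
        ax.plot(c.times_s - shift, c.normalized, color="0.6", lw=0.8, alpha=0.7)
        if mcta_times is not None:
            for j, tm in enumerate(mcta_times[i]):
                ax.plot(tm - shift, c.value_at(tm), "o", ms=4, color=colors[j])
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time from AV-ratio peak (s)")
    ax.set_ylabel("normalized AV enhancement ratio")
    return ax
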