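"""Normalized AV-ratio curve and contrast acquisition phase classification.

The raw arteriovenous enhancement ratio is normalized per subject by
offsetting the equilibrium point (raw ratio = 1) to 0 and dividing by the
curve maximum, so that the normalized value is exactly 1 at the AV-ratio
peak and exactly 0 at the (interpolated) equilibrium. Five acquisition
phases are then defined on this curve:

====  ======================================================
EA    early arterial: upslope from 0.2 to 1.0
PA    peak arterial: downslope from 1.0 to 0.5
EQ    equilibrium: downslope from 0.5 to 0
PV    early venous: 0 down to the post-equilibrium minimum
LV    late venous: from the minimum back toward 0
====  ======================================================

plus PRE for times before the 0.2 upslope threshold (or before contrast
arrival). Boundary values belong to the later phase; up/downslope is
operationalized as before/after the curve peak.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .curves import TimeIntensityCurves, smooth_curve
from .errors import (ConfigurationError, DegenerateCurveError,
                     EquilibriumNotFoundError)


class Phase(str, Enum):
    PRE = "PRE"
    EA = "EA"
    PA = "PA"
    EQ = "EQ"
    PV = "PV"
    LV = "LV"


PHASE_ORDER = [Phase.PRE, Phase.EA, Phase.PA, Phase.EQ, Phase.PV, Phase.LV]


@dataclass
class NormalizedAVCurve:
    """Per-subject normalized AV-ratio curve with its phase landmarks."""

    times_s: np.ndarray          # valid sample times
    normalized: np.ndarray       # normalized ratio at those times
    t_peak_s: float              # time of the AV-ratio maximum
    t_equi_s: float              # interpolated time where the raw ratio = 1
    t_min_s: float               # post-equilibrium minimum (or last sample)
    arrival_s: float | None      # contrast arrival; gates non-PRE labels
    valid_range: tuple[float, float]

    def value_at(self, t) -> float | np.ndarray:
        v = np.interp(t, self.times_s, self.normalized)
        return float(v) if np.ndim(t) == 0 else v


def find_equilibrium(curves: TimeIntensityCurves,
                     smoothing_window: int = 1) -> float:
    """Time of the first downward crossing of the raw AV ratio through 1
    after the ratio peak, linearly interpolated between bracketing frames."""
    r = smooth_curve(curves.av_ratio, smoothing_window)
    t = curves.times_s
    if not np.isfinite(r).any():
        raise EquilibriumNotFoundError("AV ratio curve has no valid samples")
    peak = int(np.nanargmax(r))
    for k in range(peak + 1, len(r)):
        if not (np.isfinite(r[k]) and np.isfinite(r[k - 1])):
            continue
        if r[k] <= 1.0 < r[k - 1]:
            frac = (r[k - 1] - 1.0) / (r[k - 1] - r[k])
            return float(t[k - 1] + frac * (t[k] - t[k - 1]))
        if r[k] == 1.0:
            return float(t[k])
    raise EquilibriumNotFoundError("AV ratio never falls through 1 after its peak")


def normalize_av_curve(curves: TimeIntensityCurves,
                       smoothing_window: int = 1) -> NormalizedAVCurve:
    """Normalize the AV-ratio curve: equilibrium -> 0, maximum -> 1.

    ``normalized(t) = (ratio(t) - 1) / (ratio_peak - 1)``. Invalid samples
    (venous at or below the blood baseline) are dropped from the curve; the
    optional smoothing window is applied before landmark finding, matching
    the curve the phases are read from.
    """
    r = smooth_curve(curves.av_ratio, smoothing_window)
    t = np.asarray(curves.times_s, dtype=float)
    valid = np.isfinite(r)
    if valid.sum() < 2:
        raise DegenerateCurveError("fewer than 2 valid AV-ratio samples")
    tv, rv = t[valid], r[valid]
    peak_idx = int(np.argmax(rv))
    r_peak = float(rv[peak_idx])
    if r_peak <= 1.0:
        raise DegenerateCurveError(
            f"AV-ratio peak {r_peak:.3f} <= 1; curve cannot be normalized")
    t_equi = find_equilibrium(curves, smoothing_window)
    norm = (rv - 1.0) / (r_peak - 1.0)
    after_equi = tv >= t_equi
    if after_equi.any():
        rel = int(np.argmin(norm[after_equi]))
        t_min = float(tv[after_equi][rel])
    else:
        t_min = float(tv[-1])   # acquisition ended before the minimum
    return NormalizedAVCurve(
        times_s=tv,
        normalized=norm,
        t_peak_s=float(tv[peak_idx]),
        t_equi_s=t_equi,
        t_min_s=t_min,
        arrival_s=curves.arrival_s,
        valid_range=(float(tv[0]), float(tv[-1])),
    )


def classify_phase(curve: NormalizedAVCurve, t: float) -> Phase:
    """Contrast acquisition phase at time ``t`` (boundaries -> later phase)."""
    lo, hi = curve.valid_range
    if not lo <= t <= hi:
        raise ConfigurationError(
            f"t = {t:.2f} s outside the valid curve range [{lo:.2f}, {hi:.2f}]")
    v = curve.value_at(t)
    if t < curve.t_peak_s:
        if (curve.arrival_s is not None and t < curve.arrival_s) or v < 0.2:
            return Phase.PRE
        return Phase.EA
    if t > curve.t_min_s:
        return Phase.LV
    if t >= curve.t_equi_s:
        return Phase.PV
    if v > 0.5:
        return Phase.PA
    return Phase.EQ


def label_frames(curve: NormalizedAVCurve) -> list[Phase]:
    """Phase label of every valid curve sample."""
    return [classify_phase(curve, float(t)) for t in curve.times_s]
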