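"""Predefined CTP time points and the per-subject collateral-ratio profile.

Six landmarks are read off the time-intensity curves: the peaks of
contralateral vessel volume (vol_max), occluded-side vessel volume
(vol_occluded_max), arterial enhancement (arterial_max), venous enhancement
(venous_max) and AV ratio (av_max), plus the arteriovenous equilibrium
(equi). The CR at each landmark — together with the time-invariant CR and
the three temporally aligned mCTA CRs — forms the subject's CR profile.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentResult
from .curves import ExtractionParams, TimeIntensityCurves, smooth_curve
from .errors import LandmarkNotFoundError
from .phases import Phase, find_equilibrium

CTP_LANDMARKS = ["vol_max", "vol_occluded_max", "arterial_max",
                 "venous_max", "equi", "av_max"]

#: the ten CR variables of the full profile, in reporting order
CR_VARIABLES = ["cr_vol_max", "cr_vol_occluded_max", "cr_arterial_max",
                "cr_venous_max", "cr_equi", "cr_av_max", "cr_mip",
                "cr_mcta_baseline", "cr_mcta_delay1", "cr_mcta_delay2"]


@dataclass
class Landmark:
    time_s: float
    time_since_arrival_s: float | None


@dataclass
class CRProfile:
    """All ten collateral ratios of one subject (percent; ``nan`` = missing)."""

    ctp_crs: dict            # landmark name -> CR percent
    landmark_times: dict     # landmark name -> Landmark
    cr_mip: float
    mcta_crs: dict = field(default_factory=dict)       # position -> CR percent
    mcta_times_s: dict = field(default_factory=dict)   # position -> aligned time
    mcta_phases: dict = field(default_factory=dict)    # position -> Phase

    def as_record(self) -> dict:
        """Flat record with the ten CR variables plus timing columns."""
        rec = {}
        for lm in CTP_LANDMARKS:
            rec[f"cr_{lm}"] = self.ctp_crs.get(lm, float("nan"))
            lmk = self.landmark_times.get(lm)
            rec[f"t_{lm}_s"] = lmk.time_s if lmk else float("nan")
            rec[f"t_{lm}_since_arrival_s"] = (
                lmk.time_since_arrival_s if lmk and lmk.time_since_arrival_s is not None
                else float("nan"))
        rec["cr_mip"] = self.cr_mip
        for pos in ("mcta_baseline", "mcta_delay1", "mcta_delay2"):
            rec[f"cr_{pos}"] = self.mcta_crs.get(pos, float("nan"))
            rec[f"t_{pos}_s"] = self.mcta_times_s.get(pos, float("nan"))
            ph = self.mcta_phases.get(pos)
            rec[f"phase_{pos}"] = ph.value if isinstance(ph, Phase) else ph
        return rec


def _argmax_time(values: np.ndarray, times: np.ndarray, window: int, name: str) -> float:
    v = smooth_curve(values, window)
    if not np.isfinite(v).any():
        raise LandmarkNotFoundError(f"curve '{name}' has no valid sample")
    return float(times[int(np.nanargmax(v))])   # earliest frame wins ties


def find_timepoints(curves: TimeIntensityCurves,
                    ext: ExtractionParams | None = None) -> dict[str, Landmark]:
    """Locate the six predefined landmark times.

    Peaks are frame-wise argmax of the (optionally smoothed) curves with the
    earliest frame winning ties; the equilibrium is interpolated between
    frames. Times are reported both absolute and relative to contrast
    arrival. A curve with no valid sample yields no landmark rather than a
    fabricated one.
    """
    ext = ext if ext is not None else ExtractionParams()
    w = ext.smoothing_window
    t = curves.times_s
    peak_curves = {
        "vol_max": curves.vol_contralateral_ml,
        "vol_occluded_max": curves.vol_occluded_ml,
        "arterial_max": curves.arterial_hu,
        "venous_max": curves.venous_hu,
        "av_max": curves.av_ratio,
    }
    out: dict[str, Landmark] = {}
    for name, vals in peak_curves.items():
        try:
            tm = _argmax_time(vals, t, w, name)
        except LandmarkNotFoundError:
            continue
        out[name] = _landmark(tm, curves.arrival_s)
    try:
        out["equi"] = _landmark(find_equilibrium(curves, w), curves.arrival_s)
    except Exception:
        pass
    if not out:
        raise LandmarkNotFoundError("no landmark could be placed on any curve")
    return out


def _landmark(time_s: float, arrival_s: float | None) -> Landmark:
    since = time_s - arrival_s if arrival_s is not None else None
    return Landmark(time_s=float(time_s), time_since_arrival_s=since)


def cr_at_time(curves: TimeIntensityCurves, time_s: float) -> float:
    """CR at the acquired frame nearest to ``time_s``.

    The CR is a ratio of segmented volumes and only exists at frames, so the
    nearest frame is used rather than interpolating between frames.
    """
    i = int(np.argmin(np.abs(curves.times_s - time_s)))
    return float(curves.cr_percent[i])


def extract_cr_profile(curves: TimeIntensityCurves,
                       landmarks: dict[str, Landmark],
                       cr_mip: float,
                       alignment: AlignmentResult | None = None,
                       mcta_crs=None) -> CRProfile:
    """Assemble the full CR profile of one subject."""
    ctp_crs = {name: cr_at_time(curves, lm.time_s) for name, lm in landmarks.items()}
    profile = CRProfile(ctp_crs=ctp_crs, landmark_times=dict(landmarks), cr_mip=cr_mip)
    if alignment is not None and mcta_crs is not None:
        positions = ("mcta_baseline", "mcta_delay1", "mcta_delay2")
        for pos, cr, tm in zip(positions, mcta_crs, alignment.aligned_times_s):
            profile.mcta_crs[pos] = float(cr)
            profile.mcta_times_s[pos] = float(tm)
        if alignment.phases is not None:
            for pos, ph in zip(positions, alignment.phases):
                profile.mcta_phases[pos] = ph
    return profile
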