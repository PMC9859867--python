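"""Time-intensity curves (TICs) from a dynamic CT series.

Four curve families are extracted per subject: enhanced vessel volume on the
occluded and contralateral sides, the per-frame collateral ratio, arterial
and venous enhancement (median HU over small spherical ROIs), and the
blood-subtracted arteriovenous (AV) enhancement ratio
``(arterial - 40) / (venous - 40)``. A time-invariant angiogram (voxelwise
maximum over all frames) and its collateral ratio are also computed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArrivalNotFoundError, ConfigurationError, GeometryError
from .series import CTPSeries, RegionSpec, SphereROI
from .vessels import (SegmentationParams, baseline_volume, collateral_ratio,
                      enhanced_vessel_volume, segment_vessels)


@dataclass
class ExtractionParams:
    """Curve-extraction parameters.

    ``blood_hu`` is the average density of unclotted blood subtracted from
    arterial and venous values before forming the AV ratio. ``arrival_delta_hu``
    is the arterial rise over the pre-contrast baseline that defines contrast
    arrival. ``smoothing_window`` (odd frame count) is applied only when
    locating curve landmarks, never to the stored raw curves; 1 disables it.
    """

    blood_hu: float = 40.0
    arrival_delta_hu: float = 10.0
    smoothing_window: int = 1

    def __post_init__(self) -> None:
        if self.arrival_delta_hu <= 0:
            raise ConfigurationError("arrival_delta_hu must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigurationError("smoothing_window must be an odd count >= 1")


@dataclass
class TimeIntensityCurves:
    """Per-frame measurements of one subject; invalid samples are ``nan``."""

    times_s: np.ndarray
    vol_occluded_ml: np.ndarray
    vol_contralateral_ml: np.ndarray
    cr_percent: np.ndarray
    arterial_hu: np.ndarray
    venous_hu: np.ndarray
    av_ratio: np.ndarray
    arrival_s: float | None = None
    blood_hu: float = 40.0

    def __post_init__(self) -> None:
        n = len(self.times_s)
        for name in ("vol_occluded_ml", "vol_contralateral_ml", "cr_percent",
                     "arterial_hu", "venous_hu", "av_ratio"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ConfigurationError(f"{name} length {len(arr)} != {n} frames")
            setattr(self, name, arr)
        self.times_s = np.asarray(self.times_s, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times_s,
            "vol_occ_ml": self.vol_occluded_ml,
            "vol_con_ml": self.vol_contralateral_ml,
            "cr_pct": self.cr_percent,
            "arterial_hu": self.arterial_hu,
            "venous_hu": self.venous_hu,
            "av_ratio": self.av_ratio,
            "cr_valid": np.isfinite(self.cr_percent),
            "av_valid": np.isfinite(self.av_ratio),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   arrival_s: float | None = None,
                   blood_hu: float = 40.0) -> "TimeIntensityCurves":
        return cls(
            times_s=df["time_s"].to_numpy(),
            vol_occluded_ml=df["vol_occ_ml"].to_numpy(),
            vol_contralateral_ml=df["vol_con_ml"].to_numpy(),
            cr_percent=df["cr_pct"].to_numpy(),
            arterial_hu=df["arterial_hu"].to_numpy(),
            venous_hu=df["venous_hu"].to_numpy(),
            av_ratio=df["av_ratio"].to_numpy(),
            arrival_s=arrival_s,
            blood_hu=blood_hu,
        )


# ---------------------------------------------------------------------------
# primitive measurements
# ---------------------------------------------------------------------------

def roi_enhancement(volume: np.ndarray,
                    center_vox,
                    radius_mm: float,
                    voxel_size_mm) -> float:
    """Median intensity over a spherical ROI.

    A voxel contributes iff its centre lies within ``radius_mm`` of the ROI
    centre (world distance, anisotropic spacing respected). The median uses
    the lower-middle convention for even counts, so the value returned is
    always an observed voxel intensity.
    """
    volume = np.asarray(volume)
    spacing = np.asarray(voxel_size_mm, dtype=float)
    center = np.asarray(center_vox, dtype=float)
    lo = np.maximum(np.floor(center - radius_mm / spacing).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius_mm / spacing).astype(int) + 1,
                    np.asarray(volume.shape))
    if np.any(lo >= hi):
        raise GeometryError("ROI sphere does not intersect the image grid")
    sub = np.indices(tuple(hi - lo)).reshape(3, -1).T + lo
    d = np.linalg.norm((sub - center) * spacing, axis=1)
    sel = sub[d <= radius_mm]
    if len(sel) == 0:
        raise GeometryError("ROI sphere contains no voxel centre")
    values = np.sort(volume[tuple(sel.T)].ravel())
    return float(values[(len(values) - 1) // 2])


def av_ratio(arterial: float, venous: float, blood_hu: float = 40.0) -> float:
    """Blood-subtracted arteriovenous enhancement ratio.

    ``(arterial - blood) / (venous - blood)`` where the venous excess is
    positive; ``nan`` (invalid) otherwise. A negative arterial excess is
    clamped to 0 so the pre-contrast ratio is 0 rather than negative.
    """
    ven_excess = venous - blood_hu
    if not ven_excess > 0:
        return float("nan")
    art_excess = max(arterial - blood_hu, 0.0)
    return float(art_excess / ven_excess)


def av_ratio_curve(arterial_hu: np.ndarray,
                   venous_hu: np.ndarray,
                   blood_hu: float = 40.0) -> np.ndarray:
    a = np.asarray(arterial_hu, dtype=float) - blood_hu
    v = np.asarray(venous_hu, dtype=float) - blood_hu
    out = np.full(a.shape, np.nan)
    valid = v > 0
    out[valid] = np.clip(a[valid], 0.0, None) / v[valid]
    return out


def contrast_arrival(arterial_hu: np.ndarray,
                     times_s: np.ndarray,
                     params: ExtractionParams) -> float:
    """Contrast arrival time on the arterial curve.

    Baseline is the mean of the first two samples; arrival is where the curve
    first reaches baseline + ``arrival_delta_hu``, linearly interpolated
    between the crossing frame and its predecessor.
    """
    a = np.asarray(arterial_hu, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if len(a) < 3:
        raise ArrivalNotFoundError("need at least 3 frames to detect arrival")
    level = a[:2].mean() + params.arrival_delta_hu
    above = np.nonzero(a >= level)[0]
    if len(above) == 0:
        raise ArrivalNotFoundError(
            f"arterial curve never rises {params.arrival_delta_hu} HU above baseline")
    i = int(above[0])
    if i == 0:
        return float(t[0])
    frac = (level - a[i - 1]) / (a[i] - a[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def smooth_curve(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average used only for landmark finding (nan-skipping)."""
    if window <= 1:
        return np.asarray(values, dtype=float).copy()
    return (pd.Series(np.asarray(values, dtype=float))
            .rolling(window, center=True, min_periods=1).mean().to_numpy())


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def extract_tics(series: CTPSeries,
                 regions: RegionSpec,
                 seg: SegmentationParams | None = None,
                 ext: ExtractionParams | None = None) -> TimeIntensityCurves:
    """Compute all per-frame curves for one subject."""
    seg = seg if seg is not None else SegmentationParams()
    ext = ext if ext is not None else ExtractionParams()
    baseline = baseline_volume(series, seg)

    n = series.n_frames
    vol_occ = np.empty(n)
    vol_con = np.empty(n)
    cr = np.empty(n)
    art = np.empty(n)
    ven = np.empty(n)
    for i in range(n):
        frame = series.frame(i)
        m_occ = segment_vessels(frame, baseline, seg, regions.mca_occluded_mask)
        m_con = segment_vessels(frame, baseline, seg, regions.mca_contralateral_mask)
        vol_occ[i] = enhanced_vessel_volume(m_occ, series.voxel_size_mm)
        vol_con[i] = enhanced_vessel_volume(m_con, series.voxel_size_mm)
        cr[i] = collateral_ratio(vol_occ[i], vol_con[i], seg)
        art[i] = roi_enhancement(frame, regions.arterial_roi.center_vox,
                                 regions.arterial_roi.radius_mm, series.voxel_size_mm)
        ven[i] = roi_enhancement(frame, regions.venous_roi.center_vox,
                                 regions.venous_roi.radius_mm, series.voxel_size_mm)
    ratio = av_ratio_curve(art, ven, ext.blood_hu)
    arrival = contrast_arrival(art, series.times_s, ext)
    return TimeIntensityCurves(
        times_s=series.times_s.copy(),
        vol_occluded_ml=vol_occ,
        vol_contralateral_ml=vol_con,
        cr_percent=cr,
        arterial_hu=art,
        venous_hu=ven,
        av_ratio=ratio,
        arrival_s=arrival,
        blood_hu=ext.blood_hu,
    )


def time_invariant_mip(series: CTPSeries) -> np.ndarray:
    """Timing-invariant angiogram: voxelwise maximum over all frames."""
    if series.n_frames < 2:
        raise ConfigurationError("MIP over time needs at least 2 frames")
    return series.data.max(axis=0)


def mip_collateral_ratio(series: CTPSeries,
                         regions: RegionSpec,
                         seg: SegmentationParams | None = None) -> float:
    """CR of the time-invariant angiogram, segmented against the baseline."""
    seg = seg if seg is not None else SegmentationParams()
    baseline = baseline_volume(series, seg)
    mip = time_invariant_mip(series)
    m_occ = segment_vessels(mip, baseline, seg, regions.mca_occluded_mask)
    m_con = segment_vessels(mip, baseline, seg, regions.mca_contralateral_mask)
    return collateral_ratio(enhanced_vessel_volume(m_occ, series.voxel_size_mm),
                            enhanced_vessel_volume(m_con, series.voxel_size_mm),
                            seg)
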