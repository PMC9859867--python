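"""Vessel segmentation and the collateral ratio (CR).

The CR is 100 x (enhanced vessel volume in the occluded-side MCA region) /
(enhanced vessel volume in the contralateral MCA region), in percent.

Segmentation stand-in
---------------------
Vessels are identified here by *subtraction thresholding*: a voxel is vessel
iff it lies in the region mask and its enhancement over the pre-contrast
baseline volume is at least ``enhancement_threshold_hu``. This is a
deliberately simple, fully deterministic stand-in for a learned vessel
segmentation; the step is isolated behind :func:`segment_vessels` so any
segmentation producing a binary mask can be plugged in instead.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .series import CTPSeries, check_same_grid


@dataclass
class SegmentationParams:
    """Parameters of the subtraction-threshold vessel segmentation.

    Parameters
    ----------
    enhancement_threshold_hu
        Minimum enhancement over baseline (HU) for a voxel to count as
        vessel; the comparison is inclusive (>=).
    baseline_frames
        Number of leading pre-contrast frames averaged into the baseline.
    cr_cap
        Optional upper clamp for the CR in percent. Off by default: measured
        CRs well above 150% are meaningful (late venous-phase acquisitions),
        so no clamp is imposed unless explicitly requested.
    """

    enhancement_threshold_hu: float = 50.0
    baseline_frames: int = 2
    cr_cap: float | None = None

    def __post_init__(self) -> None:
        if self.enhancement_threshold_hu <= 0:
            raise ConfigurationError("enhancement_threshold_hu must be positive")
        if self.baseline_frames < 1:
            raise ConfigurationError("baseline_frames must be >= 1")
        if self.cr_cap is not None and self.cr_cap <= 0:
            raise ConfigurationError("cr_cap must be positive when set")


def baseline_volume(series: CTPSeries, params: SegmentationParams) -> np.ndarray:
    """Pre-contrast reference: mean of the first ``baseline_frames`` frames."""
    n = min(params.baseline_frames, series.n_frames)
    return series.data[:n].mean(axis=0)


def segment_vessels(frame: np.ndarray,
                    baseline: np.ndarray,
                    params: SegmentationParams,
                    region: np.ndarray) -> np.ndarray:
    """Binary vessel mask: in-region voxels enhanced >= threshold over baseline."""
    frame = np.asarray(frame)
    check_same_grid(frame, np.asarray(baseline))
    check_same_grid(frame, np.asarray(region))
    return (np.asarray(region, dtype=bool)
            & ((frame - baseline) >= params.enhancement_threshold_hu))


def enhanced_vessel_volume(mask: np.ndarray,
                           voxel_size_mm: tuple[float, float, float]) -> float:
    """Volume of a binary mask in millilitres (mm^3 / 1000)."""
    voxel_mm3 = float(np.prod(voxel_size_mm))
    return float(np.count_nonzero(mask)) * voxel_mm3 / 1000.0


def collateral_ratio(vol_occluded: float,
                     vol_contralateral: float,
                     params: SegmentationParams | None = None) -> float:
    """CR in percent; ``nan`` (invalid) when the contralateral volume is zero.

    Frames before contrast arrival have no contralateral enhanced volume and
    therefore no defined CR — the invalid marker propagates as a missing
    value through the curves, never as 0 or infinity.
    """
    if vol_contralateral < 0 or vol_occluded < 0:
        raise ConfigurationError("volumes must be non-negative")
    if vol_contralateral == 0.0:
        return float("nan")
    cr = 100.0 * vol_occluded / vol_contralateral
    if params is not None and params.cr_cap is not None:
        cr = min(cr, params.cr_cap)
    return cr
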