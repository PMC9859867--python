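"""Core in-memory containers: dynamic CT series and region specifications.

Conventions
-----------
* Volumes are numpy arrays indexed ``(x, y, z)``; a 4D series is ``(t, x, y, z)``.
* Times are seconds from the first frame of the dynamic series; frame 0 is t = 0.
* Voxel indexing is 0-based; world coordinates are ``index * voxel_size_mm``.
* Intensities are Hounsfield units (HU).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GridMismatchError


@dataclass
class CTPSeries:
    """A dynamic (4D) CT perfusion acquisition.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, nx, ny, nz)`` in HU.
    times_s
        Per-frame acquisition times in seconds, strictly increasing,
        relative to the first frame.
    voxel_size_mm
        Physical voxel size per axis ``(dx, dy, dz)`` in millimetres.
    """

    data: np.ndarray
    times_s: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim != 4:
            raise ConfigurationError(f"series data must be 4D, got {self.data.ndim}D")
        if len(self.times_s) != self.data.shape[0]:
            raise ConfigurationError(
                f"{self.data.shape[0]} frames but {len(self.times_s)} timestamps"
            )
        if len(self.times_s) >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ConfigurationError("frame times must be strictly increasing")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def frame(self, i: int) -> np.ndarray:
        return self.data[i]


@dataclass
class SphereROI:
    """A spherical region of interest: centre in voxel coordinates, radius in mm."""

    center_vox: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        self.center_vox = tuple(float(c) for c in self.center_vox)
        if self.radius_mm <= 0:
            raise ConfigurationError("ROI radius must be positive")


@dataclass
class RegionSpec:
    """Region definitions used for collateral scoring and enhancement sampling.

    The two MCA-territory masks must be non-empty and disjoint; the arterial
    ROI sits at the top of the intracranial carotid artery on the non-occluded
    side and the venous ROI at the confluence of the sinuses.
    """

    mca_occluded_mask: np.ndarray
    mca_contralateral_mask: np.ndarray
    arterial_roi: SphereROI
    venous_roi: SphereROI
    occlusion_side: str = "left"

    def __post_init__(self) -> None:
        self.mca_occluded_mask = np.asarray(self.mca_occluded_mask, dtype=bool)
        self.mca_contralateral_mask = np.asarray(self.mca_contralateral_mask, dtype=bool)
        if self.mca_occluded_mask.shape != self.mca_contralateral_mask.shape:
            raise GridMismatchError("MCA masks must share a grid")
        if not self.mca_occluded_mask.any() or not self.mca_contralateral_mask.any():
            raise ConfigurationError("MCA masks must be non-empty")
        if (self.mca_occluded_mask & self.mca_contralateral_mask).any():
            raise ConfigurationError("MCA masks must be disjoint")
        if self.occlusion_side not in ("left", "right"):
            raise ConfigurationError("occlusion_side must be 'left' or 'right'")


def check_same_grid(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise GridMismatchError(f"grid mismatch: {a.shape} vs {b.shape}")
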