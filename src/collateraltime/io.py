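"""File formats: NIfTI volumes/series, JSON sidecars, YAML run configuration.

NIfTI carries no per-frame acquisition-time field, so a 4D series travels
with a JSON sidecar holding the frame times; region specifications are
uint8 mask NIfTIs plus a JSON sidecar for the spherical ROIs and the
occlusion side.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .curves import ExtractionParams, TimeIntensityCurves
from .errors import ConfigurationError, FormatError
from .series import CTPSeries, RegionSpec, SphereROI
from .synthetic import PhantomConfig
from .vessels import SegmentationParams


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


# ---------------------------------------------------------------------------
# volumes and series
# ---------------------------------------------------------------------------

def write_volume(volume: np.ndarray, path, voxel_size_mm) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32),
                             _affine(voxel_size_mm)), str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float32), zooms


def write_mask(mask: np.ndarray, path, voxel_size_mm) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                             _affine(voxel_size_mm)), str(path))


def write_series(series: CTPSeries, path, sidecar_path) -> None:
    """4D NIfTI (x, y, z, t) plus a JSON sidecar with the frame times."""
    data = np.moveaxis(series.data, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(data, _affine(series.voxel_size_mm)), str(path))
    Path(sidecar_path).write_text(json.dumps(
        {"frame_times_s": [float(t) for t in series.times_s]}, indent=2))


def read_series(path, sidecar_path) -> CTPSeries:
    """Load a 4D series; frame count must match the sidecar timestamps."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D NIfTI, got {data.ndim}D")
    sidecar = json.loads(Path(sidecar_path).read_text())
    times = np.asarray(sidecar["frame_times_s"], dtype=float)
    if len(times) != data.shape[3]:
        raise FormatError(
            f"{path}: {data.shape[3]} frames but {len(times)} timestamps in sidecar")
    if len(times) >= 2 and not np.all(np.diff(times) > 0):
        raise FormatError(f"{sidecar_path}: frame times must be strictly increasing")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTPSeries(np.moveaxis(data, -1, 0), times, zooms)


# ---------------------------------------------------------------------------
# region specification
# ---------------------------------------------------------------------------

def write_region_spec(regions: RegionSpec, out_dir, voxel_size_mm, stem: str = "regions") -> None:
    out_dir = Path(out_dir)
    write_mask(regions.mca_occluded_mask, out_dir / f"{stem}_occluded.nii.gz", voxel_size_mm)
    write_mask(regions.mca_contralateral_mask, out_dir / f"{stem}_contralateral.nii.gz",
               voxel_size_mm)
    sidecar = {
        "occlusion_side": regions.occlusion_side,
        "arterial_roi": {"center_vox": list(regions.arterial_roi.center_vox),
                         "radius_mm": regions.arterial_roi.radius_mm},
        "venous_roi": {"center_vox": list(regions.venous_roi.center_vox),
                       "radius_mm": regions.venous_roi.radius_mm},
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))


def read_region_spec(out_dir, stem: str = "regions") -> RegionSpec:
    out_dir = Path(out_dir)
    occ, _ = read_volume(out_dir / f"{stem}_occluded.nii.gz")
    con, _ = read_volume(out_dir / f"{stem}_contralateral.nii.gz")
    meta = json.loads((out_dir / f"{stem}.json").read_text())
    return RegionSpec(
        mca_occluded_mask=occ > 0,
        mca_contralateral_mask=con > 0,
        arterial_roi=SphereROI(tuple(meta["arterial_roi"]["center_vox"]),
                               meta["arterial_roi"]["radius_mm"]),
        venous_roi=SphereROI(tuple(meta["venous_roi"]["center_vox"]),
                             meta["venous_roi"]["radius_mm"]),
        occlusion_side=meta["occlusion_side"],
    )


# ---------------------------------------------------------------------------
# curves CSV
# ---------------------------------------------------------------------------

def write_curves_csv(curves: TimeIntensityCurves, path) -> None:
    curves.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_curves_csv(path, arrival_s: float | None = None,
                    blood_hu: float = 40.0) -> TimeIntensityCurves:
    import pandas as pd
    return TimeIntensityCurves.from_frame(pd.read_csv(path), arrival_s, blood_hu)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration (see ``configs/demo.yaml``)."""

    n_subjects: int = 58
    seed: int = 7
    out_dir: str = "results"
    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    segmentation: SegmentationParams = dataclasses.field(default_factory=SegmentationParams)
    extraction: ExtractionParams = dataclasses.field(
        default_factory=lambda: ExtractionParams(smoothing_window=3))
    alignment_grid_step_s: float = 0.1
    aspects_noise_sd: float = 1.0
    nihss_noise_sd: float = 3.0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(_to_plain(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return run_config_from_dict(raw)


def run_config_from_dict(raw: dict) -> RunConfig:
    kwargs = dict(raw)
    try:
        if "phantom" in kwargs:
            kwargs["phantom"] = PhantomConfig(**_tupled(kwargs["phantom"]))
        if "segmentation" in kwargs:
            kwargs["segmentation"] = SegmentationParams(**kwargs["segmentation"])
        if "extraction" in kwargs:
            kwargs["extraction"] = ExtractionParams(**kwargs["extraction"])
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"invalid run configuration: {exc}") from exc


def _tupled(d: dict) -> dict:
    out = dict(d)
    for key in ("grid_shape", "voxel_size_mm"):
        if key in out:
            out[key] = tuple(out[key])
    return out


def save_run_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))
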