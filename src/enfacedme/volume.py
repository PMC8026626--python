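"""Volume / surface / en face containers and their file formats.

Volumes travel as multi-page TIFF (one page per B-scan) or NIfTI, both
backed by a JSON sidecar carrying the physical geometry.  Intensities are
floats in [0, 1] in memory and uint16 on disk.  Boundary-surface maps are
stored as wide CSV tables (one row per A-scan).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
import tifffile

from .geometry import VoxelGeometry

__all__ = [
    "OCTVolume",
    "SurfaceSet",
    "SlabSpec",
    "EnFaceImage",
    "SURFACE_ORDER",
    "read_volume",
    "write_volume",
    "read_surfaces",
    "write_surfaces",
]

#: canonical boundary names, vitreous side first
SURFACE_ORDER = ("ILM", "IPL/INL", "EZ", "RPE")

_SIDECAR_KEYS = ("lateral_spacing_um", "axial_spacing_um", "fovea_index")
_UINT16_MAX = np.float64(65535.0)


class FormatError(ValueError):
    """Raised when a file and its sidecar disagree or metadata is missing."""


@dataclass
class OCTVolume:
    """3D reflectivity volume, indexed ``(b_scan, a_scan, depth)``."""

    intensity: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3D (b_scan, a_scan, depth)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[2]

    @property
    def axial_extent_um(self) -> float:
        return self.n_depth * self.geometry.axial_spacing_um


@dataclass
class SurfaceSet:
    """Named per-A-scan boundary depth maps (μm from the volume top)."""

    surfaces: dict[str, np.ndarray]

    def __post_init__(self):
        self.surfaces = {k: np.asarray(v, dtype=float) for k, v in self.surfaces.items()}
        shapes = {v.shape for v in self.surfaces.values()}
        if len(shapes) > 1:
            raise ValueError(f"surface maps have inconsistent shapes: {shapes}")
        self.validate_order()

    def __getitem__(self, name: str) -> np.ndarray:
        return self.surfaces[name]

    def __contains__(self, name: str) -> bool:
        return name in self.surfaces

    @property
    def names(self) -> list[str]:
        return list(self.surfaces)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.surfaces.values())).shape

    def validate_order(self):
        """ILM < IPL/INL < EZ < RPE at every A-scan (where all are present)."""
        present = [n for n in SURFACE_ORDER if n in self.surfaces]
        for shallow, deep in zip(present, present[1:]):
            a, b = self.surfaces[shallow], self.surfaces[deep]
            ok = np.isnan(a) | np.isnan(b) | (a < b)
            if not np.all(ok):
                raise ValueError(f"surface ordering violated: {shallow} !< {deep}")


@dataclass(frozen=True)
class SlabSpec:
    """A depth slab relative to a named reference surface.

    ``offset_um`` is signed, negative toward the vitreous; ``depth_um`` is
    the slab thickness (0 selects the single nearest plane).
    """

    reference_surface: str
    offset_um: float
    depth_um: float
    projection: str = "mean"

    def __post_init__(self):
        if self.depth_um < 0:
            raise ValueError("depth_um must be >= 0")
        if self.projection not in ("mean", "min", "max"):
            raise ValueError(f"unknown projection {self.projection!r}")


@dataclass
class EnFaceImage:
    """2D projection of a slab; pixels align with the lateral A-scan grid."""

    pixels: np.ndarray
    geometry: VoxelGeometry
    slab: SlabSpec | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("en face pixels must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


# ---------------------------------------------------------------------------
# volume I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _geometry_to_dict(geometry: VoxelGeometry) -> dict:
    return {
        "lateral_spacing_um": list(geometry.lateral_spacing_um),
        "axial_spacing_um": geometry.axial_spacing_um,
        "fovea_index": list(geometry.fovea_index),
    }


def _geometry_from_dict(meta: dict, source: str) -> VoxelGeometry:
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise FormatError(f"{source}: sidecar is missing geometry keys {missing}")
    return VoxelGeometry(
        lateral_spacing_um=tuple(float(v) for v in meta["lateral_spacing_um"]),
        axial_spacing_um=float(meta["axial_spacing_um"]),
        fovea_index=tuple(int(v) for v in meta["fovea_index"]),
    )


def write_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF (``.tif``) or NIfTI (``.nii``/``.nii.gz``)
    at 16-bit depth, plus a JSON geometry sidecar. Returns the sidecar path."""
    path = Path(path)
    data = np.clip(volume.intensity, 0.0, 1.0)
    quantized = np.round(data * _UINT16_MAX).astype(np.uint16)
    if path.suffix in (".tif", ".tiff"):
        # one page per B-scan, page axes (a_scan, depth)
        tifffile.imwrite(path, quantized)
    elif path.name.endswith((".nii", ".nii.gz")):
        sp = volume.geometry
        affine = np.diag(
            [sp.lateral_spacing_um[0] / 1000.0, sp.lateral_spacing_um[1] / 1000.0,
             sp.axial_spacing_um / 1000.0, 1.0]
        )
        nib.save(nib.Nifti1Image(quantized, affine), str(path))
    else:
        raise FormatError(f"unsupported volume format: {path.name}")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(_geometry_to_dict(volume.geometry), indent=1))
    return sidecar


def read_volume(path: str | Path, sidecar: str | Path | None = None) -> OCTVolume:
    """Read a TIFF or NIfTI volume; geometry comes from the JSON sidecar."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(
            f"{path}: missing geometry sidecar {sidecar.name} "
            f"(required keys: {', '.join(_SIDECAR_KEYS)})"
        )
    geometry = _geometry_from_dict(json.loads(sidecar.read_text()), str(sidecar))
    if path.suffix in (".tif", ".tiff"):
        quantized = tifffile.imread(path)
    elif path.name.endswith((".nii", ".nii.gz")):
        quantized = np.asanyarray(nib.load(str(path)).dataobj)
    else:
        raise FormatError(f"unsupported volume format: {path.name}")
    if quantized.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {quantized.shape}")
    intensity = quantized.astype(np.float32) / np.float32(_UINT16_MAX)
    return OCTVolume(intensity=intensity, geometry=geometry)


# ---------------------------------------------------------------------------
# surface I/O


def write_surfaces(surfaces: SurfaceSet, path: str | Path) -> None:
    nb, na = surfaces.shape
    bb, aa = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    table = {"b_scan": bb.ravel(), "a_scan": aa.ravel()}
    for name, depth in surfaces.surfaces.items():
        table[name] = depth.ravel()
    pd.DataFrame(table).to_csv(path, index=False)


def read_surfaces(path: str | Path) -> SurfaceSet:
    df = pd.read_csv(path)
    nb = int(df["b_scan"].max()) + 1
    na = int(df["a_scan"].max()) + 1
    maps = {}
    for name in df.columns:
        if name in ("b_scan", "a_scan"):
            continue
        maps[name] = df[name].to_numpy(dtype=float).reshape(nb, na)
    return SurfaceSet(maps)
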