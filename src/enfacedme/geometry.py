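"""Voxel geometry and index <-> physical-coordinate conversions.

Conventions used throughout the package:

* volumes are indexed ``(b_scan, a_scan, depth)`` with depth increasing from
  the vitreous toward the choroid;
* all axial quantities are carried in micrometres and converted to voxel
  indices only at sampling time;
* the micrometre -> voxel rounding mode is *nearest, ties toward the
  vitreous* (i.e. a depth exactly halfway between two voxel centres maps to
  the shallower voxel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGeometry", "um_to_voxel", "voxel_to_um"]


def um_to_voxel(depth_um, axial_spacing_um: float):
    """Map axial depth(s) in μm to the nearest voxel index.

    Voxel ``z`` is taken to span ``[z*s, (z+1)*s)`` with centre
    ``(z + 0.5) * s``; the nearest-centre voxel is returned, ties resolved
    toward the vitreous (smaller index).
    """
    z = np.ceil(np.asarray(depth_um, dtype=float) / axial_spacing_um - 0.5)
    return z.astype(int) if z.ndim else int(z)


def voxel_to_um(index, axial_spacing_um: float):
    """Depth in μm of a voxel centre."""
    return (np.asarray(index, dtype=float) + 0.5) * axial_spacing_um


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical sampling grid of an OCT volume.

    Parameters
    ----------
    lateral_spacing_um
        ``(b_scan, a_scan)`` spacing, i.e. spacing along the slow and fast
        lateral axes in array order.
    axial_spacing_um
        Depth sampling in μm/voxel.
    fovea_index
        ``(b_scan, a_scan)`` integer position of the foveal centre.
    """

    lateral_spacing_um: tuple[float, float]
    axial_spacing_um: float
    fovea_index: tuple[int, int]

    def __post_init__(self):
        if min(self.lateral_spacing_um) <= 0 or self.axial_spacing_um <= 0:
            raise ValueError("voxel spacings must be positive")

    @property
    def pixel_area_mm2(self) -> float:
        return (self.lateral_spacing_um[0] / 1000.0) * (self.lateral_spacing_um[1] / 1000.0)

    def lateral_mm(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel lateral coordinates (mm) relative to the fovea.

        Returns ``(y_mm, x_mm)`` broadcastable grids for the b-scan and
        a-scan axes; pixel *centres* are at integer indices.
        """
        nb, na = shape
        if not (0 <= self.fovea_index[0] < nb and 0 <= self.fovea_index[1] < na):
            raise ValueError("fovea_index outside the lateral grid")
        y = (np.arange(nb) - self.fovea_index[0]) * self.lateral_spacing_um[0] / 1000.0
        x = (np.arange(na) - self.fovea_index[1]) * self.lateral_spacing_um[1] / 1000.0
        return y[:, None], x[None, :]

    def radius_mm(self, shape: tuple[int, int]) -> np.ndarray:
        """Distance of every pixel centre from the fovea, in mm."""
        y, x = self.lateral_mm(shape)
        return np.hypot(y, x)

    def depth_to_index(self, depth_um):
        return um_to_voxel(depth_um, self.axial_spacing_um)

    def index_to_depth(self, index):
        return voxel_to_um(index, self.axial_spacing_um)
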