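"""Boundary-surface segmentation, volume flattening and en face projection.

The en face construction mirrors the clinical workflow: segment the four
working boundaries (ILM, IPL/INL, EZ, RPE), axially shift every A-scan so a
chosen reference boundary sits on one constant row ("flattening"), then
project a depth slab — ``[reference + offset, reference + offset + depth)``
in μm — to a 2D image.

The segmenter is a transparent per-A-scan rule set (intensity thresholds,
bright-band rising edges, steepest-descent boundary finding) with lateral
median smoothing and ordering constraints.  It is designed for layered
phantom volumes, not as a clinical segmenter; A-scans where a boundary has
no local contrast (e.g. the IPL/INL inside the foveal pit, the EZ inside a
gap) are flagged and interpolated from their neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter

from .geometry import VoxelGeometry
from .volume import EnFaceImage, OCTVolume, SlabSpec, SurfaceSet

__all__ = [
    "FlattenedVolume",
    "SegmentationParams",
    "segment_surfaces",
    "flatten",
    "make_enface",
    "standard_slabs",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds of the rule-based segmenter (intensities in [0, 1])."""

    tissue_threshold: float = 0.15   # vitreous -> retina rise (ILM)
    bright_threshold: float = 0.70   # hyperreflective bands (EZ, RPE)
    min_drop: float = 0.08           # steepest-descent floor for IPL/INL
    axial_smooth_sigma: float = 0.8  # voxels
    median_window: int = 3           # lateral median filter, pixels
    ez_window_um: tuple[float, float] = (160.0, 10.0)  # EZ search above RPE
    ipl_inl_margin_um: float = 10.0  # skip below ILM before searching
    ipl_inl_ez_clearance_um: float = 100.0  # IPL/INL must sit this far above EZ


def _fill_invalid(depth: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill flagged A-scans by 1D linear interpolation along rows, then columns."""
    out = depth.astype(float).copy()
    out[~valid] = np.nan

    def _interp_rows(arr):
        for row in arr:
            bad = np.isnan(row)
            if bad.all() or not bad.any():
                continue
            idx = np.arange(row.size)
            row[bad] = np.interp(idx[bad], idx[~bad], row[~bad])

    _interp_rows(out)
    if np.isnan(out).any():
        _interp_rows(out.T)
    if np.isnan(out).any():
        raise ValueError("surface interpolation failed: too few valid A-scans")
    return out


def segment_surfaces(volume: OCTVolume, params: SegmentationParams | None = None) -> SurfaceSet:
    """Estimate ILM, IPL/INL, EZ and RPE depth maps (μm) from a volume.

    Raises ``ValueError`` when no boundaries are detectable (e.g. a
    constant-intensity volume).
    """
    params = params or SegmentationParams()
    s = volume.geometry.axial_spacing_um
    intensity = gaussian_filter1d(volume.intensity.astype(np.float32),
                                  params.axial_smooth_sigma, axis=2, mode="nearest")
    nb, na, nz = intensity.shape
    z_idx = np.arange(nz)

    # --- ILM: first rise above the tissue threshold ------------------------
    # raw intensity: the vitreous/retina step is high-contrast, and axial
    # smoothing would pull the crossing one voxel into the vitreous
    tissue = volume.intensity > params.tissue_threshold
    ilm_valid = tissue.any(axis=2)
    if not ilm_valid.any():
        raise ValueError("no detectable tissue band: cannot segment boundaries")
    ilm_idx = np.argmax(tissue, axis=2)

    # --- bright-band rising edges (EZ / RPE candidates) --------------------
    # raw intensity again: the EZ/RPE bands are far brighter than anything
    # around them, and smoothing across an adjacent fluid pocket can push
    # the first band voxel under the threshold
    bright = volume.intensity > params.bright_threshold
    rise = bright.copy()
    rise[..., 1:] &= ~bright[..., :-1]
    if not rise.any():
        raise ValueError("no hyperreflective band: cannot segment EZ/RPE")

    rpe_valid = rise.any(axis=2)
    rpe_idx = nz - 1 - np.argmax(rise[..., ::-1], axis=2)

    ez_lo = rpe_idx - int(round(params.ez_window_um[0] / s))
    ez_hi = rpe_idx - int(round(params.ez_window_um[1] / s))
    ez_rise = rise & (z_idx >= ez_lo[..., None]) & (z_idx < ez_hi[..., None])
    ez_valid = ez_rise.any(axis=2)
    ez_idx = nz - 1 - np.argmax(ez_rise[..., ::-1], axis=2)

    # --- IPL/INL: steepest intensity descent in the inner-retina window ----
    drop = intensity[..., :-1] - intensity[..., 1:]  # positive = darkening
    lo = ilm_idx + int(round(params.ipl_inl_margin_um / s))
    hi = ez_idx - int(round(params.ipl_inl_ez_clearance_um / s))
    in_window = (z_idx[: nz - 1] >= lo[..., None]) & (z_idx[: nz - 1] < hi[..., None])
    # the boundary is a descent out of the moderately reflective inner
    # retina; descents out of hyperreflective structures (ERM) don't qualify
    in_window &= intensity[..., :-1] < params.bright_threshold
    drop_w = np.where(in_window, drop, -np.inf)
    best = np.argmax(drop_w, axis=2)
    best_drop = np.take_along_axis(drop_w, best[..., None], axis=2)[..., 0]
    inl_valid = np.isfinite(best_drop) & (best_drop >= params.min_drop)
    inl_idx = best + 1  # boundary lies between z and z+1

    # --- assemble, interpolate failures, smooth, enforce ordering ----------
    maps = {
        "ILM": _fill_invalid(ilm_idx * s, ilm_valid),
        "IPL/INL": _fill_invalid(inl_idx * s, inl_valid & ilm_valid & ez_valid),
        "EZ": _fill_invalid(ez_idx * s, ez_valid),
        "RPE": _fill_invalid(rpe_idx * s, rpe_valid),
    }
    # despike: isolated columns (fold lines, speckle) that disagree with the
    # local neighbourhood by several voxels take the neighbourhood value.
    # The ILM is left untouched: its raw threshold crossing is exact, and
    # smoothing would blur genuinely steep relief (SRF dome walls, membrane
    # edges).
    for k, v in maps.items():
        if k == "ILM":
            continue
        local = median_filter(v, size=7, mode="nearest")
        spike = np.abs(v - local) > 4 * s
        v[spike] = local[spike]
        if params.median_window > 1:
            maps[k] = median_filter(v, size=params.median_window, mode="nearest")
    # monotone ordering, at least one voxel apart
    order = ["ILM", "IPL/INL", "EZ", "RPE"]
    for shallow, deep in zip(order, order[1:]):
        maps[deep] = np.maximum(maps[deep], maps[shallow] + s)
    return SurfaceSet(maps)


@dataclass
class FlattenedVolume:
    """Volume axially shifted so one boundary sits at a constant row.

    Out-of-range voxels are NaN.  ``surfaces`` holds all boundary maps in
    the shifted frame, so flattening is idempotent and composable.
    """

    intensity: np.ndarray
    geometry: VoxelGeometry
    reference_surface: str
    reference_row: int
    surfaces: SurfaceSet

    @property
    def shape(self):
        return self.intensity.shape


def flatten(volume, surfaces: SurfaceSet, reference: str) -> FlattenedVolume:
    """Shift every A-scan so ``reference`` lies at one constant depth row.

    ``volume`` may be an :class:`OCTVolume` or an already-flattened volume
    (flattening twice along the same surface is a no-op).
    """
    if reference not in surfaces:
        raise KeyError(f"reference surface {reference!r} not in surface set")
    ref_um = surfaces[reference]
    if not np.all(np.isfinite(ref_um)):
        raise ValueError(f"reference surface {reference!r} contains non-finite values")
    s = volume.geometry.axial_spacing_um
    nz = volume.intensity.shape[2]
    ref_idx = np.ceil(ref_um / s - 0.5).astype(int)
    r0 = int(np.median(ref_idx))
    shift = ref_idx - r0

    zz = np.arange(nz)[None, None, :] + shift[..., None]
    inside = (zz >= 0) & (zz < nz)
    gathered = np.take_along_axis(volume.intensity.astype(np.float32),
                                  np.clip(zz, 0, nz - 1), axis=2)
    gathered[~inside] = np.nan

    shifted = SurfaceSet({k: v - shift * s for k, v in surfaces.surfaces.items()})
    return FlattenedVolume(
        intensity=gathered,
        geometry=volume.geometry,
        reference_surface=reference,
        reference_row=r0,
        surfaces=shifted,
    )


def make_enface(flattened: FlattenedVolume, slab: SlabSpec) -> EnFaceImage:
    """Project a slab of a flattened volume to an en face image.

    The slab covers ``[reference + offset, reference + offset + depth)``;
    ``depth_um = 0`` selects the single nearest plane.  NaN (out-of-range)
    voxels are excluded from the projection; pixels with no valid voxel in
    the slab are NaN.
    """
    if slab.reference_surface != flattened.reference_surface:
        raise ValueError(
            f"slab references {slab.reference_surface!r} but volume is "
            f"flattened on {flattened.reference_surface!r}"
        )
    s = flattened.geometry.axial_spacing_um
    nz = flattened.intensity.shape[2]
    r0 = flattened.reference_row
    i0 = r0 + int(np.ceil(slab.offset_um / s - 0.5))
    if slab.depth_um == 0:
        i1 = i0 + 1
    else:
        i1 = r0 + int(np.ceil((slab.offset_um + slab.depth_um) / s - 0.5))
        i1 = max(i1, i0 + 1)
    if i1 <= 0 or i0 >= nz:
        raise ValueError(
            f"slab rows [{i0}, {i1}) lie entirely outside the volume (nz={nz})"
        )
    block = flattened.intensity[:, :, max(i0, 0):min(i1, nz)]
    with np.errstate(invalid="ignore"):
        if slab.projection == "mean":
            pixels = np.nanmean(block, axis=2)
        elif slab.projection == "min":
            pixels = np.nanmin(block, axis=2)
        else:
            pixels = np.nanmax(block, axis=2)
    return EnFaceImage(pixels=pixels, geometry=flattened.geometry, slab=slab)


def standard_slabs() -> dict[str, SlabSpec]:
    """The four working slabs.

    * ``surface``  — single plane at the ILM (retinal surface / ERM view);
    * ``segment1`` — 50 μm below the IPL/INL boundary (INL + OPL/Henle);
    * ``segment2`` — 50 μm slab whose inferior face is 70 μm above the RPE
      (the ONL), i.e. offset −120 μm, depth 50 μm;
    * ``subretinal`` — the 70 μm immediately above the RPE, used for
      subretinal-fluid detection.
    """
    return {
        "surface": SlabSpec("ILM", 0.0, 0.0),
        "segment1": SlabSpec("IPL/INL", 0.0, 50.0),
        "segment2": SlabSpec("RPE", -120.0, 50.0),
        "subretinal": SlabSpec("RPE", -70.0, 70.0),
    }
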