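"""Per-eye structural biomarkers: CST, EZ disruption, ERM, MDRF, logMAR.

* CST — central subfield thickness: mean ILM→RPE distance over the 1-mm
  ETDRS foveal circle.
* EZ disruption — loss of the hyperreflective ellipsoid-zone band within a
  3-mm width centred at the fovea, judged on the horizontal and vertical
  B-scans through the fovea.
* ERM — irregular hyperreflective membrane-like structures on the retinal
  surface en face image.
* MDRF — maximum depth of retinal folds: the deepest sub-ILM en face slab
  on which traction fold lines are still visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .segment import FlattenedVolume, flatten, make_enface, segment_surfaces, standard_slabs
from .taxonomy import ClassifyParams, ETDRSGrid, NotDMEError, classify_eye
from .volume import EnFaceImage, OCTVolume, SlabSpec, SurfaceSet

__all__ = [
    "central_subfield_thickness",
    "ez_disruption",
    "detect_erm",
    "max_depth_retinal_folds",
    "decimal_to_logmar",
    "measure_eye",
]


def central_subfield_thickness(surfaces: SurfaceSet, geometry,
                               grid: ETDRSGrid | None = None) -> float:
    """Mean retinal thickness (RPE − ILM, μm) over the ETDRS foveal circle."""
    grid = grid or ETDRSGrid()
    ilm, rpe = surfaces["ILM"], surfaces["RPE"]
    if not (np.all(np.isfinite(ilm)) and np.all(np.isfinite(rpe))):
        raise ValueError("ILM and RPE maps must be finite")
    zone = geometry.radius_mm(ilm.shape) <= grid.foveal_radius_mm
    if not zone.any():
        raise ValueError("no A-scan falls inside the foveal circle")
    return float(np.mean((rpe - ilm)[zone]))


def ez_disruption(volume: OCTVolume, surfaces: SurfaceSet,
                  grid: ETDRSGrid | None = None, *, half_width_mm: float = 1.5,
                  band_halfwidth_um: float = 10.0, gap_min_um: float = 50.0,
                  floor_fraction: float = 0.5) -> bool:
    """Judge EZ disruption on the foveal horizontal and vertical B-scans.

    Along each scan, within ±``half_width_mm`` of the fovea, the mean
    intensity in a ±``band_halfwidth_um`` band around the EZ surface is
    compared to ``floor_fraction`` × the median band intensity; a
    contiguous sub-floor run of lateral extent ≥ ``gap_min_um`` on either
    scan is a disruption.
    """
    fb, fa = volume.geometry.fovea_index
    nb, na, nz = volume.shape
    if not (0 <= fb < nb and 0 <= fa < na):
        raise ValueError("fovea index outside the volume")
    zc = (np.arange(nz) + 0.5) * volume.geometry.axial_spacing_um

    scans = (
        (volume.intensity[fb, :, :], surfaces["EZ"][fb, :], volume.geometry.lateral_spacing_um[1], fa),
        (volume.intensity[:, fa, :], surfaces["EZ"][:, fa], volume.geometry.lateral_spacing_um[0], fb),
    )
    for img, ez_um, spacing, center in scans:
        n = img.shape[0]
        lateral_mm = (np.arange(n) - center) * spacing / 1000.0
        window = np.abs(lateral_mm) <= half_width_mm
        in_band = np.abs(zc[None, :] - ez_um[:, None]) <= band_halfwidth_um
        with np.errstate(invalid="ignore"):
            band_mean = np.where(
                in_band.any(axis=1),
                np.sum(img * in_band, axis=1) / np.maximum(in_band.sum(axis=1), 1),
                np.nan,
            )
        vals = band_mean[window]
        if not np.isfinite(vals).any():
            raise ValueError("EZ band fell outside the volume on a foveal B-scan")
        floor = floor_fraction * np.nanmedian(vals)
        dark = vals < floor
        # longest contiguous sub-floor run, in μm
        run, longest = 0, 0
        for flag in dark:
            run = run + 1 if flag else 0
            longest = max(longest, run)
        if longest * spacing >= gap_min_um:
            return True
    return False


def detect_erm(surface_image: EnFaceImage, *, brightness_factor: float = 1.5,
               min_fraction: float = 0.02) -> bool:
    """ERM present iff hyperreflective pixels (> ``brightness_factor`` ×
    median) cover at least ``min_fraction`` of the surface en face frame."""
    pixels = surface_image.pixels
    finite = np.isfinite(pixels)
    med = float(np.median(pixels[finite]))
    bright = finite & (pixels > brightness_factor * med)
    return bool(bright.sum() >= min_fraction * finite.sum())


def max_depth_retinal_folds(flattened: FlattenedVolume, *, step_um: float = 10.0,
                            max_depth_um: float = 200.0, dark_fraction: float = 0.85,
                            min_eccentricity: float = 0.9,
                            min_length_mm: float = 1.0) -> float:
    """Maximum depth of retinal folds on sub-ILM en face slabs.

    Steps ``step_um`` slabs down from the ILM and looks for fold lines —
    elongated (eccentricity ≥ ``min_eccentricity``, major axis ≥
    ``min_length_mm``) hyporeflective components darker than
    ``dark_fraction`` × the slab median.  Returns the largest depth at
    which folds are still detected, 0 when none are visible at the ILM.
    """
    if flattened.reference_surface != "ILM":
        raise ValueError("MDRF requires a volume flattened at the ILM")
    px_mm = min(flattened.geometry.lateral_spacing_um) / 1000.0
    min_len_px = min_length_mm / px_mm
    deepest = 0.0
    misses = 0
    for d in np.arange(0.0, max_depth_um + step_um, step_um):
        try:
            # thin slab centred on d: folds count as visible *at* this depth
            img = make_enface(flattened, SlabSpec("ILM", d - step_um / 2, step_um))
        except ValueError:  # slab walked out of the volume
            break
        pixels = img.pixels
        finite = np.isfinite(pixels)
        if not finite.any():
            break
        dark = finite & (pixels < dark_fraction * np.median(pixels[finite]))
        found = False
        for rp in measure.regionprops(measure.label(dark, connectivity=2)):
            if rp.eccentricity >= min_eccentricity and rp.axis_major_length >= min_len_px:
                found = True
                break
        if found:
            deepest = float(d)
            misses = 0
        else:
            misses += 1
            if misses >= 2:
                break
    return deepest


def decimal_to_logmar(decimal_va: float) -> float:
    """Convert decimal visual acuity to logMAR (= −log10(decimal))."""
    if decimal_va <= 0:
        raise ValueError("decimal visual acuity must be positive")
    return float(-np.log10(decimal_va))


def measure_eye(volume: OCTVolume, surfaces: SurfaceSet | None = None,
                params: ClassifyParams | None = None) -> dict:
    """Classify one eye and extract all structural biomarkers.

    Returns a dict with the taxonomy label (None when no fluid is found),
    ``cst_um``, ``ez_disrupted``, ``erm_present`` and ``mdrf_um`` (None
    when no ERM is detected), plus the classification provenance.
    """
    if surfaces is None:
        surfaces = segment_surfaces(volume)
    try:
        classification, provenance = classify_eye(volume, params, surfaces=surfaces)
        label = classification.label
        observed = classification.observed_type
    except NotDMEError:
        label, observed, provenance = None, None, {"not_dme": True}

    flat_ilm = flatten(volume, surfaces, "ILM")
    surface_img = make_enface(flat_ilm, standard_slabs()["surface"])
    erm = detect_erm(surface_img)
    mdrf = max_depth_retinal_folds(flat_ilm) if erm else None
    return {
        "type_label": label,
        "observed_type": observed,
        "cst_um": central_subfield_thickness(surfaces, volume.geometry),
        "ez_disrupted": ez_disruption(volume, surfaces),
        "erm_present": erm,
        "mdrf_um": mdrf,
        "provenance": provenance,
    }
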