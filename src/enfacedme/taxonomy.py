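"""ETDRS-grid fluid-extent classification and the DME taxonomy.

The retina is read in two depth slabs: Segment 1 (inner nuclear layer +
outer plexiform/Henle complex, flattened on the IPL/INL boundary) and
Segment 2 (outer nuclear layer, flattened on the RPE).  Fluid extent in
Segment 1 is graded against the ETDRS circles — foveal cystoid space (FC,
all fluid within the 1-mm foveal circle), parafoveal cystoid space (PC,
within the 3-mm parafoveal circle), diffuse fluid (DF, beyond it), or no
fluid (NF).  Segment 2 is graded for presence of fluid only, plus a
subretinal-fluid (SF) flag.  Crossing the 4 Segment-1 states with the 4
Segment-2 renderings (NF, DF, SF, DF+SF) and removing the fluid-free state
yields 15 combination labels, of which 5 occur as recognised clinical
types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fluid import DetectionParams, FluidMask, detect_fluid, detect_srf
from .segment import flatten, make_enface, segment_surfaces, standard_slabs
from .volume import OCTVolume, SurfaceSet

__all__ = [
    "ETDRSGrid",
    "SegmentFinding",
    "DMEClassification",
    "NotDMEError",
    "SEGMENT1_STATES",
    "SEGMENT2_STATES",
    "OBSERVED_TYPES",
    "enumerate_taxonomy",
    "classify_extent",
    "combine",
    "parse_label",
    "classify_eye",
]

SEGMENT1_STATES = ("NF", "FC", "PC", "DF")
SEGMENT2_STATES = ("NF", "DF")
#: Segment-2 column renderings: no fluid, diffuse fluid, subretinal fluid
#: alone, diffuse fluid with subretinal fluid.
SEGMENT2_RENDERINGS = ("NF", "DF", "SF", "DF+SF")
OBSERVED_TYPES = ("FC/NF", "PC/NF", "PC/DF", "DF/DF", "DF/DF+SF")


class NotDMEError(ValueError):
    """Signals the all-no-fluid combination, outside the (center-involving) taxonomy."""


@dataclass(frozen=True)
class ETDRSGrid:
    """ETDRS macular circles: 1-mm foveal and 3-mm parafoveal diameters."""

    foveal_radius_mm: float = 0.5
    parafoveal_radius_mm: float = 1.5


@dataclass(frozen=True)
class SegmentFinding:
    segment1_state: str
    segment2_state: str
    srf_present: bool

    def __post_init__(self):
        if self.segment1_state not in SEGMENT1_STATES:
            raise ValueError(f"invalid Segment 1 state {self.segment1_state!r}")
        if self.segment2_state not in SEGMENT2_STATES:
            raise ValueError(f"invalid Segment 2 state {self.segment2_state!r}")


@dataclass(frozen=True)
class DMEClassification:
    label: str
    finding: SegmentFinding
    observed_type: str | None = None


def _segment2_rendering(segment2_state: str, srf_present: bool) -> str:
    if segment2_state == "DF":
        return "DF+SF" if srf_present else "DF"
    return "SF" if srf_present else "NF"


def enumerate_taxonomy() -> list[str]:
    """All combination labels: 4 x 4 renderings minus the fluid-free state = 15."""
    labels = []
    for s1 in SEGMENT1_STATES:
        for s2r in SEGMENT2_RENDERINGS:
            if s1 == "NF" and s2r == "NF":
                continue
            labels.append(f"{s1}/{s2r}")
    return labels


def combine(segment1_state: str, segment2_state: str, srf_present: bool) -> DMEClassification:
    """Combine per-segment states into a taxonomy label.

    Raises :class:`NotDMEError` for the all-no-fluid combination: the
    taxonomy covers center-involving DME only.
    """
    finding = SegmentFinding(segment1_state, segment2_state, bool(srf_present))
    s2r = _segment2_rendering(segment2_state, srf_present)
    if segment1_state == "NF" and s2r == "NF":
        raise NotDMEError("no fluid in either segment and no SRF: not DME")
    label = f"{segment1_state}/{s2r}"
    observed = label if label in OBSERVED_TYPES else None
    return DMEClassification(label=label, finding=finding, observed_type=observed)


def parse_label(label: str) -> SegmentFinding:
    """Parse a taxonomy label like ``"PC/DF"`` or ``"DF/DF + SF"``."""
    compact = label.replace(" ", "")
    try:
        s1, s2r = compact.split("/")
    except ValueError:
        raise ValueError(f"malformed taxonomy label {label!r}") from None
    if s1 not in SEGMENT1_STATES or s2r not in SEGMENT2_RENDERINGS:
        raise ValueError(f"unknown taxonomy label {label!r}")
    segment2_state = "DF" if s2r in ("DF", "DF+SF") else "NF"
    srf = s2r in ("SF", "DF+SF")
    if s1 == "NF" and s2r == "NF":
        raise ValueError("NF/NF is not a DME label")
    return SegmentFinding(s1, segment2_state, srf)


def canonical_label(label: str) -> str:
    f = parse_label(label)
    return combine(f.segment1_state, f.segment2_state, f.srf_present).label


def classify_extent(mask: FluidMask, grid: ETDRSGrid | None = None,
                    tolerance_px: int = 0) -> str:
    """Grade fluid extent against the ETDRS circles.

    NF if the mask is empty; FC if every fluid pixel centre lies within the
    foveal radius; PC if not FC but all within the parafoveal radius; DF
    otherwise.  ``tolerance_px`` isolated out-of-zone pixels are ignored
    (default strict).
    """
    grid = grid or ETDRSGrid()
    m = mask.mask
    if not m.any():
        return "NF"
    r = mask.geometry.radius_mm(m.shape)
    if r.shape != m.shape:
        raise ValueError("mask and grid geometry shapes differ")
    rr = r[m]
    if np.count_nonzero(rr > grid.foveal_radius_mm) <= tolerance_px:
        return "FC"
    if np.count_nonzero(rr > grid.parafoveal_radius_mm) <= tolerance_px:
        return "PC"
    return "DF"


@dataclass
class ClassifyParams:
    """End-to-end classification parameters."""

    fluid: DetectionParams = field(default_factory=DetectionParams)
    srf: DetectionParams = field(default_factory=lambda: DetectionParams(min_area_mm2=0.05))
    grid: ETDRSGrid = field(default_factory=ETDRSGrid)
    tolerance_px: int = 0


def classify_eye(
    volume: OCTVolume,
    params: ClassifyParams | None = None,
    surfaces: SurfaceSet | None = None,
) -> tuple[DMEClassification, dict]:
    """Run the full per-eye pipeline and return (classification, provenance).

    Stages: surface segmentation -> flattening on IPL/INL and RPE ->
    standard slabs -> fluid detection in Segments 1/2 and the subretinal
    slab -> ETDRS extent grading -> taxonomy combination.  Precomputed
    ``surfaces`` (e.g. phantom ground truth) bypass segmentation.

    Raises :class:`NotDMEError` when no fluid is found anywhere.
    """
    params = params or ClassifyParams()
    provenance: dict = {"stages": []}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except NotDMEError:
            raise
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"classification stage {name!r} failed: {exc}") from exc

    if surfaces is None:
        surfaces = _stage("segment_surfaces", segment_surfaces, volume)
        provenance["surface_source"] = "segmented"
    else:
        provenance["surface_source"] = "provided"

    slabs = standard_slabs()
    flat_inl = _stage("flatten[IPL/INL]", flatten, volume, surfaces, "IPL/INL")
    flat_rpe = _stage("flatten[RPE]", flatten, volume, surfaces, "RPE")

    seg1_img = _stage("enface[segment1]", make_enface, flat_inl, slabs["segment1"])
    seg2_img = _stage("enface[segment2]", make_enface, flat_rpe, slabs["segment2"])
    sub_img = _stage("enface[subretinal]", make_enface, flat_rpe, slabs["subretinal"])

    seg1_mask = _stage("detect_fluid[segment1]", detect_fluid, seg1_img, params.fluid)
    seg2_mask = _stage("detect_fluid[segment2]", detect_fluid, seg2_img, params.fluid)
    srf_mask, srf_present = _stage("detect_srf", detect_srf, sub_img, params.srf)

    s1 = classify_extent(seg1_mask, params.grid, params.tolerance_px)
    s2_extent = classify_extent(seg2_mask, params.grid, params.tolerance_px)
    s2 = "NF" if s2_extent == "NF" else "DF"  # Segment 2: presence/absence only

    provenance.update(
        {
            "stages": [
                "segment_surfaces", "flatten", "make_enface",
                "detect_fluid", "detect_srf", "classify_extent", "combine",
            ],
            "slabs": {k: vars(v) for k, v in slabs.items()},
            "fluid_params": vars(params.fluid),
            "srf_params": vars(params.srf),
            "segment1_area_mm2": float(seg1_mask.total_area_mm2),
            "segment2_area_mm2": float(seg2_mask.total_area_mm2),
            "segment2_extent": s2_extent,
            "srf_area_mm2": float(srf_mask.total_area_mm2),
            "tolerance_px": params.tolerance_px,
        }
    )
    classification = combine(s1, s2, srf_present)
    return classification, provenance
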