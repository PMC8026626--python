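"""Parameterised 3D macular OCT phantoms with exact ground truth.

A phantom is a layered reflectivity model on a regular ``(b_scan, a_scan,
depth)`` grid.  From the vitreous down: ILM, inner retina (RNFL/GCL/IPL),
INL, OPL + Henle complex, ONL, photoreceptor band (ELM -> EZ -> outer
segments) and RPE, painted as piecewise-constant bands between analytic
boundary surfaces.  The foveal pit is modelled as a Gaussian collapse of
the inner layers (the INL vanishes at the foveal centre while Henle's
layer thickens), so the anatomy that makes foveal cystoid spaces visible in
the Segment-1 slab is present.

Optional pathology:

* intraretinal fluid pockets (cystoid clusters or diffuse sheets) confined
  to the Henle, INL or ONL bands;
* a subretinal fluid dome that lifts the neurosensory retina off the RPE;
* an epiretinal membrane: an irregular hyperreflective cap on the ILM plus
  retinal folds, rendered as thin hyporeflective lines below the ILM whose
  contrast decays with depth and vanishes at the true fold depth (this
  keeps the maximum depth of retinal folds exactly defined);
* an ellipsoid-zone gap of configurable lateral extent;
* multiplicative gamma speckle.

Ground truth (surfaces, fluid masks, type label, biomarkers) is recorded
exactly as painted, which makes the phantoms usable as oracles for every
downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import VoxelGeometry
from .volume import OCTVolume, SurfaceSet
from .taxonomy import OBSERVED_TYPES, NotDMEError, combine

__all__ = [
    "FluidPocket",
    "ErmSpec",
    "EzGapSpec",
    "SrfSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "preset_cohort",
    "preset_spec",
    "verify_truth",
    "CONTROL_LABEL",
]

CONTROL_LABEL = "control"

FLUID_LAYERS = ("henle", "inl", "onl", "subretinal")

DEFAULT_THICKNESSES_UM = {
    "inner_retina": 100.0,  # ILM -> IPL/INL
    "inl": 35.0,
    "opl_henle": 40.0,
    "onl": 50.0,
    "photoreceptor": 70.0,  # ELM -> RPE
    "rpe": 20.0,
    "ez_band": 20.0,
    "elm_ez_gap": 25.0,
}

DEFAULT_INTENSITIES = {
    "vitreous": 0.02,
    "erm": 0.85,
    "inner_retina": 0.50,
    "inl": 0.27,
    "opl_henle": 0.55,
    "onl": 0.25,
    "elm_ez_gap": 0.30,
    "ez": 0.90,
    "outer_segment": 0.35,
    "rpe": 0.90,
    "choroid": 0.20,
    "fluid": 0.05,
}


@dataclass(frozen=True)
class FluidPocket:
    """A fluid pocket confined to one retinal band.

    ``cystoid_cluster`` renders a petaloid cluster of round cysts (a centre
    cyst plus a ring of six) whose footprint stays within ``radius_mm`` of
    ``center_mm``; ``diffuse_sheet`` fills the whole band over a disk.
    ``height_um = None`` fills the full band thickness.
    """

    layer: str
    shape: str
    radius_mm: float
    center_mm: tuple[float, float] = (0.0, 0.0)
    height_um: float | None = None

    def __post_init__(self):
        if self.layer not in FLUID_LAYERS:
            raise ValueError(f"unknown fluid layer {self.layer!r}")
        if self.shape not in ("cystoid_cluster", "diffuse_sheet"):
            raise ValueError(f"unknown pocket shape {self.shape!r}")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass(frozen=True)
class ErmSpec:
    fold_depth_um: float = 60.0   # depth below ILM where folds vanish (the true MDRF)
    fold_spacing_mm: float = 0.3
    coverage: float = 0.35        # fraction of the frame covered by membrane patches
    thickness_um: float = 12.0
    fold_contrast: float = 0.55


@dataclass(frozen=True)
class EzGapSpec:
    radius_mm: float
    center_mm: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class SrfSpec:
    """Subretinal fluid bleb: a flat-topped dome of height ``height_um``
    whose wall rises over the outer ``rim_fraction`` of the radius (SRF
    pockets detach steeply, so the footprint is close to the full disk)."""

    radius_mm: float = 0.7
    height_um: float = 60.0
    rim_fraction: float = 0.25
    center_mm: tuple[float, float] = (0.0, 0.0)


@dataclass
class PhantomSpec:
    """Full description of one phantom acquisition."""

    lateral_extent_mm: tuple[float, float] = (6.0, 6.0)
    n_ascans: tuple[int, int] = (128, 128)  # (b_scans, a_scans/line); 512 x 256 matches acquisition
    axial_spacing_um: float = 5.0
    axial_extent_um: float = 1500.0
    rpe_depth_um: float | None = None       # default: 60% of the axial extent
    fovea_center: tuple[int, int] | None = None
    layer_thicknesses_um: dict = field(default_factory=lambda: dict(DEFAULT_THICKNESSES_UM))
    intensity_map: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    pit_sigma_mm: float = 0.35
    pit_inner_fraction: float = 0.85        # fraction of inner retina lost at the pit centre
    pit_inl_collapse: float = 1.0           # fraction of the INL lost at the pit centre
    pit_henle_gain_um: float = 30.0         # Henle thickening at the pit centre
    fluid_config: list[FluidPocket] = field(default_factory=list)
    erm_config: ErmSpec | None = None
    ez_gap_config: EzGapSpec | None = None
    srf_config: SrfSpec | None = None
    pvd_label: str = "complete"
    noise_amplitude: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if any(t <= 0 for t in self.layer_thicknesses_um.values()):
            raise ValueError("all layer thicknesses must be positive")
        if self.rpe_depth_um is None:
            self.rpe_depth_um = 0.6 * self.axial_extent_um
        if self.fovea_center is None:
            self.fovea_center = (self.n_ascans[0] // 2, self.n_ascans[1] // 2)

    @property
    def geometry(self) -> VoxelGeometry:
        nb, na = self.n_ascans
        return VoxelGeometry(
            lateral_spacing_um=(
                self.lateral_extent_mm[0] * 1000.0 / nb,
                self.lateral_extent_mm[1] * 1000.0 / na,
            ),
            axial_spacing_um=self.axial_spacing_um,
            fovea_index=self.fovea_center,
        )


@dataclass
class PhantomTruth:
    """Exact ground truth recorded while painting a phantom."""

    surfaces: SurfaceSet
    fluid_mask: np.ndarray
    srf_mask: np.ndarray
    type_label: str
    erm_present: bool
    mdrf_true_um: float
    ez_disrupted: bool
    pvd_label: str


def _cluster_footprint(pocket: FluidPocket, y_mm: np.ndarray, x_mm: np.ndarray) -> np.ndarray:
    """Lateral footprint of a pocket (bool grid)."""
    cy, cx = pocket.center_mm
    dy, dx = y_mm - cy, x_mm - cx
    if pocket.shape == "diffuse_sheet":
        return dy**2 + dx**2 <= pocket.radius_mm**2
    # petaloid cluster: centre cyst + ring of six, all within radius_mm
    r_blob = 0.35 * pocket.radius_mm
    footprint = dy**2 + dx**2 <= (0.40 * pocket.radius_mm) ** 2
    ring = 0.60 * pocket.radius_mm
    for angle in np.arange(6) * (np.pi / 3):
        by, bx = ring * np.sin(angle), ring * np.cos(angle)
        footprint |= (dy - by) ** 2 + (dx - bx) ** 2 <= r_blob**2
    return footprint


def _pocket_extent_mm(pocket: FluidPocket) -> float:
    """Maximum distance from the fovea reached by a pocket's footprint."""
    offset = float(np.hypot(*pocket.center_mm))
    reach = pocket.radius_mm if pocket.shape == "diffuse_sheet" else 0.95 * pocket.radius_mm
    return offset + reach


def _derive_type_label(spec: PhantomSpec) -> str:
    seg1 = [p for p in spec.fluid_config if p.layer in ("henle", "inl")]
    seg2 = [p for p in spec.fluid_config if p.layer == "onl"]
    srf = spec.srf_config is not None or any(
        p.layer == "subretinal" for p in spec.fluid_config
    )
    if not seg1:
        s1 = "NF"
    else:
        extent = max(_pocket_extent_mm(p) for p in seg1)
        s1 = "FC" if extent <= 0.5 else ("PC" if extent <= 1.5 else "DF")
    s2 = "DF" if seg2 else "NF"
    try:
        return combine(s1, s2, srf).label
    except NotDMEError:
        return CONTROL_LABEL


def generate_phantom(spec: PhantomSpec) -> tuple[OCTVolume, PhantomTruth]:
    """Render a phantom volume and its exact ground truth.

    Identical spec + seed produce identical volumes.  Raises ``ValueError``
    when a fluid pocket has no room in its layer band or the retina does
    not fit the axial extent.
    """
    geom = spec.geometry
    nb, na = spec.n_ascans
    nz = int(round(spec.axial_extent_um / spec.axial_spacing_um))
    t = spec.layer_thicknesses_um
    iv = spec.intensity_map
    rng = np.random.default_rng(spec.seed)

    y_mm, x_mm = geom.lateral_mm((nb, na))
    y_mm, x_mm = np.broadcast_arrays(y_mm, x_mm)
    r_mm = np.hypot(y_mm, x_mm)
    pit = np.exp(-(r_mm**2) / (2.0 * spec.pit_sigma_mm**2))

    # --- boundary surfaces (μm from the volume top) ------------------------
    rpe = np.full((nb, na), float(spec.rpe_depth_um))
    lift = np.zeros((nb, na))
    if spec.srf_config is not None or any(p.layer == "subretinal" for p in spec.fluid_config):
        srf = spec.srf_config or SrfSpec()
        for p in spec.fluid_config:
            if p.layer == "subretinal":
                srf = SrfSpec(radius_mm=p.radius_mm,
                              height_um=p.height_um or 60.0, center_mm=p.center_mm)
        dy, dx = y_mm - srf.center_mm[0], x_mm - srf.center_mm[1]
        profile = (1.0 - (dy**2 + dx**2) / srf.radius_mm**2) / srf.rim_fraction
        lift = srf.height_um * np.clip(profile, 0.0, 1.0)
    else:
        srf = None

    elm = rpe - t["photoreceptor"] - lift
    ez = elm + t["elm_ez_gap"]
    onl_top = elm - t["onl"]
    henle_thick = t["opl_henle"] + spec.pit_henle_gain_um * pit
    inl_bot = onl_top - henle_thick
    inl_thick = t["inl"] * (1.0 - spec.pit_inl_collapse * pit)
    ipl_inl = inl_bot - inl_thick
    inner_thick = t["inner_retina"] * (1.0 - spec.pit_inner_fraction * pit)
    ilm_anat = ipl_inl - inner_thick

    # epiretinal membrane cap: the truth ILM rides on top of the membrane
    erm = spec.erm_config
    if erm is not None:
        noise_field = rng.standard_normal((nb, na))
        from scipy.ndimage import gaussian_filter

        smooth = gaussian_filter(noise_field, sigma=max(nb, na) / 24.0)
        patch = smooth > np.quantile(smooth, 1.0 - erm.coverage)
        ilm = ilm_anat - erm.thickness_um * patch
    else:
        patch = np.zeros((nb, na), dtype=bool)
        ilm = ilm_anat

    if float(ilm.min()) < 2 * spec.axial_spacing_um:
        raise ValueError("retina does not fit: ILM reaches the top of the volume")
    if float(rpe.max()) + t["rpe"] + 2 * spec.axial_spacing_um > spec.axial_extent_um:
        raise ValueError("retina does not fit: RPE reaches the bottom of the volume")

    # --- paint bands -------------------------------------------------------
    zc = (np.arange(nz, dtype=float) + 0.5) * spec.axial_spacing_um  # voxel centres
    vol = np.full((nb, na, nz), iv["vitreous"], dtype=np.float32)

    def paint(top, bottom, value):
        m = (zc >= np.asarray(top)[..., None]) & (zc < np.asarray(bottom)[..., None])
        vol[m] = value
        return m

    paint(ilm, ilm_anat, iv["erm"])                       # membrane cap (empty if no ERM)
    paint(ilm_anat, ipl_inl, iv["inner_retina"])
    paint(ipl_inl, inl_bot, iv["inl"])
    paint(inl_bot, onl_top, iv["opl_henle"])
    paint(onl_top, elm, iv["onl"])
    paint(elm, ez, iv["elm_ez_gap"])
    ez_band = paint(ez, ez + t["ez_band"], iv["ez"])
    paint(ez + t["ez_band"], rpe, iv["outer_segment"])
    paint(rpe, rpe + t["rpe"], iv["rpe"])
    paint(rpe + t["rpe"], np.full_like(rpe, np.inf), iv["choroid"])

    # ellipsoid-zone gap
    ez_disrupted = False
    if spec.ez_gap_config is not None:
        g = spec.ez_gap_config
        in_gap = (y_mm - g.center_mm[0]) ** 2 + (x_mm - g.center_mm[1]) ** 2 <= g.radius_mm**2
        vol[ez_band & in_gap[..., None]] = iv["onl"]
        ez_disrupted = True

    # retinal folds: thin dark lines below the ILM, contrast -> 0 at fold depth
    mdrf_true = 0.0
    if erm is not None and erm.fold_depth_um > 0:
        mdrf_true = float(erm.fold_depth_um)
        line = (x_mm[0] / erm.fold_spacing_mm) % 1.0 < 0.18
        d = zc[None, None, :] - ilm[..., None]
        rel = 1.0 - d / erm.fold_depth_um
        contrast = np.where((d >= 0) & (rel > 0), erm.fold_contrast * np.clip(rel, 0, 1) ** 0.25, 0.0)
        vol *= (1.0 - contrast * line[None, :, None]).astype(np.float32)

    # --- fluid -------------------------------------------------------------
    bands = {
        "henle": (inl_bot, onl_top),
        "inl": (ipl_inl, inl_bot),
        "onl": (onl_top, elm),
    }
    fluid_mask = np.zeros_like(vol, dtype=bool)
    for pocket in spec.fluid_config:
        if pocket.layer == "subretinal":
            continue  # rendered as the SRF dome below
        top, bottom = bands[pocket.layer]
        footprint = _cluster_footprint(pocket, y_mm, x_mm)
        thick = (bottom - top)[footprint]
        if footprint.sum() == 0 or not (thick >= 2.0).any():
            raise ValueError(
                f"fluid pocket in layer {pocket.layer!r} at {pocket.center_mm} "
                f"has no room in its band (band thickness "
                f"{0.0 if thick.size == 0 else float(thick.max()):.1f} μm)"
            )
        if pocket.height_um is not None:
            mid = 0.5 * (top + bottom)
            half = np.minimum(pocket.height_um / 2.0, (bottom - top) / 2.0)
            top, bottom = mid - half, mid + half
        m = (
            footprint[..., None]
            & (zc >= top[..., None])
            & (zc < bottom[..., None])
        )
        fluid_mask |= m

    srf_mask = np.zeros_like(vol, dtype=bool)
    if srf is not None:
        srf_mask = (zc >= (rpe - lift)[..., None]) & (zc < rpe[..., None]) & (lift > 0)[..., None]

    vol[fluid_mask] = iv["fluid"]
    vol[srf_mask] = iv["fluid"]

    # --- speckle -----------------------------------------------------------
    if spec.noise_amplitude > 0:
        a2 = spec.noise_amplitude**2
        speckle = rng.gamma(shape=1.0 / a2, scale=a2, size=vol.shape).astype(np.float32)
        vol *= speckle
    np.clip(vol, 0.0, 1.0, out=vol)

    surfaces = SurfaceSet({"ILM": ilm, "IPL/INL": ipl_inl, "EZ": ez, "RPE": rpe})
    truth = PhantomTruth(
        surfaces=surfaces,
        fluid_mask=fluid_mask,
        srf_mask=srf_mask,
        type_label=_derive_type_label(spec),
        erm_present=erm is not None,
        mdrf_true_um=mdrf_true,
        ez_disrupted=ez_disrupted,
        pvd_label=spec.pvd_label,
    )
    return OCTVolume(intensity=vol, geometry=geom), truth


# ---------------------------------------------------------------------------
# preset cohort factory

#: per-type EZ-disruption and incomplete-PVD probabilities used when
#: randomising preset phantoms (clinical frequencies of the five types)
_EZ_RATE = {"FC/NF": 0.0, "PC/NF": 0.20, "PC/DF": 0.3125, "DF/DF": 0.676, "DF/DF+SF": 0.962}
_PVD_RATE = {"FC/NF": 0.417, "PC/NF": 0.32, "PC/DF": 0.438, "DF/DF": 0.432, "DF/DF+SF": 0.654}
_ERM_RATE = 0.469


def preset_spec(type_label: str, rng: np.random.Generator, *, n_ascans=(128, 128),
                axial_extent_um=600.0, rpe_depth_um=470.0,
                noise_amplitude=0.15) -> PhantomSpec:
    """Randomise one phantom spec of a given observed type.

    Geometry (pocket radii, SRF dome, fold depth, layer jitter) is drawn
    within the constraints that keep the type label valid by construction.
    """
    if type_label not in OBSERVED_TYPES:
        raise ValueError(f"unknown preset type {type_label!r}")

    thick = dict(DEFAULT_THICKNESSES_UM)
    thick["inner_retina"] *= rng.uniform(0.92, 1.08)
    thick["inl"] = rng.uniform(33.0, 38.0)
    thick["opl_henle"] *= rng.uniform(0.92, 1.08)
    thick["onl"] = rng.uniform(46.0, 54.0)
    thick["photoreceptor"] = rng.uniform(64.0, 76.0)

    fluid: list[FluidPocket] = []
    srf = None
    if type_label == "FC/NF":
        fluid = [FluidPocket("henle", "cystoid_cluster", radius_mm=rng.uniform(0.32, 0.42))]
    elif type_label == "PC/NF":
        r = rng.uniform(0.85, 1.25)
        fluid = [FluidPocket("henle", "cystoid_cluster", radius_mm=r),
                 FluidPocket("inl", "cystoid_cluster", radius_mm=r)]
    elif type_label == "PC/DF":
        r = rng.uniform(0.85, 1.25)
        fluid = [FluidPocket("henle", "cystoid_cluster", radius_mm=r),
                 FluidPocket("inl", "cystoid_cluster", radius_mm=r),
                 FluidPocket("onl", "diffuse_sheet", radius_mm=rng.uniform(1.85, 2.2))]
    else:  # DF/DF and DF/DF+SF
        r1 = rng.uniform(1.7, 2.05)
        fluid = [FluidPocket("henle", "diffuse_sheet", radius_mm=r1),
                 FluidPocket("inl", "diffuse_sheet", radius_mm=r1),
                 FluidPocket("onl", "diffuse_sheet", radius_mm=rng.uniform(1.85, 2.2))]
        if type_label == "DF/DF+SF":
            srf = SrfSpec(radius_mm=rng.uniform(0.5, 0.9), height_um=rng.uniform(40.0, 70.0))

    erm = None
    if rng.uniform() < _ERM_RATE:
        erm = ErmSpec(fold_depth_um=rng.uniform(20.0, 80.0),
                      fold_spacing_mm=rng.uniform(0.25, 0.4),
                      coverage=rng.uniform(0.2, 0.45))
    ez_gap = None
    if rng.uniform() < _EZ_RATE[type_label]:
        # centred on the horizontal or vertical foveal B-scan so the
        # disruption is visible to the B-scan-based judgement
        radius = rng.uniform(0.15, 0.5)
        offset = rng.uniform(0.0, min(0.8, 1.4 - radius)) * rng.choice([-1.0, 1.0])
        center = (0.0, offset) if rng.uniform() < 0.5 else (offset, 0.0)
        ez_gap = EzGapSpec(radius_mm=radius, center_mm=center)
    pvd = "incomplete" if rng.uniform() < _PVD_RATE[type_label] else "complete"

    return PhantomSpec(
        n_ascans=tuple(n_ascans),
        axial_extent_um=axial_extent_um,
        rpe_depth_um=rpe_depth_um + rng.uniform(-15.0, 15.0),
        layer_thicknesses_um=thick,
        fluid_config=fluid,
        erm_config=erm,
        ez_gap_config=ez_gap,
        srf_config=srf,
        pvd_label=pvd,
        noise_amplitude=noise_amplitude,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def preset_cohort(n_per_type: dict[str, int], seed: int, *, noise_amplitude=0.15,
                  n_ascans=(128, 128), axial_extent_um=600.0,
                  specs_only=False):
    """Generate a cohort of preset phantoms.

    ``n_per_type`` maps observed type labels to counts.  The same seed
    yields the identical spec list; ``specs_only`` returns the specs
    without rendering.
    """
    if any(n < 0 for n in n_per_type.values()):
        raise ValueError("phantom counts must be non-negative")
    rng = np.random.default_rng(seed)
    specs = []
    for label in OBSERVED_TYPES:
        for _ in range(n_per_type.get(label, 0)):
            specs.append(preset_spec(label, rng, n_ascans=n_ascans,
                                     axial_extent_um=axial_extent_um,
                                     noise_amplitude=noise_amplitude))
    if specs_only:
        return specs
    return [generate_phantom(s) for s in specs]


def verify_truth(volume: OCTVolume, truth: PhantomTruth) -> bool:
    """Self-check: re-derive the type label through the classification
    pipeline using the ground-truth surfaces."""
    from .taxonomy import classify_eye

    try:
        classification, _ = classify_eye(volume, surfaces=truth.surfaces)
    except NotDMEError:
        return truth.type_label == CONTROL_LABEL
    return classification.label == truth.type_label
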