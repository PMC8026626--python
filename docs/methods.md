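# Methods

This note documents the models and procedures implemented in `enfacedme`,
the parameters that matter, and what the synthetic phantoms do and do not
establish about real data.

## The classification procedure

Diabetic macular edema (DME) is graded from en face projections of a 3D
macular OCT volume rather than from individual B-scans. Two depth slabs
are constructed after flattening the volume on a boundary surface:

* **Segment 1** — reference IPL/INL boundary, offset 0, depth 50 μm. The
  slab covers the INL and the upper outer plexiform / Henle fiber complex
  (INL thickness is ~33–40 μm, so 50 μm reaches past it).
* **Segment 2** — reference RPE, offset −120 μm, depth 50 μm. The inferior
  slab face sits 70 μm above the RPE (the RPE–ELM distance is ~60–80 μm),
  so the slab covers the ONL.
* **surface** — a single plane at the ILM (depth 0), used for ERM reading.
* **subretinal** — the 70 μm immediately above the RPE; an addition of
  this package used to decide subretinal fluid (SF) volumetrically, where
  a human grader recognises SF by its bright ring appearance on Segment 2.

One reading of the Segment-2 definition is ambiguous in the source
procedure (whether the 50 μm extends upward from the RPE−70 μm line or is
centred on it); we take the literal reading — the RPE−70 μm line is the
*inferior* face — so the slab is [RPE−120, RPE−70) μm.

Fluid appears as well-demarcated hyporeflective regions. Segment-1 extent
is graded against the ETDRS circles centred at the fovea: **FC** if all
fluid pixel centres lie within the 0.5 mm foveal radius, **PC** if within
the 1.5 mm parafoveal radius, **DF** beyond it, **NF** if none. Segment 2
is graded for presence only (in clinical material, Segment-2 fluid always
exceeded the parafoveal circle); the measured extent is still recorded.
Crossing 4 Segment-1 states with 4 Segment-2 renderings (NF, DF, SF,
DF+SF) and removing the all-no-fluid cell gives **15** combination labels;
a full cross product would give 16, and we resolve the published count of
15 by excluding exactly that fluid-free cell, which cannot occur in a
center-involving DME cohort. Five combinations occur as recognised types:
FC/NF, PC/NF, PC/DF, DF/DF, DF/DF+SF.

## Phantom model

Phantoms are piecewise-constant reflectivity volumes between analytic
boundary surfaces, sampled at 5 μm/voxel axially (configurable; the
scanner's axial pixel size is not public, and 50 μm slabs = 10 voxels is
ample for mean projection) and 6 × 6 mm laterally (128 × 128 A-scans by
default; 512 × 256 matches the acquisition geometry).

Layer stack and defaults (μm): inner retina 100, INL 35, OPL+Henle 40,
ONL 50, ELM→RPE photoreceptor band 70 (ELM→EZ gap 25, EZ band 20, outer
segments 25), RPE band 20. Reflectivities in [0, 1]: vitreous 0.02,
inner retina 0.50, INL 0.27, OPL/Henle 0.55, ONL 0.25, EZ and RPE 0.90,
fluid 0.05. The foveal pit is a Gaussian (σ = 0.35 mm) collapse of the
inner layers: the INL vanishes and the inner retina loses 85 % of its
thickness at the centre while Henle's layer thickens by 30 μm. This
matters: it is why a purely Henle-layer foveal cyst dominates the
Segment-1 slab at the fovea, as in real FC/NF eyes.

Pathology models:

* **Intraretinal fluid** — pockets confined to the Henle, INL or ONL band:
  `cystoid_cluster` (a centre cyst plus a ring of six, footprint within
  the pocket radius — the petaloid appearance of cystoid edema) or
  `diffuse_sheet` (the full band over a disk). Painted fluid voxels carry
  exactly the fluid reflectivity before noise, and the painted masks are
  the ground truth.
* **Subretinal fluid** — a flat-topped dome (wall over the outer 25 % of
  the radius) between the photoreceptors and the RPE. The dome lifts the
  whole neurosensory retina, so CST grows by the dome height and the
  displaced bright photoreceptor band produces the ring appearance on
  Segment 2.
* **ERM** — an irregular hyperreflective 12 μm cap covering ~35 % of the
  frame (thresholded smoothed noise), rendered *attached* to the ILM; the
  ground-truth ILM rides on the membrane where present, as clinical
  segmenters track the inner surface of an adherent membrane. Retinal
  folds are rendered as thin dark lines below the ILM whose contrast
  decays as `(1 − d/D)^{1/4}` and vanishes at the fold depth `D`. A
  geometric (corrugated-ILM) fold model was rejected because flattening on
  the ILM removes the corrugation, leaving no well-defined maximum depth
  of retinal folds (MDRF); the contrast-decay model keeps the en face
  appearance and an exact truth `D`.
* **EZ gap** — the EZ band takes ONL reflectivity over a disk.
* **Speckle** — multiplicative gamma noise, mean 1, amplitude (sd) 0.15 by
  default.

Preset phantoms randomise pocket radii within the constraints of each
type (FC clusters reach ≤ 0.40 mm; PC clusters 0.81–1.19 mm; DF sheets
1.7–2.2 mm), layer thicknesses by a few percent, and draw ERM (46.9 %),
EZ gaps and incomplete PVD at the per-type clinical frequencies. Preset
EZ gaps are centred on a foveal B-scan axis so that the B-scan-based
judgement can see them.

## Surface segmentation

A transparent rule set, adequate for layered phantoms and not intended as
a clinical segmenter:

* **ILM** — first raw-intensity crossing above 0.15 (raw, because axial
  smoothing pulls the crossing into the vitreous by one voxel).
* **EZ, RPE** — rising edges of raw intensity above 0.70: RPE is the
  deepest such edge, EZ the deepest edge in a window 10–160 μm above the
  RPE. A-scans with no edge in the window (EZ gaps) are flagged.
* **IPL/INL** — steepest axial descent of smoothed intensity (Gaussian
  σ = 0.8 voxel) between ILM+10 μm and EZ−100 μm, requiring a pre-descent
  intensity below 0.70 (so descents out of an ERM do not qualify) and a
  drop ≥ 0.08. Inside the foveal pit the boundary has no contrast and is
  flagged.
* Flagged A-scans are filled by row/column linear interpolation; all maps
  except the ILM are despiked against a 7 × 7 median (outliers > 4 voxels
  replaced) and smoothed with a 3 × 3 median; ordering ILM < IPL/INL < EZ
  < RPE is enforced with one-voxel minimum separation. The ILM is left
  raw because its crossing is already exact and smoothing would blur
  genuinely steep relief (SRF dome walls, membrane edges).

On noise-free phantoms all four surfaces are within one voxel of truth;
under 0.15 speckle the median error stays within quantization (≤ half a
voxel beyond the noise-free error).

## Numerical conventions

All depths are carried in μm and converted to voxel indices only at
sampling time; rounding is *nearest, ties toward the vitreous*
(`ceil(x/s − 0.5)`). Slab projection is the mean over in-slab voxels
(min/max available for sensitivity checks); a depth of 0 selects the
single nearest plane; out-of-range voxels after flattening are NaN and
excluded from the projection. Volumes are stored at 16 bit, floats in
[0, 1] in memory.

## Fluid detection and grading

Threshold at 0.5 × the slab median (fluid reflectivity sits far below
every tissue band, making the rule scale-free; Otsu is available),
morphological closing with a 1-pixel disk, and an area floor of 0.01 mm²
(≈ 70 μm diameter) against speckle. SF is present iff a hyporeflective
component ≥ 0.05 mm² exists in the subretinal slab. Extent grading uses
pixel centres against the exact 0.5 / 1.5 mm radii; a tolerance parameter
(default 0 pixels — the rule is absolute) can ignore isolated out-of-zone
pixels.

## Biomarkers

* **CST** — mean ILM→RPE distance over the 1-mm foveal circle. The outer
  boundary is the RPE (the convention of the measuring software; the
  phantom RPE is a single surface).
* **EZ disruption** — on the horizontal and vertical B-scans through the
  fovea, within ±1.5 mm: per A-scan mean intensity in EZ ± 10 μm, floor
  0.5 × the median band intensity, disruption iff a contiguous sub-floor
  run ≥ 50 μm exists on either scan. The 50 μm floor replaces a human
  grader's judgement and is exposed as a parameter.
* **ERM** — pixels > 1.5 × median covering ≥ 2 % of the surface en face
  frame.
* **MDRF** — thin slabs centred at depths 0, 10, 20 … μm below the ILM;
  fold lines are elongated components (eccentricity ≥ 0.9, major axis
  ≥ 1 mm) darker than 0.85 × the slab median; MDRF is the deepest slab
  with folds. The 10 μm step bounds the error; the step is a parameter.
* **logMAR** = −log10(decimal acuity).

## Cohort statistics

χ² test of independence (Pearson, no continuity correction) for
categorical variables; one-way ANOVA for age, HbA1c, CST, MDRF;
Kruskal–Wallis (tie-corrected) for BCVA; Student's t (pooled variance by
default, matching the named test; Welch available) for the two-group
Segment-2 comparison; logistic regression by maximum likelihood with Wald
95 % CIs, perfect separation flagged rather than reported. No multiplicity
correction is applied (each test at its nominal 0.05 level). Pooled
proportions and pooled mean ± sd use the within + between variance
decomposition and equal concatenating the raw data exactly. When a
published classification odds ratio is compared against, note the
predictor coding: a single odds ratio for a five-level type implies an
ordinal 1–5 encoding in type order, which is what the package uses; the
original coding is not stated and dummy coding would not yield one OR.

## Problem sizes

Tests and the acceptance script use 96–128² lateral grids with a 600 μm
axial extent (120 voxels at 5 μm), five noise-free presets for exact
recovery, and a 50-phantom speckled cohort (10 per type, amplitude 0.15)
for the stochastic recovery rate. These sizes keep a full run in tens of
seconds while every stage operates at the acquisition's native lateral
pixel pitch scale.

## What the phantoms do not show

* No vascular shadows, hyperreflective foci, motion artifacts or
  biophysically realistic speckle correlation — detector performance on
  real scans is not established, only the correctness of the pipeline's
  geometry and logic.
* Retinal layers do not swell around intraretinal fluid, so phantom CST
  does not reproduce the clinical CST distribution across types (only the
  SRF dome raises it); CST accuracy is assessed against phantom truth,
  and the published pooled CST values are recomputed from the published
  summaries, not from phantoms.
* Disambiguation of Segment-2 hyporeflectivity caused by Henle-fluid
  shadowing (noted as a confound for the en face method) is not modelled.
* Incomplete PVD is carried as a ground-truth label only; detecting it
  would require modelling the optic disc.
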