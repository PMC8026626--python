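#!/usr/bin/env python
"""Simulate the phantom cohort.

Generates one noise-free phantom of each of the five observed DME types
plus a fluid-free control, writes the volumes (multi-page TIFF + JSON
geometry sidecar), ground-truth surfaces (CSV) and truth labels (JSON)
under results/phantoms/, and prints what was built.
"""

import json
from pathlib import Path

import numpy as np

import enfacedme as ed
from enfacedme.taxonomy import OBSERVED_TYPES
from enfacedme.volume import write_surfaces

OUT = Path(__file__).resolve().parents[1] / "results" / "phantoms"
SEED = 11


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    pairs = ed.preset_cohort({t: 1 for t in OBSERVED_TYPES}, seed=SEED,
                             noise_amplitude=0.0)
    pairs.append(ed.generate_phantom(ed.PhantomSpec(
        n_ascans=(128, 128), axial_extent_um=600.0, rpe_depth_um=470.0,
        noise_amplitude=0.0, seed=SEED)))

    for vol, truth in pairs:
        stem = truth.type_label.replace("/", "_").replace("+", "_")
        ed.write_volume(vol, OUT / f"{stem}.tif")
        write_surfaces(truth.surfaces, OUT / f"{stem}_surfaces.csv")
        (OUT / f"{stem}_truth.json").write_text(json.dumps({
            "type_label": truth.type_label,
            "erm_present": truth.erm_present,
            "mdrf_true_um": truth.mdrf_true_um,
            "ez_disrupted": truth.ez_disrupted,
            "pvd_label": truth.pvd_label,
            "fluid_voxels": int(truth.fluid_mask.sum()),
            "srf_voxels": int(truth.srf_mask.sum()),
        }, indent=1))
        print(f"{truth.type_label:10s}  shape={vol.shape}  "
              f"fluid={int(truth.fluid_mask.sum()):7d} vox  "
              f"srf={int(truth.srf_mask.sum()):6d} vox  "
              f"erm={truth.erm_present}  ez_gap={truth.ez_disrupted}")
    print(f"\nwrote {len(pairs)} phantoms to {OUT}")


if __name__ == "__main__":
    main()
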