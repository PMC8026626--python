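#!/usr/bin/env python
"""Render the en face gallery.

For each of the five observed DME types, builds the four standard en face
views (retinal surface, Segment 1, Segment 2, subretinal) from a
noise-free phantom and saves a panel figure per type under
results/figures/.  The appearance to check: foveal vs parafoveal vs
diffuse dark fluid in Segment 1, diffuse fluid confined to the wetter
types in Segment 2, and the subretinal bleb only in DF/DF+SF.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import enfacedme as ed
from enfacedme.segment import flatten, make_enface, standard_slabs
from enfacedme.taxonomy import OBSERVED_TYPES

OUT = Path(__file__).resolve().parents[1] / "results" / "figures"
SEED = 11


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    pairs = ed.preset_cohort({t: 1 for t in OBSERVED_TYPES}, seed=SEED,
                             noise_amplitude=0.0)
    slabs = standard_slabs()
    for vol, truth in pairs:
        surfaces = ed.segment_surfaces(vol)
        fig, axes = plt.subplots(1, 4, figsize=(12, 3.2))
        for ax, name in zip(axes, ("surface", "segment1", "segment2", "subretinal")):
            slab = slabs[name]
            flat = flatten(vol, surfaces, slab.reference_surface)
            img = make_enface(flat, slab)
            ax.imshow(np.nan_to_num(img.pixels), cmap="gray", vmin=0, vmax=0.8)
            ax.set_title(name, fontsize=9)
            ax.axis("off")
        fig.suptitle(f"type {truth.type_label}", fontsize=11)
        stem = truth.type_label.replace("/", "_").replace("+", "_")
        fig.savefig(OUT / f"enface_{stem}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        print(f"{truth.type_label:10s} -> enface_{stem}.png")
    print(f"\nwrote {len(pairs)} panels to {OUT}")


if __name__ == "__main__":
    main()
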