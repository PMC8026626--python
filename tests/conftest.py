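import numpy as np
import pytest

import enfacedme as ed
from enfacedme.taxonomy import OBSERVED_TYPES

SMALL = dict(n_ascans=(96, 96), axial_extent_um=600.0, rpe_depth_um=470.0)


def small_spec(**kwargs):
    """A fast 96x96 phantom spec with sensible axial bounds."""
    base = dict(SMALL)
    base.update(kwargs)
    return ed.PhantomSpec(**base)


@pytest.fixture(scope="session")
def noise_free_presets():
    """One noise-free preset phantom of each observed type (128x128)."""
    pairs = ed.preset_cohort({t: 1 for t in OBSERVED_TYPES}, seed=11, noise_amplitude=0.0)
    return {truth.type_label: (vol, truth) for vol, truth in pairs}


@pytest.fixture(scope="session")
def fc_phantom():
    """Noise-free foveal-cystoid phantom: one Henle cluster at the fovea."""
    spec = small_spec(
        fluid_config=[ed.FluidPocket("henle", "cystoid_cluster", radius_mm=0.4)],
        noise_amplitude=0.0,
    )
    return ed.generate_phantom(spec)


@pytest.fixture(scope="session")
def control_phantom():
    return ed.generate_phantom(small_spec(noise_amplitude=0.0))
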