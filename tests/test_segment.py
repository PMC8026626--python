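import numpy as np
import pytest

import enfacedme as ed
from enfacedme.segment import flatten, make_enface, segment_surfaces, standard_slabs
from enfacedme.volume import SlabSpec, SurfaceSet

from conftest import small_spec

SURFACES = ("ILM", "IPL/INL", "EZ", "RPE")


def _enface_oracle(flat, slab):
    """Brute-force per-pixel projection loop (same slab arithmetic, scalar code)."""
    s = flat.geometry.axial_spacing_um
    nz = flat.intensity.shape[2]
    r0 = flat.reference_row
    i0 = r0 + int(np.ceil(slab.offset_um / s - 0.5))
    if slab.depth_um == 0:
        i1 = i0 + 1
    else:
        i1 = max(r0 + int(np.ceil((slab.offset_um + slab.depth_um) / s - 0.5)), i0 + 1)
    nb, na, _ = flat.intensity.shape
    out = np.full((nb, na), np.nan)
    for b in range(nb):
        for a in range(na):
            vals = [flat.intensity[b, a, z] for z in range(max(i0, 0), min(i1, nz))
                    if np.isfinite(flat.intensity[b, a, z])]
            if vals:
                out[b, a] = {"mean": np.mean, "min": np.min, "max": np.max}[slab.projection](vals)
    return out


# ---------------------------------------------------------------------------
# surface segmentation


@pytest.mark.parametrize(
    "config, srf",
    [
        ([], None),
        ([ed.FluidPocket("henle", "cystoid_cluster", radius_mm=0.4)], None),
        ([ed.FluidPocket("henle", "cystoid_cluster", radius_mm=1.1),
          ed.FluidPocket("inl", "cystoid_cluster", radius_mm=1.1),
          ed.FluidPocket("onl", "diffuse_sheet", radius_mm=2.0)], None),
        ([ed.FluidPocket("henle", "diffuse_sheet", radius_mm=1.9),
          ed.FluidPocket("inl", "diffuse_sheet", radius_mm=1.9),
          ed.FluidPocket("onl", "diffuse_sheet", radius_mm=2.0)], ed.SrfSpec()),
    ],
    ids=["control", "foveal-cyst", "parafoveal+onl", "diffuse+srf"],
)
def test_noise_free_surfaces_within_one_voxel(config, srf):
    spec = small_spec(fluid_config=config, srf_config=srf, noise_amplitude=0.0)
    vol, truth = ed.generate_phantom(spec)
    est = segment_surfaces(vol)
    for name in SURFACES:
        err = np.abs(est[name] - truth.surfaces[name])
        assert err.max() <= vol.geometry.axial_spacing_um + 1e-6, name


def test_speckle_surfaces_median_within_two_voxels():
    spec = small_spec(
        fluid_config=[ed.FluidPocket("henle", "cystoid_cluster", radius_mm=0.4)],
        noise_amplitude=0.15, seed=7)
    vol, truth = ed.generate_phantom(spec)
    est = segment_surfaces(vol)
    for name in SURFACES:
        err = np.abs(est[name] - truth.surfaces[name])
        assert np.median(err) <= 2 * vol.geometry.axial_spacing_um, name


def test_constant_volume_has_no_boundaries():
    geom = ed.VoxelGeometry((50.0, 50.0), 5.0, (8, 8))
    vol = ed.OCTVolume(np.full((16, 16, 40), 0.5, dtype=np.float32), geom)
    with pytest.raises(ValueError):
        segment_surfaces(vol)


# ---------------------------------------------------------------------------
# flattening


def test_flatten_puts_reference_on_constant_row(fc_phantom):
    vol, truth = fc_phantom
    flat = flatten(vol, truth.surfaces, "RPE")
    s = vol.geometry.axial_spacing_um
    shifted = flat.surfaces["RPE"]
    rows = np.ceil(shifted / s - 0.5)
    assert np.abs(rows - flat.reference_row).max() <= 1  # one voxel of rounding


def test_flatten_is_idempotent(fc_phantom):
    vol, truth = fc_phantom
    once = flatten(vol, truth.surfaces, "IPL/INL")
    twice = flatten(once, once.surfaces, "IPL/INL")
    assert np.array_equal(np.nan_to_num(once.intensity), np.nan_to_num(twice.intensity))
    assert twice.reference_row == once.reference_row


def test_flatten_rejects_nonfinite_reference(fc_phantom):
    vol, truth = fc_phantom
    maps = {k: v.copy() for k, v in truth.surfaces.surfaces.items()}
    maps["RPE"][0, 0] = np.nan
    with pytest.raises(ValueError):
        flatten(vol, SurfaceSet(maps), "RPE")


def test_erm_folds_survive_ilm_flattening():
    spec = small_spec(erm_config=ed.ErmSpec(fold_depth_um=60.0), noise_amplitude=0.0)
    vol, truth = ed.generate_phantom(spec)
    flat = flatten(vol, truth.surfaces, "ILM")
    img = make_enface(flat, SlabSpec("ILM", 5.0, 10.0))
    px = img.pixels[np.isfinite(img.pixels)]
    assert px.min() < 0.8 * np.median(px)  # dark fold lines below the ILM


# ---------------------------------------------------------------------------
# en face projection


def test_projection_of_constant_volume_is_constant(control_phantom):
    vol, truth = control_phantom
    geom = vol.geometry
    const = ed.OCTVolume(np.full_like(vol.intensity, 0.5), geom)
    flat = flatten(const, truth.surfaces, "IPL/INL")
    img = make_enface(flat, SlabSpec("IPL/INL", 0.0, 50.0))
    vals = img.pixels[np.isfinite(img.pixels)]
    assert np.allclose(vals, 0.5)


@pytest.mark.parametrize("slab", [
    SlabSpec("RPE", -120.0, 50.0),
    SlabSpec("RPE", -70.0, 70.0),
    SlabSpec("RPE", 0.0, 0.0),
    SlabSpec("RPE", -33.0, 17.0, projection="min"),
    SlabSpec("RPE", -200.0, 120.0, projection="max"),
])
def test_enface_matches_brute_force_loop(slab):
    rng = np.random.default_rng(12)
    geom = ed.VoxelGeometry((375.0, 375.0), 5.0, (8, 8))
    vol = ed.OCTVolume(rng.uniform(0, 1, (16, 16, 64)).astype(np.float32), geom)
    ref = np.full((16, 16), 200.0) + rng.integers(-8, 8, (16, 16)) * 5.0
    surfaces = SurfaceSet({"RPE": ref})
    flat = flatten(vol, surfaces, "RPE")
    img = make_enface(flat, slab)
    expected = _enface_oracle(flat, slab)
    assert np.array_equal(np.nan_to_num(img.pixels, nan=-1),
                          np.nan_to_num(expected, nan=-1))


def test_projection_linearity_and_additivity(fc_phantom):
    vol, truth = fc_phantom
    flat = flatten(vol, truth.surfaces, "IPL/INL")
    full = make_enface(flat, SlabSpec("IPL/INL", 0.0, 30.0)).pixels
    upper = make_enface(flat, SlabSpec("IPL/INL", 0.0, 10.0)).pixels
    lower = make_enface(flat, SlabSpec("IPL/INL", 10.0, 20.0)).pixels
    assert np.allclose(full, upper / 3 + 2 * lower / 3, atol=1e-6, equal_nan=True)

    doubled = flatten(
        ed.OCTVolume(np.clip(vol.intensity * 2.0, 0, None), vol.geometry),
        truth.surfaces, "IPL/INL")
    img2 = make_enface(doubled, SlabSpec("IPL/INL", 0.0, 30.0)).pixels
    assert np.allclose(img2, 2.0 * full, atol=1e-6, equal_nan=True)


def test_slab_outside_volume_is_an_error(fc_phantom):
    vol, truth = fc_phantom
    flat = flatten(vol, truth.surfaces, "RPE")
    with pytest.raises(ValueError):
        make_enface(flat, SlabSpec("RPE", 5000.0, 50.0))
    with pytest.raises(ValueError):
        make_enface(flat, SlabSpec("ILM", 0.0, 50.0))  # wrong reference


def test_standard_slab_definitions():
    slabs = standard_slabs()
    assert slabs["segment1"].reference_surface == "IPL/INL"
    assert slabs["segment1"].depth_um == 50.0
    assert slabs["segment1"].offset_um == 0.0
    # Segment 2: inferior face 70 μm above the RPE, 50 μm deep
    assert slabs["segment2"].reference_surface == "RPE"
    assert slabs["segment2"].offset_um == -120.0
    assert slabs["segment2"].offset_um + slabs["segment2"].depth_um == -70.0
    assert slabs["surface"].depth_um == 0.0
    assert slabs["subretinal"].offset_um + slabs["subretinal"].depth_um == 0.0
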