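import numpy as np
import pytest

import enfacedme as ed
from enfacedme.biomarkers import (
    central_subfield_thickness,
    decimal_to_logmar,
    detect_erm,
    ez_disruption,
    max_depth_retinal_folds,
)
from enfacedme.segment import flatten, make_enface, standard_slabs
from enfacedme.volume import EnFaceImage

from conftest import small_spec


def _surface_image(vol, truth):
    flat = flatten(vol, truth.surfaces, "ILM")
    return make_enface(flat, standard_slabs()["surface"])


# ---------------------------------------------------------------------------
# CST


def test_cst_equals_analytic_zone_mean(control_phantom):
    vol, truth = control_phantom
    zone = vol.geometry.radius_mm(truth.surfaces["ILM"].shape) <= 0.5
    expected = float(np.mean((truth.surfaces["RPE"] - truth.surfaces["ILM"])[zone]))
    cst = central_subfield_thickness(truth.surfaces, vol.geometry)
    assert cst == pytest.approx(expected, abs=1e-9)
    # and from *estimated* surfaces, within one axial voxel
    est = ed.segment_surfaces(vol)
    assert central_subfield_thickness(est, vol.geometry) == pytest.approx(
        expected, abs=vol.geometry.axial_spacing_um)


def test_cst_independent_of_fovea_position_on_flat_phantom():
    # no pit: every inner layer at full thickness everywhere
    spec = small_spec(pit_inner_fraction=0.0, pit_inl_collapse=0.0,
                      pit_henle_gain_um=1e-9, noise_amplitude=0.0)
    vol, truth = ed.generate_phantom(spec)
    g = vol.geometry
    cst_center = central_subfield_thickness(truth.surfaces, g)
    shifted = ed.VoxelGeometry(g.lateral_spacing_um, g.axial_spacing_um, (30, 60))
    cst_shifted = central_subfield_thickness(truth.surfaces, shifted)
    assert cst_center == pytest.approx(cst_shifted, abs=1e-6)


def test_srf_dome_raises_cst_by_its_height():
    base, _ = ed.generate_phantom(small_spec(noise_amplitude=0.0))
    dome = small_spec(srf_config=ed.SrfSpec(radius_mm=1.0, height_um=50.0),
                      noise_amplitude=0.0)
    vol, truth = ed.generate_phantom(dome)
    cst0 = central_subfield_thickness(
        ed.generate_phantom(small_spec(noise_amplitude=0.0))[1].surfaces, base.geometry)
    cst1 = central_subfield_thickness(truth.surfaces, vol.geometry)
    # the foveal circle sits on the dome plateau -> CST grows by ≈ the height
    assert cst1 - cst0 == pytest.approx(50.0, abs=2.0)


# ---------------------------------------------------------------------------
# EZ disruption


def test_ez_gap_at_fovea_is_detected():
    spec = small_spec(ez_gap_config=ed.EzGapSpec(radius_mm=0.3), noise_amplitude=0.0)
    vol, truth = ed.generate_phantom(spec)
    assert truth.ez_disrupted
    assert ez_disruption(vol, truth.surfaces)


def test_intact_ez_is_not_disrupted(control_phantom):
    vol, truth = control_phantom
    assert not ez_disruption(vol, truth.surfaces)


def test_ez_gap_outside_central_3mm_is_ignored():
    spec = small_spec(ez_gap_config=ed.EzGapSpec(radius_mm=0.3, center_mm=(0.0, 2.5)),
                      noise_amplitude=0.0)
    vol, truth = ed.generate_phantom(spec)
    assert not ez_disruption(vol, truth.surfaces)


def test_ez_gap_shorter_than_floor_is_ignored():
    spec = small_spec(ez_gap_config=ed.EzGapSpec(radius_mm=0.3), noise_amplitude=0.0)
    vol, truth = ed.generate_phantom(spec)
    assert not ez_disruption(vol, truth.surfaces, gap_min_um=1000.0)


# ---------------------------------------------------------------------------
# ERM and MDRF


def test_erm_detected_only_when_present():
    with_erm = ed.generate_phantom(small_spec(erm_config=ed.ErmSpec(), noise_amplitude=0.0))
    without = ed.generate_phantom(small_spec(noise_amplitude=0.0))
    assert detect_erm(_surface_image(*with_erm))
    assert not detect_erm(_surface_image(*without))


def test_erm_detection_invariant_to_global_scaling():
    vol, truth = ed.generate_phantom(small_spec(erm_config=ed.ErmSpec(), noise_amplitude=0.0))
    img = _surface_image(vol, truth)
    scaled = EnFaceImage(pixels=0.4 * img.pixels, geometry=img.geometry, slab=img.slab)
    assert detect_erm(img) == detect_erm(scaled)


@pytest.mark.parametrize("fold_depth", [40.0, 60.0, 80.0])
def test_mdrf_recovers_fold_depth_within_one_step(fold_depth):
    spec = small_spec(erm_config=ed.ErmSpec(fold_depth_um=fold_depth), noise_amplitude=0.0)
    vol, truth = ed.generate_phantom(spec)
    flat = flatten(vol, truth.surfaces, "ILM")
    mdrf = max_depth_retinal_folds(flat, step_um=10.0)
    assert abs(mdrf - fold_depth) <= 10.0


def test_mdrf_zero_without_folds(control_phantom):
    vol, truth = control_phantom
    flat = flatten(vol, truth.surfaces, "ILM")
    assert max_depth_retinal_folds(flat) == 0.0


def test_mdrf_halving_step_does_not_lose_precision():
    spec = small_spec(erm_config=ed.ErmSpec(fold_depth_um=60.0), noise_amplitude=0.0)
    vol, truth = ed.generate_phantom(spec)
    flat = flatten(vol, truth.surfaces, "ILM")
    err10 = abs(max_depth_retinal_folds(flat, step_um=10.0) - 60.0)
    err5 = abs(max_depth_retinal_folds(flat, step_um=5.0) - 60.0)
    assert err5 <= err10 + 5.0


# ---------------------------------------------------------------------------
# logMAR


@pytest.mark.parametrize("decimal, logmar", [(1.0, 0.0), (0.1, 1.0), (0.5, 0.30103)])
def test_decimal_to_logmar(decimal, logmar):
    assert decimal_to_logmar(decimal) == pytest.approx(logmar, abs=1e-5)


def test_logmar_rejects_nonpositive():
    with pytest.raises(ValueError):
        decimal_to_logmar(0.0)


# ---------------------------------------------------------------------------
# full per-eye measurement


def test_measure_eye_recovers_truth_on_noise_free_presets(noise_free_presets):
    for label, (vol, truth) in noise_free_presets.items():
        m = ed.measure_eye(vol)
        assert m["type_label"] == truth.type_label, label
        assert m["ez_disrupted"] == truth.ez_disrupted, label
        assert m["erm_present"] == truth.erm_present, label
        if truth.erm_present:
            assert abs(m["mdrf_um"] - truth.mdrf_true_um) <= 10.0, label
        else:
            assert m["mdrf_um"] is None
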