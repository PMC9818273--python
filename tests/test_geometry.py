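"""Geometry unit and property tests: surface extraction, signed distances,
OVH and POV, checked against exhaustive brute-force enumeration and against
their symmetry invariants."""

import numpy as np
import pytest

from lnspatial import geometry
from lnspatial import synthetic as syn
from lnspatial.geometry import EmptyMaskError
from lnspatial.structures import StructureVolume

from conftest import random_structure_pair


def single_voxel_gtv(spacing=(1.0, 1.0, 1.0), shape=(8, 8, 8), at=(0, 0, 0)):
    m = np.zeros(shape, bool)
    m[at] = True
    return StructureVolume("GTVn", m, spacing)


# ---------------------------------------------------------------------------
# surface extraction
# ---------------------------------------------------------------------------


def test_single_voxel_is_its_own_surface():
    surf = geometry.extract_surface(single_voxel_gtv(at=(2, 3, 4)))
    np.testing.assert_allclose(surf.points, [[2.0, 3.0, 4.0]])


def test_solid_cube_surface_excludes_only_center():
    m = np.zeros((5, 5, 5), bool)
    m[1:4, 1:4, 1:4] = True
    surf = geometry.extract_surface(StructureVolume("GTVn", m))
    assert len(surf) == 26
    assert [2.0, 2.0, 2.0] not in surf.points.tolist()


def test_empty_mask_raises():
    empty = StructureVolume("GTVn", np.zeros((4, 4, 4), bool))
    with pytest.raises(EmptyMaskError, match="GTVn"):
        geometry.extract_surface(empty)
    with pytest.raises(EmptyMaskError):
        geometry.signed_distance_map(empty)


@pytest.mark.parametrize("seed", range(5))
def test_surface_matches_exhaustive_neighbor_scan(seed):
    gtv, _ = random_structure_pair(seed)
    fast = geometry.extract_surface(gtv).points
    brute = syn.brute_force_surface(gtv)
    np.testing.assert_array_equal(fast, brute)


# ---------------------------------------------------------------------------
# signed distances
# ---------------------------------------------------------------------------


def test_pythagorean_distance_from_single_voxel():
    dm = geometry.signed_distance_map(single_voxel_gtv())
    assert dm.values[3, 4, 0] == pytest.approx(5.0)
    assert dm.values[0, 0, 0] == 0.0


def test_inside_voxels_are_non_positive():
    m = np.zeros((6, 6, 6), bool)
    m[1:5, 1:5, 1:5] = True
    dm = geometry.signed_distance_map(StructureVolume("GTVn", m, (1.3, 0.9, 2.1)))
    assert np.all(dm.values[m] <= 0)
    assert np.all(dm.values[~m] > 0)


@pytest.mark.parametrize("seed", range(5))
def test_distance_map_matches_pairwise_oracle(seed):
    gtv, oar = random_structure_pair(seed)
    dm = geometry.signed_distance_map(gtv)
    brute = syn.brute_force_signed_distances(gtv, oar)
    np.testing.assert_allclose(dm.values[oar.mask], brute, atol=1e-9)


# ---------------------------------------------------------------------------
# OVH
# ---------------------------------------------------------------------------


def test_ovh_counts_fractions_at_edges():
    # engineered distances {-1, 0, 1, 2} mm via a 4-voxel line OAR next to a
    # half-infinite slab tumor
    m = np.zeros((8, 4, 4), bool)
    m[:4] = True  # tumor occupies x < 4; surface plane at x = 3
    gtv = StructureVolume("GTVn", m)
    oar_mask = np.zeros((8, 4, 4), bool)
    oar_mask[2:6, 1, 1] = True  # distances to surface voxel centers: -1, 0, 1, 2
    oar = StructureVolume("OAR", oar_mask)
    dm = geometry.signed_distance_map(gtv)
    curve = geometry.compute_ovh(dm, oar, np.arange(-2.0, 3.0))
    ovh = dict(zip(curve.bin_edges, curve.values))
    assert ovh[0.0] == pytest.approx(0.5)
    assert ovh[2.0] == pytest.approx(1.0)


def test_oar_inside_tumor_has_full_overlap_at_zero():
    gtv, _ = random_structure_pair(1)
    oar = gtv.with_mask(gtv.mask, name="OAR")
    curve = geometry.ovh(gtv, oar, np.arange(-5.0, 6.0))
    assert curve.values[list(curve.bin_edges).index(0.0)] == pytest.approx(1.0)


def test_ovh_monotone_and_terminal_one():
    gtv, oar = random_structure_pair(7)
    curve = geometry.ovh(gtv, oar, geometry.default_ovh_edges(-20, 80, 1.0))
    assert np.all(np.diff(curve.values) >= 0)
    assert curve.values[-1] == pytest.approx(1.0)


def test_ovh_errors():
    gtv, oar = random_structure_pair(0)
    with pytest.raises(EmptyMaskError, match="OAR"):
        geometry.ovh(gtv, oar.with_mask(np.zeros_like(oar.mask)), np.arange(5.0))
    dm = geometry.signed_distance_map(gtv)
    other = StructureVolume("OAR", np.ones((4, 4, 4)))
    with pytest.raises(ValueError, match="same grid"):
        geometry.compute_ovh(dm, other, np.arange(5.0))


def test_ovh_translation_invariance():
    # blobs embedded with a margin so that rolling is a pure translation
    inner_gtv, inner_oar = random_structure_pair(3, shape=(12, 12, 12))
    full = np.zeros((20, 20, 20), bool)
    gtv_m, oar_m = full.copy(), full.copy()
    gtv_m[4:16, 4:16, 4:16] = inner_gtv.mask
    oar_m[4:16, 4:16, 4:16] = inner_oar.mask
    gtv = StructureVolume("GTVn", gtv_m, inner_gtv.spacing)
    oar = StructureVolume("OAR", oar_m, inner_gtv.spacing)
    edges = geometry.default_ovh_edges(-15, 60, 1.0)
    base = geometry.ovh(gtv, oar, edges).values
    shift = (2, -1, 3)
    gtv2 = gtv.with_mask(np.roll(gtv.mask, shift, axis=(0, 1, 2)))
    oar2 = oar.with_mask(np.roll(oar.mask, shift, axis=(0, 1, 2)))
    moved = geometry.ovh(gtv2, oar2, edges).values
    np.testing.assert_allclose(moved, base, atol=1e-12)


# ---------------------------------------------------------------------------
# POV
# ---------------------------------------------------------------------------


def test_single_pair_angle_is_ninety_degrees():
    gtv = single_voxel_gtv(shape=(4, 16, 4))
    oar_mask = np.zeros((4, 16, 4), bool)
    oar_mask[0, 10, 0] = True  # +y direction from the surface point
    oar = StructureVolume("OAR", oar_mask)
    curve = geometry.compute_pov(geometry.extract_surface(gtv), oar)
    assert curve.values[90] == 1.0
    assert curve.values[0] == 0.0
    assert curve.values.sum() == 1.0  # degenerate arc covers exactly one grid angle


def test_pov_values_in_unit_interval():
    gtv, oar = random_structure_pair(11)
    curve = geometry.compute_pov(geometry.extract_surface(gtv), oar)
    assert np.all(curve.values >= 0) and np.all(curve.values <= 1)


@pytest.mark.parametrize("occlusion", ["none", "before"])
@pytest.mark.parametrize("seed", range(4))
def test_pov_matches_enumeration_oracle(seed, occlusion):
    gtv, oar = random_structure_pair(seed)
    fast = geometry.compute_pov(geometry.extract_surface(gtv), oar, occlusion=occlusion)
    brute = syn.brute_force_pov(gtv, oar, geometry.default_pov_angles(), occlusion=occlusion)
    np.testing.assert_allclose(fast.values, brute.values, atol=1e-9)


def test_pov_monotone_under_tumor_superset():
    from scipy import ndimage

    gtv, oar = random_structure_pair(5, shape=(20, 20, 20))
    bigger = gtv.with_mask(ndimage.binary_dilation(gtv.mask))
    small = geometry.compute_pov(geometry.extract_surface(gtv), oar).values
    large = geometry.compute_pov(geometry.extract_surface(bigger), oar).values
    assert np.all(large >= small - 1e-12)


def test_pov_rotation_equivariance_quarter_turn():
    rng = np.random.default_rng(21)
    shape = (20, 20, 9)
    from conftest import random_blob_mask

    gtv_m = random_blob_mask(rng, shape)
    oar_m = random_blob_mask(rng, shape)
    spacing = (1.5, 1.5, 2.0)  # in-plane isotropic: required for grid rotation
    gtv = StructureVolume("GTVn", gtv_m, spacing)
    oar = StructureVolume("OAR", oar_m, spacing)
    base = geometry.compute_pov(geometry.extract_surface(gtv), oar).values
    # np.rot90 over (x, y) is a +90 degree physical rotation about the grid
    # center, so the angular histogram shifts by 90 bins on the 1 degree grid
    gtv_r = gtv.with_mask(np.rot90(gtv.mask, axes=(0, 1)))
    oar_r = oar.with_mask(np.rot90(oar.mask, axes=(0, 1)))
    rotated = geometry.compute_pov(geometry.extract_surface(gtv_r), oar_r).values
    np.testing.assert_allclose(rotated, np.roll(base, 90), atol=1e-12)


def test_fold_pov_takes_opposite_angle_maximum():
    angles = geometry.default_pov_angles(1.0)
    values = np.zeros(360)
    values[10] = 0.4
    values[190] = 0.7
    folded = geometry.fold_pov(geometry.POVCurve(angles=angles, values=values))
    assert folded.angles.size == 180
    assert folded.values[10] == pytest.approx(0.7)


def test_pov_empty_oar_raises():
    gtv, oar = random_structure_pair(0)
    with pytest.raises(EmptyMaskError):
        geometry.compute_pov(
            geometry.extract_surface(gtv), oar.with_mask(np.zeros_like(oar.mask))
        )
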