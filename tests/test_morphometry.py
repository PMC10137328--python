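"""Shape measures against analytic solids and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from mitomorph.morphometry import (
    EPS_DISC,
    aspect_ratio,
    compute_morphometry,
    measure_length,
    measure_surface_area,
    measure_volume,
    skeleton_profile,
    sphericity,
)
from mitomorph.synthetic import SPHERE, SceneSpec, ShapeSpec, rasterize_scene
from mitomorph.volume_io import MITOCHONDRION, LabelVolume, OrganelleObject, extract_objects
from tests.conftest import random_blob


def make_obj(coords, oid=1):
    return OrganelleObject(
        id=oid,
        voxel_coords=np.asarray(coords, dtype=int),
        organelle_class=MITOCHONDRION,
        touches_boundary=False,
    )


# --- volume ------------------------------------------------------------------


def test_single_voxel_volume_is_voxel_volume():
    obj = make_obj([[0, 0, 0]])
    assert measure_volume(obj, (50.0, 8.0, 8.0)) == pytest.approx(3.2e-6)


def test_sphere_volume_within_3pct(iso_sphere_500):
    mito, obj = iso_sphere_500
    analytic = 4.0 / 3.0 * math.pi * 0.25**3
    assert measure_volume(obj, mito.spacing) == pytest.approx(analytic, rel=0.03)


def test_volume_equals_independent_recount(panel):
    mito, _, _ = panel
    for obj in extract_objects(mito, exclude_boundary=False):
        recount = int((mito.labels == obj.source_label).sum())
        assert measure_volume(obj, mito.spacing) == pytest.approx(
            recount * mito.voxel_volume_nm3 * 1e-9
        )


# --- surface area ------------------------------------------------------------


def test_sphere_surface_area_within_5pct(iso_sphere_500):
    mito, obj = iso_sphere_500
    assert measure_surface_area(obj, mito.spacing) == pytest.approx(
        4 * math.pi * 0.25**2, rel=0.05
    )


def test_cube_surface_area_within_10pct():
    labels = np.zeros((60, 60, 60), dtype=np.uint8)
    labels[5:55, 5:55, 5:55] = 1  # 400 nm cube at 8 nm
    vol = LabelVolume(labels, (8.0, 8.0, 8.0))
    obj = extract_objects(vol, exclude_boundary=False)[0]
    assert measure_surface_area(obj, vol.spacing) == pytest.approx(0.96, rel=0.10)


def test_surface_area_converges_under_refinement():
    shape = ShapeSpec(SPHERE, (300.0, 300.0, 300.0), diameter=500.0)
    sa = {}
    for s in (8.0, 4.0):
        mito, _, _ = rasterize_scene(SceneSpec(spacing=(s, s, s), objects=[shape]))
        obj = extract_objects(mito, exclude_boundary=False)[0]
        sa[s] = measure_surface_area(obj, mito.spacing)
    assert abs(sa[4.0] / sa[8.0] - 1.0) < 0.02


# --- length ------------------------------------------------------------------


def test_two_voxel_length_along_x():
    obj = make_obj([[0, 0, 0], [0, 0, 100]])
    assert measure_length(obj, (50.0, 8.0, 8.0)) == pytest.approx(0.8)


def test_sphere_length_is_diameter(iso_sphere_500):
    mito, obj = iso_sphere_500
    diag = np.linalg.norm(mito.spacing) * 1e-3
    assert measure_length(obj, mito.spacing) == pytest.approx(0.5, abs=diag)


def test_length_equals_brute_force_on_random_blob():
    coords = random_blob(200, seed=4)
    obj = make_obj(coords)
    spacing = (50.0, 8.0, 8.0)
    pts = (coords + 0.5) * np.array(spacing)
    brute = pdist(pts).max() * 1e-3
    assert measure_length(obj, spacing) == pytest.approx(brute, rel=1e-12)


def test_length_translation_invariant():
    coords = random_blob(150, seed=9)
    spacing = (50.0, 8.0, 8.0)
    a = measure_length(make_obj(coords), spacing)
    b = measure_length(make_obj(coords + [3, 7, 11]), spacing)
    assert a == pytest.approx(b, rel=1e-12)


# --- aspect ratio ------------------------------------------------------------


def test_sphere_aspect_ratio_is_one(iso_sphere_500):
    mito, obj = iso_sphere_500
    ar, flags = aspect_ratio(obj, mito.spacing)
    assert ar == pytest.approx(1.0, abs=EPS_DISC)
    assert not flags


def test_capsule_aspect_ratio_matches_analytic(iso_capsule_2um):
    # analytic extents under the max-extent definition: major 2 µm, minor 0.2 µm
    mito, obj = iso_capsule_2um
    ar, _ = aspect_ratio(obj, mito.spacing)
    assert ar == pytest.approx(10.0, rel=0.05)


def test_aspect_ratio_invariant_under_lattice_rotation(iso_capsule_2um):
    mito, obj = iso_capsule_2um
    ar0, _ = aspect_ratio(obj, mito.spacing)
    rotated = np.rot90(mito.labels, k=1, axes=(1, 2))  # swap x into y
    vol2 = LabelVolume(np.ascontiguousarray(rotated), mito.spacing)
    obj2 = extract_objects(vol2, exclude_boundary=False)[0]
    ar1, _ = aspect_ratio(obj2, vol2.spacing)
    assert ar1 == pytest.approx(ar0, rel=0.02)


def test_collinear_voxels_fall_back_to_voxel_diagonal_minor_axis():
    obj = make_obj([[0, 0, i] for i in range(20)])
    ar, flags = aspect_ratio(obj, (8.0, 8.0, 8.0))
    assert "degenerate_minor_axis" in flags
    assert ar >= 1.0


# --- sphericity --------------------------------------------------------------


def test_sphericity_of_perfect_sphere_is_exactly_one():
    for r in (0.1, 0.25, 1.7):
        v = 4.0 / 3.0 * math.pi * r**3
        sa = 4.0 * math.pi * r**2
        assert sphericity(v, sa) == pytest.approx(1.0, abs=1e-12)


def test_sphericity_of_cube_closed_form():
    a = 0.4
    assert sphericity(a**3, 6 * a**2) == pytest.approx((math.pi / 6) ** (1 / 3), abs=1e-12)


def test_sphericity_of_capsule_closed_form_oracle(iso_capsule_2um):
    # analytic capsule: V = pi r^2 L_cyl + 4/3 pi r^3, SA = 2 pi r L_cyl + 4 pi r^2
    mito, obj = iso_capsule_2um
    r, cyl = 0.1, 1.8
    v = math.pi * r * r * cyl + 4.0 / 3.0 * math.pi * r**3
    sa = 2 * math.pi * r * cyl + 4 * math.pi * r * r
    expected = sphericity(v, sa)
    rec = compute_morphometry(obj, mito.spacing)
    assert rec.sphericity == pytest.approx(expected, rel=0.02)


def test_sphericity_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        sphericity(0.0, 1.0)
    with pytest.raises(ValueError):
        sphericity(1.0, -1.0)


def test_sphericity_bounded_and_maximal_for_sphere_on_panel(panel):
    mito, _, _ = panel
    recs = {
        o.id: compute_morphometry(o, mito.spacing)
        for o in extract_objects(mito, exclude_boundary=False)
    }
    psis = {oid: r.sphericity for oid, r in recs.items()}
    assert all(0 < p <= 1 + EPS_DISC for p in psis.values())
    sphere_psi = max(psis.values())
    sphere_id = [oid for oid, p in psis.items() if p == sphere_psi][0]
    assert recs[sphere_id].length_um < 0.55  # the panel's sphere wins


# --- skeleton profile --------------------------------------------------------


def test_capsule_skeleton_single_path_radius(iso_capsule_2um):
    mito, obj = iso_capsule_2um
    prof = skeleton_profile(obj, mito.spacing)
    assert len(prof.paths) == 1
    assert np.median(prof.radii_nm) == pytest.approx(100.0, rel=0.15)
    assert (prof.radii_nm > 0).all()


def test_sphere_skeleton_is_compact_with_central_radius(iso_sphere_500):
    mito, obj = iso_sphere_500
    prof = skeleton_profile(obj, mito.spacing)
    assert prof.n_nodes <= 10
    assert prof.radii_nm.max() == pytest.approx(250.0, rel=0.15)


def test_moas_profile_shows_three_beads_and_two_neck_dips(moas_profile):
    obj, prof = moas_profile
    assert (prof.radii_nm > 0).all()
    longest = max(prof.paths, key=len)
    r = prof.radii_nm[longest]
    n_beads = 0
    in_bead = False
    for v in r:
        if v >= 200.0 and not in_bead:
            n_beads += 1
            in_bead = True
        elif v <= 45.0:
            in_bead = False
    assert n_beads == 3
    assert (r <= 45.0).sum() > 0


def test_tiny_object_gets_single_node_skeleton():
    obj = make_obj([[2, 2, 2], [2, 2, 3]])
    prof = skeleton_profile(obj, (8.0, 8.0, 8.0))
    assert prof.n_nodes >= 1
    assert (prof.radii_nm > 0).all()
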