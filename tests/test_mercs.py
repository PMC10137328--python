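"""Contact-site detection at the 25 nm criterion, coverage and pooling."""

import math

import numpy as np
import pytest

from mitomorph.classify import TypeCall
from mitomorph.mercs import (
    ContactParams,
    CoverageRecord,
    coverage,
    detect_contacts,
    mercs_by_type,
    surface_gap_field,
)
from mitomorph.morphometry import MorphometryRecord, compute_morphometry
from mitomorph.synthetic import make_gap_fixture, rasterize_scene
from mitomorph.volume_io import ER, LabelVolume, extract_objects


@pytest.fixture(scope="module")
def panel_capsule_contacts(panel):
    """Gap field + contacts for the panel's Type II capsule (the ER carrier)."""
    mito, er, truth = panel
    objs = extract_objects(mito, exclude_boundary=False)
    capsule = [o for o in objs if o.source_label == 2][0]
    gf = surface_gap_field(capsule, er)
    sites = detect_contacts(capsule, er, ContactParams(), gap_field=gf)
    return capsule, gf, sites


def test_gap_field_tracks_generated_gaps(panel, panel_capsule_contacts):
    """Min face gap per ER tube matches the generating gap within a voxel diagonal."""
    mito, er, truth = panel
    _, gf, _ = panel_capsule_contacts
    diag = float(np.linalg.norm(mito.spacing))
    for p in truth.placements:
        sel = gf.nearest_er_label == p.er_label
        assert sel.any()
        assert gf.gaps_nm[sel].min() == pytest.approx(p.gap_nm, abs=diag)


def test_25nm_criterion_detects_exactly_the_three_close_tubes(panel, panel_capsule_contacts):
    _, _, truth = panel
    _, _, sites = panel_capsule_contacts
    detected = sorted(s.er_id for s in sites)
    close = sorted(p.er_label for p in truth.placements if p.gap_nm <= 25.0)
    far = [p.er_label for p in truth.placements if p.gap_nm > 25.0]
    assert detected == close == [1, 2, 3]
    assert not set(far) & set(detected)


def test_contact_length_matches_apposed_extent(panel, panel_capsule_contacts):
    """Patch length tracks the generated apposed extent.

    The detected band legitimately spills past the straight apposed section
    wherever the 25 nm criterion leaves slack (the tube's curved ends and
    flanks still lie within threshold), so the oracle is a geometric
    bracket: axial spill per end is sqrt(2 r_er slack) and the
    circumferential wrap adds 2 R sqrt(2 slack / R_eff), where R_eff is the
    combined mito/ER curvature at the closest approach.  Near threshold the
    spill vanishes and the length matches the extent within 10%.
    """
    mito, _, truth = panel
    _, _, sites = panel_capsule_contacts
    diag = float(np.linalg.norm(mito.spacing))
    by_label = {p.er_label: p for p in truth.placements}
    R = 150.0  # panel capsule radius
    for s in sites:
        p = by_label[s.er_id]
        r_er = p.er_tube_diameter_nm / 2.0
        slack = 25.0 - p.gap_nm
        D = R + p.gap_nm + r_er
        axial = 2.0 * math.sqrt(2.0 * r_er * slack)
        wrap = 2.0 * R * math.sqrt(2.0 * slack * (D - R) / (D * R))
        lo = p.patch_extent_nm - diag
        hi = math.hypot(p.patch_extent_nm + axial, wrap) + diag
        assert lo <= s.contact_length_nm <= hi
        if slack <= 1.0:  # near-threshold: no spill, extent recovered directly
            assert s.contact_length_nm == pytest.approx(p.patch_extent_nm, rel=0.10)


def test_contact_invariants(panel_capsule_contacts):
    capsule, gf, sites = panel_capsule_contacts
    total = gf.total_area_um2
    assert sum(s.contact_area_um2 for s in sites) <= total
    for s in sites:
        assert (gf.gaps_nm[s.face_indices] <= 25.0).all()
        assert s.mean_gap_nm <= 25.0
        assert s.contact_length_nm >= 0
        assert s.contact_volume_um3 > 0


def test_coverage_monotone_in_gap_threshold(panel_capsule_contacts):
    capsule, gf, _ = panel_capsule_contacts
    prev_faces: set[int] = set()
    prev_area = -1.0
    for t in (10.0, 17.0, 25.0, 33.0):
        faces = set(np.flatnonzero(gf.gaps_nm <= t).tolist())
        area = float(gf.face_areas_nm2[sorted(faces)].sum()) if faces else 0.0
        assert prev_faces <= faces
        assert area >= prev_area
        prev_faces, prev_area = faces, area


def test_no_er_means_infinite_gaps_and_no_contacts(panel):
    mito, er, _ = panel
    objs = extract_objects(mito, exclude_boundary=False)
    empty = LabelVolume(np.zeros_like(er.labels), er.spacing, ER)
    gf = surface_gap_field(objs[0], empty)
    assert np.isinf(gf.gaps_nm).all()
    assert detect_contacts(objs[0], empty, gap_field=gf) == []


def test_gap_field_invariant_under_joint_translation():
    mito, er, _ = rasterize_scene(make_gap_fixture(20.0))
    shift = (2, 3, 5)
    pad = [(0, s) for s in shift]  # headroom so the shift cannot wrap content
    m1 = np.pad(mito.labels, pad)
    e1 = np.pad(er.labels, pad)
    mito = LabelVolume(m1, mito.spacing)
    er = LabelVolume(e1, er.spacing, ER)
    mito2 = LabelVolume(np.roll(m1, shift, axis=(0, 1, 2)), mito.spacing)
    er2 = LabelVolume(np.roll(e1, shift, axis=(0, 1, 2)), er.spacing, ER)
    o1 = extract_objects(mito, exclude_boundary=False)[0]
    o2 = extract_objects(mito2, exclude_boundary=False)[0]
    g1 = surface_gap_field(o1, er)
    g2 = surface_gap_field(o2, er2)
    assert g1.gaps_nm.min() == pytest.approx(g2.gaps_nm.min(), abs=1e-9)
    assert len(g1.gaps_nm) == len(g2.gaps_nm)


def test_self_contact_saturates_coverage():
    """Offering the mitochondrion itself as 'ER' gives one full-wrap contact."""
    from mitomorph.synthetic import SPHERE, SceneSpec, ShapeSpec

    mito, _, _ = rasterize_scene(
        SceneSpec(spacing=(8.0, 8.0, 8.0), objects=[ShapeSpec(SPHERE, (300, 300, 300), diameter=400.0)])
    )
    fake_er = LabelVolume(mito.labels.copy(), mito.spacing, ER)
    obj = extract_objects(mito, exclude_boundary=False)[0]
    rec = compute_morphometry(obj, mito.spacing)
    gf = surface_gap_field(obj, fake_er)
    sites = detect_contacts(obj, fake_er, gap_field=gf)
    assert len(sites) == 1
    cov = coverage(rec, sites, total_area_um2=gf.total_area_um2)
    assert cov.coverage_percent == pytest.approx(100.0, abs=1.0)


def test_hemispherical_shell_covers_half_the_sphere():
    """An ER cap over one hemisphere at a 15 nm gap yields ~50% coverage."""
    s = 8.0
    n = 90
    c = (n / 2) * s  # 360 nm, on a voxel corner; symmetric for the half-split
    idx = np.indices((n, n, n))
    centers = (idx + 0.5) * s
    d = np.sqrt(((centers - c) ** 2).sum(axis=0))
    r = 250.0
    mito_mask = d <= r
    shell = (d > r + 15.0) & (d <= r + 55.0) & (centers[1] > c)
    mito = LabelVolume(mito_mask.astype(np.uint8), (s, s, s))
    er = LabelVolume(shell.astype(np.uint8), (s, s, s), ER)
    obj = extract_objects(mito, exclude_boundary=False)[0]
    rec = compute_morphometry(obj, mito.spacing)
    gf = surface_gap_field(obj, er)
    sites = detect_contacts(obj, er, gap_field=gf)
    cov = coverage(rec, sites, total_area_um2=gf.total_area_um2)
    assert cov.coverage_percent == pytest.approx(50.0, abs=5.0)


def test_coverage_zero_without_contacts():
    rec = MorphometryRecord(1, 0.1, 1.0, 0.5, 1.0, 0.9, False)
    cov = coverage(rec, [])
    assert cov.coverage_percent == 0.0
    assert cov.n_contacts == 0
    assert cov.mean_contact_length_nm == 0.0


def _cov(mid, pct, length=100.0, vol=0.01):
    return CoverageRecord(mid, 1, pct, length, vol, 0.1)


def _call(mid, t):
    return TypeCall(mid, t, 0, 0, "test")


def test_pooling_splits_tubules_from_moas_and_conserves_counts():
    calls = [_call(1, "II"), _call(2, "II"), _call(3, "IV"), _call(4, "IV")]
    covs = [_cov(1, 10.0), _cov(2, 20.0), _cov(3, 30.0), _cov(4, 40.0)]
    table = mercs_by_type(calls, covs)
    assert sorted(table.index) == ["I-III", "MOAS"]
    assert int(table["n"].sum()) == len(covs)
    assert table.loc["MOAS", "coverage_percent_mean"] > table.loc["I-III", "coverage_percent_mean"]


def test_empty_pool_is_absent_not_zero():
    calls = [_call(1, "II"), _call(2, "II")]
    covs = [_cov(1, 10.0), _cov(2, 20.0)]
    table = mercs_by_type(calls, covs)
    assert list(table.index) == ["I-III"]
    assert "MOAS" not in table.index


def test_contact_params_validation():
    with pytest.raises(ValueError):
        ContactParams(max_gap_nm=0.0)
    with pytest.raises(ValueError):
        ContactParams(volume_mode="banana")
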