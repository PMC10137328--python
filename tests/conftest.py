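"""Shared fixtures: the canonical panel and single-shape scenes.

Heavy rasterizations are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitomorph.classify import classify_population
from mitomorph.morphometry import skeleton_profile
from mitomorph.synthetic import (
    CAPSULE,
    SPHERE,
    SceneSpec,
    ShapeSpec,
    make_fixture_panel,
    make_moas_fixture,
    rasterize_scene,
)
from mitomorph.volume_io import extract_objects


@pytest.fixture(scope="session")
def panel():
    """Canonical panel: sphere / 3 µm capsule / 6 µm capsule / MOAS + 5 ER tubes."""
    return make_fixture_panel(seed=0)


@pytest.fixture(scope="session")
def panel_objects(panel):
    mito, _, _ = panel
    return extract_objects(mito, exclude_boundary=False)


@pytest.fixture(scope="session")
def panel_calls(panel):
    mito, _, _ = panel
    calls, comp = classify_population(mito, exclude_boundary=False)
    return calls, comp


@pytest.fixture(scope="session")
def moas_scene():
    """3-bead MOAS at nominal geometry (500 nm beads, 65 nm necks), 8 nm grid."""
    return make_moas_fixture()


@pytest.fixture(scope="session")
def moas_profile(moas_scene):
    mito, _, _ = moas_scene
    obj = extract_objects(mito, exclude_boundary=False)[0]
    return obj, skeleton_profile(obj, mito.spacing)


@pytest.fixture(scope="session")
def iso_sphere_500():
    """Rasterized 500 nm sphere on an 8 nm isotropic grid, centre on a voxel centre."""
    shape = ShapeSpec(SPHERE, (300.0, 300.0, 300.0), diameter=500.0)
    mito, _, _ = rasterize_scene(SceneSpec(spacing=(8.0, 8.0, 8.0), objects=[shape]))
    obj = extract_objects(mito, exclude_boundary=False)[0]
    return mito, obj


@pytest.fixture(scope="session")
def iso_capsule_2um():
    """2 µm x 0.2 µm capsule along x on an 8 nm isotropic grid."""
    shape = ShapeSpec(CAPSULE, (300.0, 300.0, 1200.0), (0, 0, 1.0), 200.0, 2000.0)
    mito, _, _ = rasterize_scene(SceneSpec(spacing=(8.0, 8.0, 8.0), objects=[shape]))
    obj = extract_objects(mito, exclude_boundary=False)[0]
    return mito, obj


def random_blob(n_voxels: int, seed: int) -> np.ndarray:
    """Connected random-walk blob of ~n_voxels voxel coordinates (z, y, x)."""
    rng = np.random.default_rng(seed)
    pos = np.array([0, 0, 0])
    seen = {tuple(pos)}
    while len(seen) < n_voxels:
        step = rng.integers(-1, 2, size=3)
        pos = pos + step
        seen.add(tuple(pos))
    coords = np.array(sorted(seen))
    return coords - coords.min(axis=0)
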