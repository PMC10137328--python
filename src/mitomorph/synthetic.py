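"""Synthetic label-volume generator with exact geometric ground truth.

Real volume-EM reconstructions of dendritic mitochondria are segmented by
hand and rarely deposited, so validation here runs on phantoms: scenes of
continuous solids — spheres (round mitochondria), capsules (tubules),
beaded "mitochondria-on-a-string" (MOAS: spheres joined by thin cylindrical
necks) and ER tubes placed at controlled surface-to-surface gaps around the
contact-site criterion.  Each scene rasterizes to a pair of co-registered
label volumes plus a :class:`GroundTruth` record of every generating
parameter, enabling parameter-recovery tests of the whole pipeline.

Rasterization rule: a voxel belongs to a shape iff its physical *centre*
lies inside the continuous solid.  This is unbiased for volume estimates
(over- and under-shoot cancel to first order) and makes scenes exactly
reproducible from their spec.

Nominal MOAS geometry (beads ~0.5 µm across, necks ~65 nm) follows the
morphological definition used for dendritic mitochondria in the AD-model
volume-EM literature; see the thresholds in :mod:`mitomorph.classify`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .volume_io import ER, MITOCHONDRION, LabelVolume

SPHERE = "sphere"
CAPSULE = "capsule"
MOAS = "moas"

#: default acquisition-matched spacing (z, y, x) nm — 50 nm sections, 8 nm pixels
ACQUISITION_SPACING = (50.0, 8.0, 8.0)
#: isotropic grid used where analytic comparisons need low discretization error
ISO_SPACING = (8.0, 8.0, 8.0)

DEFAULT_BEAD_DIAMETER_NM = 500.0
DEFAULT_NECK_DIAMETER_NM = 65.0


class GenerationError(ValueError):
    """Scene cannot be rasterized as specified."""


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise GenerationError("orientation vector must be nonzero")
    return v / n


@dataclass
class ShapeSpec:
    """One continuous mitochondrial solid.

    ``center`` and ``orientation`` are in (z, y, x) physical nm; the default
    orientation points along +x.  ``length`` for a capsule is end-to-end
    (hemispherical caps included).  A MOAS is ``n_beads`` spheres of
    ``bead_diameter`` whose centres are spaced ``bead_diameter +
    neck_length`` along the axis, joined by cylinders of ``neck_diameter``
    — so ``neck_length`` is the surface-to-surface bead separation.
    """

    kind: str
    center: tuple[float, float, float]
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    diameter: float | None = None
    length: float | None = None
    n_beads: int = 3
    bead_diameter: float = DEFAULT_BEAD_DIAMETER_NM
    neck_diameter: float = DEFAULT_NECK_DIAMETER_NM
    neck_length: float = 400.0

    def __post_init__(self) -> None:
        if self.kind not in (SPHERE, CAPSULE, MOAS):
            raise GenerationError(f"unknown shape kind {self.kind!r}")
        if self.kind == SPHERE and not (self.diameter and self.diameter > 0):
            raise GenerationError("sphere needs a positive diameter")
        if self.kind == CAPSULE:
            if not (self.diameter and self.length):
                raise GenerationError("capsule needs diameter and length")
            if self.length <= self.diameter:
                raise GenerationError("capsule end-to-end length must exceed its diameter")
        if self.kind == MOAS:
            if self.n_beads < 2:
                raise GenerationError("a MOAS needs at least 2 beads")
            if self.neck_diameter >= self.bead_diameter:
                raise GenerationError("neck diameter must be below bead diameter")

    @property
    def true_length_nm(self) -> float:
        """End-to-end extent of the solid along its axis (max point-pair distance)."""
        if self.kind == SPHERE:
            return float(self.diameter)
        if self.kind == CAPSULE:
            return float(self.length)
        return (self.n_beads - 1) * (self.bead_diameter + self.neck_length) + self.bead_diameter

    @property
    def true_type(self) -> str:
        """Morphological class implied by the generating parameters."""
        from .classify import ClassificationThresholds

        th = ClassificationThresholds()
        if self.kind == MOAS:
            return "IV"
        L = self.true_length_nm / 1000.0  # µm
        if L <= th.type1_max_length_um:
            return "I"
        if L <= th.type2_max_length_um:
            return "II"
        return "III"

    def half_extents_nm(self) -> np.ndarray:
        """Conservative per-axis half extent around ``center`` (axis-aligned bound)."""
        u = _unit(self.orientation)
        if self.kind == SPHERE:
            return np.full(3, self.diameter / 2.0)
        if self.kind == CAPSULE:
            h = self.length / 2.0 - self.diameter / 2.0
            return np.abs(u) * h + self.diameter / 2.0
        h = (self.n_beads - 1) * (self.bead_diameter + self.neck_length) / 2.0
        return np.abs(u) * h + self.bead_diameter / 2.0

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Boolean inside-test for an (n, 3) array of physical (z, y, x) points."""
        c = np.asarray(self.center, dtype=float)
        u = _unit(self.orientation)
        if self.kind == SPHERE:
            return _dist_to_point(pts, c) <= self.diameter / 2.0
        if self.kind == CAPSULE:
            h = self.length / 2.0 - self.diameter / 2.0
            return _dist_to_segment(pts, c - h * u, c + h * u) <= self.diameter / 2.0
        inside = np.zeros(len(pts), dtype=bool)
        step = self.bead_diameter + self.neck_length
        first = c - u * step * (self.n_beads - 1) / 2.0
        prev = None
        for i in range(self.n_beads):
            b = first + u * step * i
            inside |= _dist_to_point(pts, b) <= self.bead_diameter / 2.0
            if prev is not None:
                inside |= _dist_to_segment(pts, prev, b) <= self.neck_diameter / 2.0
            prev = b
        return inside


def _dist_to_point(pts: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.linalg.norm(pts - c, axis=1)


def _dist_to_segment(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return _dist_to_point(pts, a)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


@dataclass
class ERPlacementSpec:
    """An ER tube apposed to one mitochondrial object at a known gap.

    The tube is a capsule parallel to the target's axis, offset along
    ``direction`` (perpendicular to the axis) so that the continuous
    surface-to-surface distance at closest approach equals ``gap_nm``.
    ``patch_extent_nm`` is the length of the straight tube section, i.e. the
    extent over which the tube runs parallel to the target.
    """

    target_index: int
    gap_nm: float
    patch_extent_nm: float = 300.0
    er_tube_diameter_nm: float = 100.0
    direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    offset_along_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.gap_nm < 0:
            raise GenerationError("gap_nm must be >= 0")
        if self.patch_extent_nm <= 0:
            raise GenerationError("patch_extent_nm must be > 0")

    def to_shape(self, target: ShapeSpec) -> ShapeSpec:
        u = _unit(target.orientation)
        v = _unit(self.direction)
        if abs(float(u @ v)) > 1e-9:
            raise GenerationError("ER offset direction must be perpendicular to target axis")
        if target.kind == SPHERE:
            r_t = target.diameter / 2.0
        elif target.kind == CAPSULE:
            r_t = target.diameter / 2.0
        else:
            r_t = target.bead_diameter / 2.0
        r_er = self.er_tube_diameter_nm / 2.0
        center = (
            np.asarray(target.center, dtype=float)
            + v * (r_t + self.gap_nm + r_er)
            + u * self.offset_along_nm
        )
        return ShapeSpec(
            kind=CAPSULE,
            center=tuple(center),
            orientation=tuple(u),
            diameter=self.er_tube_diameter_nm,
            length=self.patch_extent_nm + self.er_tube_diameter_nm,
        )


@dataclass
class SceneSpec:
    """Full description of one synthetic scene."""

    spacing: tuple[float, float, float] = ISO_SPACING
    objects: list[ShapeSpec] = field(default_factory=list)
    er_placements: list[ERPlacementSpec] = field(default_factory=list)
    rng_seed: int = 0
    grid_shape: tuple[int, int, int] | None = None
    allow_boundary_contact: bool = False


@dataclass
class ObjectTruth:
    label: int
    kind: str
    type_label: str
    length_nm: float
    diameter_nm: float | None
    n_beads: int | None
    bead_diameter_nm: float | None
    neck_diameter_nm: float | None
    neck_length_nm: float | None


@dataclass
class PlacementTruth:
    er_label: int
    target_label: int
    gap_nm: float
    patch_extent_nm: float
    er_tube_diameter_nm: float


@dataclass
class GroundTruth:
    """Generating parameters of a rasterized scene, for parameter-recovery tests."""

    objects: list[ObjectTruth]
    placements: list[PlacementTruth]
    rng_seed: int
    spacing: tuple[float, float, float]

    def type_of(self, label: int) -> str:
        for o in self.objects:
            if o.label == label:
                return o.type_label
        raise KeyError(label)


def _object_truth(label: int, s: ShapeSpec) -> ObjectTruth:
    return ObjectTruth(
        label=label,
        kind=s.kind,
        type_label=s.true_type,
        length_nm=s.true_length_nm,
        diameter_nm=s.diameter,
        n_beads=s.n_beads if s.kind == MOAS else None,
        bead_diameter_nm=s.bead_diameter if s.kind == MOAS else None,
        neck_diameter_nm=s.neck_diameter if s.kind == MOAS else None,
        neck_length_nm=s.neck_length if s.kind == MOAS else None,
    )


def _paint(
    labels: np.ndarray,
    shape: ShapeSpec,
    label: int,
    spacing: np.ndarray,
    allow_boundary: bool,
) -> None:
    """Rasterize ``shape`` into ``labels`` (in place) with the given label id."""
    c = np.asarray(shape.center, dtype=float)
    half = shape.half_extents_nm()
    lo_nm, hi_nm = c - half, c + half
    lo = np.floor(lo_nm / spacing - 0.5).astype(int) - 1
    hi = np.ceil(hi_nm / spacing - 0.5).astype(int) + 2
    grid = np.array(labels.shape)
    if (lo < 0).any() or (hi > grid).any():
        if not allow_boundary:
            raise GenerationError(
                f"shape {shape.kind} at {shape.center} exceeds the grid "
                f"(bbox voxels {lo}..{hi} vs grid {tuple(grid)}); enlarge the grid "
                "or set allow_boundary_contact for a boundary fixture"
            )
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, grid)
    idx = [np.arange(lo[a], hi[a]) for a in range(3)]
    zz, yy, xx = np.meshgrid(*idx, indexing="ij")
    pts = (np.stack([zz, yy, xx], axis=-1).reshape(-1, 3) + 0.5) * spacing
    inside = shape.contains(pts).reshape(zz.shape)
    sub = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    clash = inside & (sub != 0) & (sub != label)
    if clash.any():
        raise GenerationError(
            f"shape {shape.kind} at {shape.center} overlaps an existing object of the same class"
        )
    sub[inside] = label


def _auto_grid(spec: SceneSpec, spacing: np.ndarray) -> tuple[int, int, int]:
    shapes = list(spec.objects) + [
        p.to_shape(spec.objects[p.target_index]) for p in spec.er_placements
    ]
    if not shapes:
        return (1, 1, 1)
    hi = np.zeros(3)
    for s in shapes:
        hi = np.maximum(hi, np.asarray(s.center) + s.half_extents_nm())
    return tuple(int(v) for v in np.ceil(hi / spacing).astype(int) + 2)


def rasterize_scene(spec: SceneSpec) -> tuple[LabelVolume, LabelVolume, GroundTruth]:
    """Rasterize a scene into co-registered mitochondria and ER label volumes.

    Deterministic given the spec (the seed is carried into the ground truth
    for provenance).  Overlapping shapes of the same organelle class raise
    :class:`GenerationError`, since their labels could not be separated.
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    grid = spec.grid_shape or _auto_grid(spec, spacing)
    mito = np.zeros(grid, dtype=np.uint16)
    er = np.zeros(grid, dtype=np.uint16)
    truth_objects: list[ObjectTruth] = []
    truth_placements: list[PlacementTruth] = []
    for i, s in enumerate(spec.objects, start=1):
        _paint(mito, s, i, spacing, spec.allow_boundary_contact)
        truth_objects.append(_object_truth(i, s))
    for j, p in enumerate(spec.er_placements, start=1):
        er_shape = p.to_shape(spec.objects[p.target_index])
        _paint(er, er_shape, j, spacing, spec.allow_boundary_contact)
        truth_placements.append(
            PlacementTruth(
                er_label=j,
                target_label=p.target_index + 1,
                gap_nm=p.gap_nm,
                patch_extent_nm=p.patch_extent_nm,
                er_tube_diameter_nm=p.er_tube_diameter_nm,
            )
        )
    truth = GroundTruth(
        objects=truth_objects,
        placements=truth_placements,
        rng_seed=spec.rng_seed,
        spacing=tuple(spacing),
    )
    prov = f"synthetic scene, seed={spec.rng_seed}"
    mito_vol = LabelVolume(mito, tuple(spacing), MITOCHONDRION, prov)
    er_vol = LabelVolume(er, tuple(spacing), ER, prov)
    return mito_vol, er_vol, truth


# --- fixture alignment -------------------------------------------------------
#
# Gap fixtures probe a 25 nm criterion on an 8 nm grid, where surface
# positions quantize to the half-grid.  To keep the rasterized gap faithful
# to the continuous one near the criterion, fixture capsules are posed so
# their apposed surface sits 7/8 of a voxel above the outermost included
# voxel centre: the mesh then under-shoots the true surface by the same
# 3 nm that the ER-side estimate under-shoots, and the two errors cancel at
# the closest approach.  This is a fixture pose choice only — arbitrary
# scenes keep whatever pose the caller specifies.

SURFACE_PHASE_NM = 7.0


def _aligned_axis_coord(nominal: float, radius: float, step: float) -> float:
    """Shift a capsule-centre coordinate so its +surface has the fixture phase."""
    target_mod = (step / 2.0 + SURFACE_PHASE_NM) % step
    shift = (target_mod - (nominal + radius)) % step
    return nominal + shift


def _voxel_center_coord(nominal: float, step: float) -> float:
    """Nearest coordinate of the form (k + 0.5) * step."""
    return (round(nominal / step - 0.5) + 0.5) * step


def make_gap_fixture(
    gap_nm: float,
    spacing: tuple[float, float, float] = ISO_SPACING,
    capsule_length_nm: float = 2000.0,
    capsule_diameter_nm: float = 300.0,
    patch_extent_nm: float = 300.0,
) -> SceneSpec:
    """One x-aligned capsule with one ER tube at the requested surface gap."""
    sz, sy, sx = spacing
    r = capsule_diameter_nm / 2.0
    zc = _voxel_center_coord(r + 100.0, sz)
    yc = _aligned_axis_coord(r + 100.0, r, sy)
    xc = capsule_length_nm / 2.0 + 100.0
    cap = ShapeSpec(CAPSULE, (zc, yc, xc), (0.0, 0.0, 1.0), capsule_diameter_nm, capsule_length_nm)
    er = ERPlacementSpec(0, gap_nm, patch_extent_nm)
    return SceneSpec(spacing=spacing, objects=[cap], er_placements=[er])


def make_moas_fixture(
    n_beads: int = 3,
    bead_diameter_nm: float = DEFAULT_BEAD_DIAMETER_NM,
    neck_diameter_nm: float = DEFAULT_NECK_DIAMETER_NM,
    neck_length_nm: float = 400.0,
    spacing: tuple[float, float, float] = ISO_SPACING,
) -> tuple[LabelVolume, LabelVolume, GroundTruth]:
    """A single MOAS at nominal geometry, axis running through voxel centres.

    Centre-aligned pose: the medial axis of the string coincides with a row
    of voxel centres, so skeleton nodes sample the true axis rather than a
    half-voxel-offset neighbour — the configuration for radius-recovery
    studies.
    """
    sz, sy, sx = spacing
    r = bead_diameter_nm / 2.0
    half_len = ((n_beads - 1) * (bead_diameter_nm + neck_length_nm) + bead_diameter_nm) / 2.0
    center = (
        _voxel_center_coord(r + 100.0, sz),
        _voxel_center_coord(r + 100.0, sy),
        _voxel_center_coord(half_len + 100.0, sx),
    )
    shape = ShapeSpec(
        MOAS,
        center,
        (0.0, 0.0, 1.0),
        n_beads=n_beads,
        bead_diameter=bead_diameter_nm,
        neck_diameter=neck_diameter_nm,
        neck_length=neck_length_nm,
    )
    return rasterize_scene(SceneSpec(spacing=spacing, objects=[shape]))


def make_fixture_panel(
    seed: int = 0,
    spacing: tuple[float, float, float] = ISO_SPACING,
) -> tuple[LabelVolume, LabelVolume, GroundTruth]:
    """Canonical validation panel: one of each morphological type plus gap probes.

    Contents (all axes along +x, one z plane):

    * sphere, 400 nm across (Type I)
    * capsule, 3 µm end-to-end (Type II) — carries five ER tubes at surface
      gaps {10, 20, 24, 26, 40} nm straddling the 25 nm contact criterion
    * capsule, 6 µm (Type III)
    * MOAS: 3 beads of 500 nm joined by 65 nm necks, 400 nm long (Type IV)

    Fully deterministic; ``seed`` is recorded in the ground truth.
    """
    sz, sy, sx = spacing
    zc = _voxel_center_coord(450.0, sz)
    cap_r = 150.0
    y_capsule = _aligned_axis_coord(1200.0, cap_r, sy)
    sphere = ShapeSpec(SPHERE, (zc, 400.0, 500.0), diameter=400.0)
    capsule2 = ShapeSpec(CAPSULE, (zc, y_capsule, 1700.0), (0, 0, 1.0), 300.0, 3000.0)
    capsule3 = ShapeSpec(CAPSULE, (zc, 2400.0, 3300.0), (0, 0, 1.0), 300.0, 6000.0)
    moas = ShapeSpec(
        MOAS,
        (zc, _voxel_center_coord(3400.0, sy), _voxel_center_coord(1500.0, sx)),
        (0, 0, 1.0),
        n_beads=3,
        bead_diameter=DEFAULT_BEAD_DIAMETER_NM,
        neck_diameter=DEFAULT_NECK_DIAMETER_NM,
        neck_length=400.0,
    )
    gaps = (10.0, 20.0, 24.0, 26.0, 40.0)
    placements = [
        ERPlacementSpec(1, gap, patch_extent_nm=300.0, offset_along_nm=off)
        for gap, off in zip(gaps, (-1200.0, -600.0, 0.0, 600.0, 1200.0))
    ]
    spec = SceneSpec(
        spacing=spacing,
        objects=[sphere, capsule2, capsule3, moas],
        er_placements=placements,
        rng_seed=seed,
    )
    return rasterize_scene(spec)


#: per-type parameter jitter bounds (nm) used by :func:`sample_population` —
#: chosen once to span the morphological class definitions with realistic margins
POPULATION_BOUNDS = {
    "I": {"diameter": (250.0, 480.0)},
    "II": {"length": (700.0, 4600.0), "diameter": (250.0, 350.0)},
    "III": {"length": (5400.0, 7000.0), "diameter": (250.0, 350.0)},
    "IV": {
        "n_beads": (2, 4),
        "bead_diameter": (420.0, 580.0),
        "neck_diameter": (55.0, 80.0),
        "neck_length": (300.0, 700.0),
    },
}


def sample_population(
    composition: Mapping[str, float],
    n: int,
    seed: int,
    spacing: tuple[float, float, float] = (10.0, 10.0, 10.0),
) -> tuple[SceneSpec, GroundTruth]:
    """Draw ``n`` mitochondria with the given type fractions (multinomial).

    Shapes are shelf-packed into one grid, axes along +x, with per-type
    parameter jitter inside the class bounds.  Returns the scene spec and a
    ground truth whose object labels match rasterization order (label = index
    + 1), so predicted classes can be scored against truth.
    """
    if n < 1:
        raise ValueError("population size n must be >= 1")
    fracs = {k: float(v) for k, v in composition.items()}
    if any(v < 0 or v > 1 for v in fracs.values()):
        raise ValueError("composition fractions must lie in [0, 1]")
    if abs(sum(fracs.values()) - 1.0) > 1e-6:
        raise ValueError("composition fractions must sum to 1")
    rng = np.random.default_rng(seed)
    types = list(fracs)
    counts = rng.multinomial(n, [fracs[t] for t in types])
    type_seq = [t for t, c in zip(types, counts) for _ in range(c)]
    rng.shuffle(type_seq)

    shapes: list[ShapeSpec] = []
    margin = 400.0
    row_budget = 9000.0
    cursor_x = margin
    cursor_y = margin
    row_height = 0.0
    z_center = 500.0
    for t in type_seq:
        b = POPULATION_BOUNDS[t]
        if t == "I":
            s = ShapeSpec(SPHERE, (0, 0, 0), diameter=rng.uniform(*b["diameter"]))
        elif t in ("II", "III"):
            s = ShapeSpec(
                CAPSULE,
                (0, 0, 0),
                (0, 0, 1.0),
                diameter=rng.uniform(*b["diameter"]),
                length=rng.uniform(*b["length"]),
            )
        else:
            s = ShapeSpec(
                MOAS,
                (0, 0, 0),
                (0, 0, 1.0),
                n_beads=int(rng.integers(b["n_beads"][0], b["n_beads"][1] + 1)),
                bead_diameter=rng.uniform(*b["bead_diameter"]),
                neck_diameter=rng.uniform(*b["neck_diameter"]),
                neck_length=rng.uniform(*b["neck_length"]),
            )
        half = s.half_extents_nm()
        extent_x, extent_y = 2 * half[2], 2 * half[1]
        if cursor_x + extent_x > row_budget and cursor_x > margin:
            cursor_y += row_height + margin
            cursor_x = margin
            row_height = 0.0
        s.center = (z_center, cursor_y + extent_y / 2.0, cursor_x + extent_x / 2.0)
        cursor_x += extent_x + margin
        row_height = max(row_height, extent_y)
        shapes.append(s)

    spec = SceneSpec(spacing=spacing, objects=shapes, rng_seed=seed)
    truth = GroundTruth(
        objects=[_object_truth(i, s) for i, s in enumerate(shapes, start=1)],
        placements=[],
        rng_seed=seed,
        spacing=spacing,
    )
    return spec, truth
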