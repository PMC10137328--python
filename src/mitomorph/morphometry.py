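"""Per-object 3D shape measures for segmented organelles.

All measures are computed in physical units from the voxel spacing:

* volume — exact in the voxel model: count x voxel volume (µm³);
* surface area — area of a marching-cubes iso-surface of the binary mask
  extracted at physical spacing (µm²).  Counting exposed voxel faces instead
  would overestimate a sphere's area by ~50% regardless of resolution;
* length — the largest Euclidean distance between any two points of the
  object (convex-hull accelerated, brute force for small objects);
* aspect ratio — length divided by the widest extent perpendicular to the
  length axis ("length to width ratio"), always >= 1;
* sphericity — psi = pi^(1/3) (6V)^(2/3) / SA, equal to 1 for a perfect
  sphere and below 1 for elongated or irregular shapes;
* skeleton radius profile — medial curve from 3D thinning on an
  isotropically resampled mask, with the local radius (Euclidean distance
  transform) at each node.  This is the substrate for detecting the
  bead/neck alternation of mitochondria-on-a-string.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area
from skimage.morphology import skeletonize

from .volume_io import OrganelleObject

NM3_TO_UM3 = 1e-9
NM2_TO_UM2 = 1e-6
NM_TO_UM = 1e-3

#: sphericity / aspect-ratio discretization slack at <=8 nm effective resolution
EPS_DISC = 0.02


@dataclass
class MorphometryRecord:
    """Shape measures for one organelle object."""

    object_id: int
    volume_um3: float
    surface_area_um2: float
    length_um: float
    aspect_ratio: float
    sphericity: float
    touches_boundary: bool
    flags: list[str] = field(default_factory=list)


def measure_volume(obj: OrganelleObject, spacing: Sequence[float]) -> float:
    """Object volume in µm³ (exact: voxel count times voxel volume)."""
    sz, sy, sx = spacing
    return obj.n_voxels * sz * sy * sx * NM3_TO_UM3


def _cropped_mask(obj: OrganelleObject, pad: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Tight boolean mask around the object plus the crop origin (voxel index)."""
    coords = obj.voxel_coords
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad + 1
    mask = np.zeros(tuple(hi - lo), dtype=bool)
    mask[tuple((coords - lo).T)] = True
    return mask, lo


def _ellipsoid_area_nm2(semi: Sequence[float]) -> float:
    # Thomsen's approximation, exact to ~1%
    a, b, c = sorted(semi, reverse=True)
    p = 1.6075
    return 4 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)


def surface_mesh(
    obj: OrganelleObject,
    spacing: Sequence[float],
    smooth_sigma_nm: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Iso-surface mesh (vertices in physical nm, triangle index array).

    The binary mask is meshed at iso-level 0.5; with ``smooth_sigma_nm`` > 0
    it is first blurred with a physically isotropic Gaussian, which removes
    voxelization facets while leaving flat surface patches in place (the
    kernel is symmetric, so the 0.5 level does not move on locally flat or
    centrally symmetric geometry).
    """
    spacing = np.asarray(spacing, dtype=float)
    pad = 2 if smooth_sigma_nm == 0 else 2 + int(np.ceil(3 * smooth_sigma_nm / spacing.min()))
    mask, lo = _cropped_mask(obj, pad=pad)
    field_ = mask.astype(np.float32)
    if smooth_sigma_nm > 0:
        ndimage.gaussian_filter(field_, sigma=smooth_sigma_nm / spacing, output=field_)
    verts, faces, _, _ = marching_cubes(field_, level=0.5, spacing=tuple(spacing))
    verts = verts + (lo + 0.5) * spacing  # voxel centres sit at (index + 0.5) * spacing
    return verts, faces


def measure_surface_area(
    obj: OrganelleObject,
    spacing: Sequence[float],
    smooth_sigma_nm: float | None = None,
) -> float:
    """Surface area in µm² from the iso-surface mesh.

    Default smoothing is one finest-axis voxel, which brings the mesh area
    of rasterized analytic solids within a few percent of truth (unsmoothed
    binary marching cubes carries a systematic faceting overestimate).
    A single-voxel object has no meaningful mesh; it falls back to the
    analytic area of the one-voxel ellipsoid and is flagged implicitly by
    its size.
    """
    spacing = np.asarray(spacing, dtype=float)
    if obj.n_voxels == 1:
        return _ellipsoid_area_nm2(spacing / 2.0) * NM2_TO_UM2
    if smooth_sigma_nm is None:
        smooth_sigma_nm = float(spacing.min())
    verts, faces = surface_mesh(obj, spacing, smooth_sigma_nm=smooth_sigma_nm)
    return float(mesh_surface_area(verts, faces)) * NM2_TO_UM2


def _boundary_points_nm(obj: OrganelleObject, spacing: Sequence[float]) -> np.ndarray:
    """Physical centres of the object's surface voxels (6-connectivity surface)."""
    mask, lo = _cropped_mask(obj, pad=1)
    interior = ndimage.binary_erosion(mask)
    coords = np.argwhere(mask & ~interior) + lo
    return (coords + 0.5) * np.asarray(spacing, dtype=float)


def _farthest_pair(pts: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Maximum pairwise distance and the achieving pair of points."""
    if len(pts) < 2:
        return 0.0, pts[0], pts[0]
    cand = pts
    if len(pts) > 400:
        try:
            cand = pts[ConvexHull(pts).vertices]
        except QhullError:  # degenerate (coplanar/collinear) point sets
            pass
    d = pdist(cand)
    k = int(np.argmax(d))
    n = len(cand)
    # unravel condensed index
    i = int(n - 2 - math.floor(math.sqrt(-8 * k + 4 * n * (n - 1) - 7) / 2.0 - 0.5))
    j = int(k + i + 1 - n * (n - 1) // 2 + (n - i) * ((n - i) - 1) // 2)
    return float(d[k]), cand[i], cand[j]


def measure_length(obj: OrganelleObject, spacing: Sequence[float]) -> float:
    """Length in µm: the distance between the two most distant points."""
    pts = _boundary_points_nm(obj, spacing)
    dist, _, _ = _farthest_pair(pts)
    return dist * NM_TO_UM


def aspect_ratio(obj: OrganelleObject, spacing: Sequence[float]) -> tuple[float, list[str]]:
    """Aspect ratio (major/minor extent) and any degeneracy flags.

    Major axis: the farthest point pair.  Minor axis: the maximum pairwise
    distance of surface points projected onto the plane orthogonal to the
    major axis — the widest "width" seen perpendicular to the length.
    """
    spacing = np.asarray(spacing, dtype=float)
    flags: list[str] = []
    pts = _boundary_points_nm(obj, spacing)
    voxel_diag = float(np.linalg.norm(spacing))
    if len(pts) < 2:
        return 1.0, ["degenerate_single_point"]
    major, p, q = _farthest_pair(pts)
    # The single farthest voxel pair can tilt off the true axis by ~1 voxel
    # per end, inflating the perpendicular extent by length * tilt.  Average
    # the clusters of near-extreme points at both ends for a stable axis.
    diag = voxel_diag
    d_from_q = np.linalg.norm(pts - q, axis=1)
    d_from_p = np.linalg.norm(pts - p, axis=1)
    end_a = pts[d_from_q >= d_from_q.max() - diag].mean(axis=0)
    end_b = pts[d_from_p >= d_from_p.max() - diag].mean(axis=0)
    axis = end_b - end_a
    if np.linalg.norm(axis) < 1e-9:
        axis = q - p
    axis = axis / max(np.linalg.norm(axis), 1e-12)
    perp = pts - np.outer(pts @ axis, axis)
    # orthonormal in-plane basis for a 2D farthest-pair search
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    plane = np.stack([perp @ e1, perp @ e2], axis=1)
    if len(plane) > 400:
        try:
            plane = plane[ConvexHull(plane).vertices]
        except QhullError:
            pass
    minor = float(pdist(plane).max()) if len(plane) > 1 else 0.0
    if minor < voxel_diag:
        minor = voxel_diag
        flags.append("degenerate_minor_axis")
    ar = major / minor
    if ar < 1.0:
        ar = 1.0
    return float(ar), flags


def sphericity(volume_um3: float, surface_area_um2: float) -> float:
    """psi = pi^(1/3) (6 V)^(2/3) / SA; 1 for a perfect sphere."""
    if volume_um3 <= 0 or surface_area_um2 <= 0:
        raise ValueError("sphericity needs positive volume and surface area")
    return math.pi ** (1 / 3) * (6 * volume_um3) ** (2 / 3) / surface_area_um2


def compute_morphometry(obj: OrganelleObject, spacing: Sequence[float]) -> MorphometryRecord:
    """All shape measures for one object."""
    v = measure_volume(obj, spacing)
    sa = measure_surface_area(obj, spacing)
    length = measure_length(obj, spacing)
    ar, flags = aspect_ratio(obj, spacing)
    return MorphometryRecord(
        object_id=obj.id,
        volume_um3=v,
        surface_area_um2=sa,
        length_um=length,
        aspect_ratio=ar,
        sphericity=sphericity(v, sa),
        touches_boundary=obj.touches_boundary,
        flags=flags,
    )


def morphometry_table(records: Sequence[MorphometryRecord]) -> pd.DataFrame:
    """Records as a tidy table (one row per object)."""
    return pd.DataFrame(
        [
            {
                "object_id": r.object_id,
                "V_um3": r.volume_um3,
                "SA_um2": r.surface_area_um2,
                "length_um": r.length_um,
                "AR": r.aspect_ratio,
                "sphericity": r.sphericity,
                "touches_boundary": r.touches_boundary,
            }
            for r in records
        ]
    )


# --- skeleton radius profile -------------------------------------------------

_NEIGHBOR_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


@dataclass
class SkeletonProfile:
    """Medial-axis graph of one object with a local radius at every node.

    Node positions and radii are in physical nm.  ``paths`` lists maximal
    simple paths (node-index sequences) between branch points / endpoints,
    covering every skeleton edge exactly once.
    """

    object_id: int
    nodes_nm: np.ndarray
    radii_nm: np.ndarray
    edges: list[tuple[int, int]]
    paths: list[list[int]]
    flags: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.radii_nm)

    def path_arclengths(self, path: Sequence[int]) -> np.ndarray:
        """Cumulative arclength (nm) along a path, starting at 0."""
        p = self.nodes_nm[list(path)]
        if len(p) < 2:
            return np.zeros(len(p))
        steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


def _resample_isotropic(mask: np.ndarray, spacing: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-neighbour resampling of a mask to the finest spacing axis."""
    fine = float(spacing.min())
    factors = spacing / fine
    if np.allclose(factors, 1.0):
        return mask, fine
    out = ndimage.zoom(
        mask.astype(np.uint8), zoom=factors, order=0, mode="grid-constant", grid_mode=True
    ).astype(bool)
    return out, fine


def _decompose_paths(
    neighbors: dict[int, list[int]],
) -> list[list[int]]:
    deg = {n: len(nb) for n, nb in neighbors.items()}
    special = {n for n, d in deg.items() if d != 2}
    if not special and neighbors:  # pure cycle
        special = {next(iter(neighbors))}
    paths: list[list[int]] = []
    seen: set[frozenset[int]] = set()
    for s in sorted(special):
        for nb in neighbors[s]:
            e = frozenset((s, nb))
            if e in seen:
                continue
            seen.add(e)
            path = [s, nb]
            prev, cur = s, nb
            while cur not in special:
                nxt = next((m for m in neighbors[cur] if m != prev), None)
                if nxt is None:
                    break
                seen.add(frozenset((cur, nxt)))
                path.append(nxt)
                prev, cur = cur, nxt
            paths.append(path)
    return paths


def skeleton_profile(obj: OrganelleObject, spacing: Sequence[float]) -> SkeletonProfile:
    """Medial curve with per-node radius, via thinning on an isotropic grid.

    Thinning directly on a strongly anisotropic grid (e.g. 50 vs 8 nm)
    biases the medial axis toward the coarse axis, so the mask is first
    resampled (nearest-neighbour) to an isotropic grid at the finest
    spacing.  Radii are the Euclidean distance transform of the resampled
    mask, in physical nm.
    """
    spacing = np.asarray(spacing, dtype=float)
    mask, lo = _cropped_mask(obj, pad=1)
    iso, fine = _resample_isotropic(mask, spacing)
    origin = lo * spacing  # physical position of the crop corner
    edt = ndimage.distance_transform_edt(iso, sampling=fine)
    flags: list[str] = []

    skel = skeletonize(iso)
    coords = np.argwhere(skel)
    if len(coords) == 0:  # too thin to survive thinning: single medial point
        idx = np.unravel_index(int(np.argmax(edt)), edt.shape)
        coords = np.array([idx])
        flags.append("low_confidence_single_node")

    nodes_nm = (coords + 0.5) * fine + origin
    radii = edt[tuple(coords.T)].astype(float)
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    neighbors: dict[int, list[int]] = {i: [] for i in range(len(coords))}
    edges: list[tuple[int, int]] = []
    for c, i in index.items():
        for off in _NEIGHBOR_OFFSETS:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None and j > i:
                neighbors[i].append(j)
                neighbors[j].append(i)
                edges.append((i, j))
    paths = _decompose_paths(neighbors) if edges else [[0]] if len(coords) == 1 else []
    if not paths:
        paths = [[i] for i in range(len(coords))]
    return SkeletonProfile(
        object_id=obj.id,
        nodes_nm=nodes_nm,
        radii_nm=radii,
        edges=edges,
        paths=paths,
        flags=flags,
    )
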