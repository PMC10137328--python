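# mitomorph

3D morphometry of mitochondria and mitochondria–ER contact sites (MERCS)
from segmented volume-EM label stacks.

## What it is for

Serial block-face scanning EM of brain tissue yields aligned label volumes
in which mitochondria and endoplasmic reticulum have been traced slice by
slice (typical voxel size 8 × 8 × 50 nm — strongly anisotropic). In
Alzheimer-model mice, dendritic mitochondria shift from normal tubules to
*mitochondria-on-a-string* (MOAS): chains of ~0.5 µm teardrop beads joined
by thin (~65 nm) membranous necks, with greatly expanded ER apposition.
Quantifying that shift needs per-organelle shape measures, a reproducible
four-type morphology classification, and contact-site metrics — all in
physical units, respecting the voxel anisotropy. This package provides
that pipeline for anyone analysing co-registered organelle label volumes,
plus a synthetic phantom generator so every metric can be validated against
known geometry.

## The measures

For each 26-connected mitochondrion (objects touching the grid boundary
are excluded by default, as their borders are incomplete):

- **Volume** `V = n_voxels · s_z s_y s_x` (µm³), exact in the voxel model.
- **Surface area** `SA` (µm²) from a marching-cubes iso-surface at physical
  spacing (voxel-face counting would overestimate a sphere by ~50%).
- **Length** `L`: the distance between the two most distant points of the
  object (convex-hull accelerated).
- **Aspect ratio** `AR = major / minor`: length over the widest extent
  perpendicular to the length axis ("length-to-width ratio"), ≥ 1.
- **Sphericity** `ψ = π^{1/3} (6V)^{2/3} / SA`: exactly 1 for a perfect
  sphere, smaller for elongated or irregular shapes.
- **Skeleton radius profile**: a medial curve from 3D thinning (on an
  isotropically resampled mask) with the Euclidean-distance-transform
  radius at every node.

Classification: Type I — round, `L ≤ 0.5 µm`; Type II — tubule,
`0.5 < L < 5 µm`; Type III — tubule, `L ≥ 5 µm`; Type IV — MOAS, called
structurally from the radius profile (≥ 2 bead runs with radius ≥ 150 nm
separated by ≥ 1 neck run with radius ≤ 45 nm persisting over ≥ 100 nm),
regardless of total length.

MERCS: a contact site is a connected patch of mitochondrial surface whose
membrane-to-membrane distance to one ER object is ≤ 25 nm. Per patch the
pipeline reports area, end-to-end contact length, juxtaposed ER volume and
mean gap; per mitochondrion the percent surface coverage; and per pool
(Types I–III together, MOAS separately) mean ± SEM, with one-way ANOVA and
one-sided unpaired Student's t-tests for group comparisons.

## Worked example

The built-in panel contains one object of each type plus five ER tubes at
surface gaps {10, 20, 24, 26, 40} nm straddling the 25 nm criterion:

```python
from mitomorph import (
    make_fixture_panel, extract_objects, compute_morphometry, skeleton_profile,
    classify_mitochondrion, surface_gap_field, detect_contacts, coverage,
)

mito, er, truth = make_fixture_panel(seed=0)
for obj in extract_objects(mito, exclude_boundary=False):
    rec = compute_morphometry(obj, mito.spacing)
    call = classify_mitochondrion(rec, skeleton_profile(obj, mito.spacing))
    cov = coverage(rec, detect_contacts(obj, er))
    print(f"object {obj.id}: V={rec.volume_um3:.4f} um3  SA={rec.surface_area_um2:.3f} um2  "
          f"L={rec.length_um:.2f} um  AR={rec.aspect_ratio:.2f}  psi={rec.sphericity:.3f}  "
          f"-> Type {call.type}  ({cov.n_contacts} MERCS, {cov.coverage_percent:.1f}% covered)")
```

prints

```
object 1: V=0.0334 um3  SA=0.502 um2  L=0.40 um  AR=1.00  psi=1.001  -> Type I  (0 MERCS, 0.0% covered)
object 2: V=0.2047 um3  SA=2.832 um2  L=2.99 um  AR=10.01  psi=0.593  -> Type II  (3 MERCS, 2.0% covered)
object 3: V=0.4161 um3  SA=5.664 um2  L=5.98 um  AR=19.96  psi=0.476  -> Type III  (0 MERCS, 0.0% covered)
object 4: V=0.1989 um3  SA=2.497 um2  L=2.29 um  AR=4.52  psi=0.660  -> Type IV  (0 MERCS, 0.0% covered)
```

The 0.4 µm sphere reads ψ ≈ 1 and Type I; the 3 µm capsule carries exactly
the three ER tubes at gaps ≤ 25 nm as MERCS (the 26 and 40 nm tubes are
rejected); the 6 µm capsule is Type III; and the bead string is Type IV by
its radius profile even though its length (2.3 µm) falls in the Type II
range.

A shell CLI wraps the same pipeline:

```sh
mitomorph run-all --seed 0 --out report/          # built-in panel
mitomorph classify my_mito.tif --preset round-max-0.5um --out out/
mitomorph contacts my_mito.tif my_er.tif --max-gap 25 --out out/
```

Volumes are multi-page TIFF (with a JSON sidecar carrying
`spacing_nm = [z, y, x]`) or HDF5 (`/labels` with `spacing_nm` attribute).

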