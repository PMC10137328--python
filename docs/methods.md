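# Methods

## Scope and model

The pipeline starts from co-registered, already-segmented integer label
volumes (mitochondria and ER), with voxel spacing given in nm in (z, y, x)
order, z being the sectioning axis. Nothing upstream of that — imaging,
alignment, tracing — is modelled. All geometry is computed in physical
units; with 50 nm sections against 8 nm pixels, index-space distances would
be wrong by up to a factor 6.25. A voxel's physical centre is
`(index + 0.5) · spacing` per axis.

Objects are 26-connected components of each nonzero label. 26-connectivity
matches how manual tracing joins corner-touching profiles across sections;
6-connectivity would fragment thin oblique necks. The exclusion rule for
objects with incomplete borders is automated as *boundary-touching*
exclusion: an object cut by the imaged block cannot be measured whole. This
is a proxy for a manual judgement and is recorded as such in reports; it is
on by default for measurement runs and off for synthetic ground-truth runs
(phantoms are constructed to fit inside the grid).

## Shape measures

**Volume** is exact in the voxel model: count × voxel volume.

**Surface area** comes from a marching-cubes iso-surface (level 0.5)
extracted at physical spacing. Plain binary marching cubes carries a
faceting bias: on a rasterized 500 nm sphere at 8 nm it overestimates the
analytic area by ~9%. The mask is therefore pre-smoothed with a physically
isotropic Gaussian of σ = one finest-axis voxel (8 nm by default), which
brings the sphere to +0.1% and a 400 nm cube to −3.5% (corner rounding);
halving the grid changes the estimate by < 0.5%. The σ default was
calibrated once on these analytic solids. A single-voxel object has no
meaningful mesh and falls back to the analytic area of the one-voxel
ellipsoid (Thomsen approximation).

**Length** is the maximum pairwise distance between surface-voxel centres
(the "two most distant points"), computed brute-force for small objects and
over convex-hull vertices otherwise — the maximising pair is always a hull
vertex pair.

**Aspect ratio** divides that length by the *minor extent*: the maximum
pairwise distance of surface points projected onto the plane orthogonal to
the major axis. This matches the "length-to-width" reading; PCA eigenvalue
widths are moment-based and differ materially for beaded shapes (a
configurable alternative was considered and rejected as the default for
that reason). The single farthest voxel pair can tilt off the true axis by
~1 voxel per end, which inflates the perpendicular extent by length × tilt
(an 18% error on a 10:1 capsule); the axis is therefore taken between the
centroids of the near-extreme point clusters at both ends, after which a
2 µm × 0.2 µm capsule reads AR = 10.01 and a sphere 1.000. Degenerate
(collinear) objects floor the minor extent at one voxel diagonal and are
flagged.

**Sphericity** ψ = π^(1/3)(6V)^(2/3)/SA is evaluated from the V and SA
above. Discretization slack ε = 0.02 applies at ≤ 8 nm effective
resolution: rasterized spheres may read up to ψ ≈ 1.002. Because SA
estimators differ between software packages, absolute ψ values are
comparable only within one method; cross-method comparisons should be
relative.

**Skeleton radius profile.** The mask is resampled (nearest-neighbour) to
an isotropic grid at the finest spacing — thinning directly on a 6.25:1
anisotropic grid biases the medial axis toward the coarse axis — then
thinned to a medial curve (3D skeletonization). Each skeleton node carries
the Euclidean distance transform of the resampled mask, in nm, as its local
radius; no half-voxel correction is applied to radii (on centred fixtures
the raw EDT reads a 65 nm neck as 66 nm and a 500 nm bead as 495 nm, both
inside one voxel diagonal). The node graph (26-adjacency of skeleton
voxels) is decomposed into maximal simple paths between endpoints/branch
points. Objects too thin to survive thinning get a single node at the EDT
maximum, flagged low-confidence.

## Classification

Decision order: structural MOAS test first, then the length ladder.
Thresholds (defaults): Type I `L ≤ 0.5 µm`; Type II `0.5 < L < 5 µm`;
Type III `L ≥ 5 µm` ("5 µm or longer" — the boundary value is Type III,
while exactly 0.5 µm is still Type I). Two presets ship for the Type I/II
boundary, `round-max-0.5um` (default) and `round-max-1um`, because the
round-class cutoff is quoted both ways in the literature for this scheme;
the active preset is recorded in every report.

MOAS detection translates the descriptive bead/neck geometry into radius
gates with margin: bead runs need local radius ≥ 150 nm (nominal beads are
250 nm in radius, but teardrops taper); neck runs need radius ≤ 45 nm
(nominal necks are 32.5 nm and the EDT can overestimate by about a voxel)
persisting over ≥ 100 nm of arclength (a noise gate — single-node EDT dips
on anisotropic data must not trigger MOAS). A neck counts only when beads
flank it through the graph; a thin terminal tail is not a neck. "More than
one teardrop" means ≥ 2 beads plus ≥ 1 qualifying neck. Necks running
longer than 5 µm are still counted but flagged. The classification reports
AR and volume as descriptors but decides tubule classes by length; where
the source scheme is ambiguous about using AR/volume versus length, length
plus the structural MOAS test is the implemented reading.

## Contact sites

Gaps are membrane-to-membrane: from each mito mesh face centroid, distance
to the nearest ER *boundary-voxel centre* minus half the voxel extent along
the approach direction (ER voxel centres sit half a voxel inside the
rasterized membrane), clamped at 0. A centre-to-centre criterion would be
meaningless against a 25 nm threshold on 50 nm sections. Faces with gap
≤ 25 nm (configurable) are contact faces, grouped into patches by mesh edge
adjacency and split per ER object id, so apposition to two ER tubules gives
two MERCS.

Per patch: area = Σ face areas; length = maximum centroid-pair distance
(the "beginning-to-end" line; note this measures the *detected band*, which
legitimately extends past the geometrically apposed section when the gap is
well below threshold — flanks and curved tube ends are then also within
25 nm); mean gap; and contact volume. "Contact volume" is under-determined
as a concept — this implementation defines it as the ER volume lying within
the gap threshold of the mitochondrion, attributed to the nearest patch
(mode `er`), with a gap-slab alternative (`gap`: inter-membrane voxels
within threshold of both surfaces) behind a flag; the mode used is recorded
in reports. Coverage = 100 × Σ patch areas / SA of the same mesh, in
[0, 100] by construction; "perimeter covered" is implemented as this 3D
surface fraction. Pooling for group tables follows the convention of
analysing tubule classes I–III together and MOAS separately; empty pools
are reported as absent, not zero.

## Statistics

Mean ± SEM (SEM = sd(n−1)/√n, absent for n = 1), classical fixed-effects
one-way ANOVA, and one-sided unpaired Student's t (pooled variance; Welch
behind a flag). The one-sided direction must be stated explicitly per
comparison. Zero-variance ties report p = 0.5 with a flag. No
multiple-testing correction is applied by default; reports state what was
used.

## Synthetic phantoms and what they do (not) show

The generator rasterizes continuous solids — spheres, capsules, and bead
strings (spheres of bead diameter spaced bead + neck length apart, joined
by neck-diameter cylinders) — plus ER tubes placed parallel to a target at
an exact surface-to-surface gap. A voxel is labelled iff its centre lies
inside the solid (unbiased for volume); scenes are deterministic given
their spec, same-class overlaps are rejected, and every generating
parameter is returned as ground truth. Beads are spheres, not literal
teardrops: the classifier consumes radii, for which the teardrop detail is
immaterial; "teardrop" remains a qualitative descriptor.

Fixture poses are chosen deliberately. Gap fixtures align the apposed
capsule surface at 7/8-voxel phase above the outermost included voxel
centre: at that phase the mesh under-shoots the true surface by the same
~3 nm the ER-side estimate under-shoots, the errors cancel at closest
approach, and the rasterized gaps for true {10, 20, 24, 26, 40} nm read
{16, 24, 24, 32, 40} nm — each within one voxel diagonal of truth and
splitting correctly at the 25 nm criterion (an arbitrary pose cannot
distinguish 24 from 26 nm on an 8 nm grid; the information is simply not in
the mask). Radius-recovery fixtures run the string axis through voxel
centres, otherwise every skeleton node sits half a voxel off-axis and the
bead radius reads ~8 nm low. User scenes keep whatever pose they specify.

Population scenes draw types multinomially and jitter parameters within
class bounds (round: 250–480 nm; tubules: 250–350 nm across, 0.7–4.6 µm or
5.4–7 µm long; strings: 2–4 beads of 420–580 nm, necks 55–80 nm × 0.3–0.7
µm — ranges chosen once around the nominal morphology definitions), shelf-
packed into one volume at 10 nm isotropic spacing. The validation panel
uses 40 objects (comparable to the 60–100 organelles per group typical of
volume-EM morphometry studies, sized to keep the full pipeline run around
a minute); type recovery against generator truth is ≥ 95% by test.

Phantoms validate the *measurement* chain, not the biology: they contain no
segmentation error, no membrane thickness, no grayscale noise, no curved or
branched tubules, and ER as tubes/shells only. Passing tests therefore
certify that the metrics recover known geometry under the acquisition's
anisotropy and discretization — not that manual segmentations of real
tissue are accurate.

## Numerical choices and degenerate inputs

- Mesh smoothing σ = finest spacing; single-voxel objects use an analytic
  ellipsoid area; empty volumes yield empty object lists, not errors.
- EDT radii are reported raw (no half-voxel subtraction); gap estimates
  subtract half a voxel along the approach direction.
- Length/AR use surface voxels only (identical extremes, fewer points);
  hull failures on degenerate point sets fall back to brute force.
- Boundary values classify downward at 0.5 µm and upward at 5 µm.
- Label volumes are written with the narrowest lossless unsigned integer
  dtype; spacing must come from metadata or an explicit override — there
  is no silent default.
- All randomness flows through one seeded generator recorded in the ground
  truth; reports regenerate byte-identically from identical inputs.

## Known limitations

- Boundary-touching is an imperfect proxy for "incomplete borders".
- Absolute SA (hence ψ) is estimator-dependent; compare within-method.
- Contact length of wide-slack contacts measures the detected band, not
  the nominal apposed extent (see above).
- The skeleton of near-spherical objects is a degenerate cluster; bead
  counts there rely on the single-node convention.
- Sub-voxel gap discrimination is impossible in adverse poses; detection
  accuracy is one voxel diagonal, which at 8 nm isotropic is ~14 nm and on
  native 50 nm sections correspondingly coarser in z.
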