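# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `lungmorph`, at the level a user needs to interpret its
output and its test suite.

## Conventions

Axis order is `(z, y, x)`, indices are 0-based, crop intervals half-open.
All physical lengths are micrometres; voxel spacing is isotropic, and
anisotropic inputs are rejected rather than silently resampled. Binary
masks mark **tissue** as foreground (`True`) — segmentation produces
bright-voxel = tissue masks — and the thickness analysis inverts
internally because it measures the air phase. Every operation appends a
provenance record to the volume's `meta['history']`, which is append-only.

The entrance-dose utility evaluates
`D[Gy] = 1.602e-4 · I0[photons/µm²] · hν[eV] / (µ⁻¹[µm] · ρ[g/cm³])`
verbatim on that unit scale, with no unit auto-conversion.

## Segmentation pipeline

The pipeline order is fixed: background correction → Otsu threshold
(stored) → ridge enhancement → threshold at the stored value → isolated
voxel removal → connected-component filter. Parameters and the stored
threshold are recorded in the output mask's metadata.

**Background plane.** Each slice is grayscale-eroded with a disk
(default radius 20 px), which suppresses thin bright structures so the
illumination plane of region-of-interest tomography stands out. Only
pixels at ≥ one erosion radius from the slice border enter the fit: border
pixels see a clipped structuring element and would bias the slope low (we
measured up to ~14% bias without the restriction). Histogram extremes —
outside the [5th, 95th] percentile of the eroded interior — are masked,
and a plane `a·x + b·y + c` is least-squares fitted. Only the gradient
terms are subtracted; the offset `c` is kept so gray values remain
comparable across slices. On textured phantom slices with a known gradient
the slope is recovered to within ~5%.

**Otsu threshold.** One threshold per volume, from a 256-bin histogram,
maximising the between-class variance. Plateaus (e.g. across empty bins)
are resolved to the lowest bin, with a relative 1e-9 tolerance so the tie
rule is robust to floating-point noise. The returned threshold is the
first bin centre of the upper class; tissue = gray ≥ threshold.

**Ridged image.** Septa too weak for the global threshold are recovered
from 1D line profiles along 0°, 45°, 90° and 135° in each slice (diagonals
run along array diagonals at √2 px steps, without resampling; profiles are
2D per-slice, as the pipeline is defined on slices). A local maximum is
*accepted* when its prominence over the flanking minima lies in
`[min_margin, max_margin]` and the contiguous run of samples above
(flank base + `min_margin`) has width within `[min_width, max_width]`.
Of an accepted peak, the samples above flank base +
max(`min_margin`, prominence/2) — the peak core — are raised to the
volume's brightest value. Marking only the core keeps the recovered
septum as thin as the structure itself even when blur or an oblique
crossing broadens the acceptance run; marking the whole run instead
thickens every wall by roughly the blur width. `max_margin` acts as an
upper prominence cutoff for rejecting very bright vessel-like lines and is
off (`inf`) by default. Ridging only ever brightens pixels, so the tissue
set after thresholding the ridged image is a superset of the plain
thresholded tissue at the same threshold.

Default ridge parameters (`min_width 1, max_width 11, min_margin 12`)
were calibrated on the default phantom conditions below; `max_width 11 px`
admits the runs produced by oblique, blurred crossings of 2-voxel walls.

**Cleanup.** A tissue voxel with zero tissue neighbours in its
26-neighbourhood is always an artifact (real septa connect to tissue) and
is removed; the operation is idempotent and never adds tissue. Finally,
26-connected tissue components smaller than `min_component` voxels
(default 27 — a one-voxel cube at the smallest plausible septal junction
scale) are removed.

**Ensemble.** `segmentation_ensemble` runs a list of parameter variants
(typically 9, sweeping `min_margin` and `max_width`) and tags each mask
with its variant id. Downstream densities and range fractions are computed
per variant and reported as mean ± sample standard deviation. Variants
sharing an erosion radius reuse the background-corrected volume and its
Otsu value; results are identical to running `segment_volume` per variant.

## Local air-volume thickness

Definition: τ(p) = 2·max{r : p ∈ sph(x, r) ⊆ Ω}. On the voxel lattice one
convention is shared by the production algorithm and the brute-force
oracle, which makes "voxelwise equal" a meaningful test:

* candidate centres x are phase voxel centres;
* the admissible radius at x is r(x) = d(x) − ½ voxel, where d(x) is the
  Euclidean distance to the nearest background voxel centre — a single
  isolated voxel therefore has τ = spacing;
* a sphere covers voxel p iff |center(p) − x| ≤ r;
* the world outside the volume counts as background (implemented by
  padding with one background layer before the distance transform), so
  spheres are truncated at the field of view and padding a volume with the
  complementary phase changes nothing.

The fast path computes the distance transform, extracts a distance ridge
by dropping every centre whose sphere is contained in a 26-neighbour's
sphere (containment is transitive and strictly increases the radius, so a
removal chain always ends at a kept centre — the maximum is unchanged,
exactly), and paints the remaining spheres largest-first into bounding-box
views. The brute-force oracle evaluates the definition literally and is
quadratic in the phase size (guarded at 2·10⁵ voxels). The two agree to
float precision on random masks; analytic checks: digital balls of radius
r give modal τ within one voxel of 2r, a 5-voxel slab gives τ = 5 exactly
on its central plane.

τ statistics use an analysis window of 20–170 µm by default: structures
below 20 µm are smaller than the smallest expected alveoli, and above
~170 µm large airways moving through the region of interest bias the
distributions. Range fractions are volume fractions over
20–50 / 50–80 / 80–110 / ≥110 µm, normalised over the union of the
requested ranges so an exhaustive partition sums to 100%. An
`exclude_border` option drops the border voxel layer from the statistics
(the conservative choice when much of the air touches the field of view).

## Kernel density estimation

1D densities use a Gaussian kernel evaluated by linear binning on the
fixed output grid plus discrete convolution, renormalised on the grid's
support (densities truncated to [floor, cap] integrate to 1 there). The
default bandwidth is the Botev diffusion / improved-Sheather-Jones plug-in
fixed point, computed from a 1024-bin DCT of the sample; samples that are
too small or degenerate fall back to Silverman's rule. The bandwidth is
never allowed below half a grid step and is recorded in the output.

For comparisons **across** inflation states the thickness analysis uses a
single fixed bandwidth (`COMPARISON_BANDWIDTH_UM` = 6 µm) for all states:
plug-in selectors choose a different bandwidth per state and, at phantom
sample sizes, leave per-cell granularity in the density, which makes the
argmax hop between local peaks; a common bandwidth of about half the
cell-to-cell τ spread yields one smooth, comparable mode per state.

2D interface-shape densities are binned on a 256×256 grid and smoothed
with a diagonal normal-reference (Silverman) bandwidth matrix. Evaluation
grids for curvature densities span the 0.5–99.5 percentile range of the
samples (padded 10%): marching-cubes meshes carry a small tail of extreme
curvature outliers at single-voxel features that would otherwise dominate
the support. Mass above the κ1 = κ2 diagonal is zeroed and the density
renormalised.

## Curvature estimation

Surfaces are extracted by marching cubes on the air indicator at level
0.5, in physical coordinates, with triangle winding and vertex normals
oriented from air into tissue (the orientation is verified by probing the
air indicator along the normals and flipped globally if needed). Raw
marching-cubes meshes overestimate area by ~8% (staircase effect);
20 iterations of umbrella-operator Laplacian smoothing at step 0.5 remove
the staircase (smoothed ball area within 5% of analytic, enclosed volume
shrinkage < 5%, logged). No volume-preserving correction is applied.

The normal-cycle curvature tensor at vertex v accumulates, over every mesh
edge e intersecting the geodesic ball B(v, R),
`β(e) · ℓ(e ∩ B) · ē ēᵀ`, where β(e) is the dihedral angle between the
adjacent face normals, signed positive at convex edges (w.r.t. the
outward normals), and ē the unit edge direction; the sum is normalised by
the barycentric area of the reached vertices. Geodesic balls are grown by
Dijkstra over the edge graph with Euclidean edge weights; since graph
distance dominates Euclidean distance, each ball is computed on the
subgraph of vertices within Euclidean distance R (a large constant-factor
saving, exact). Edges with one endpoint inside the ball contribute their
clipped length.

The tensor is projected onto the tangent plane and eigen-decomposed; the
eigenpair aligned with the normal is discarded. The normal-cycle tensor
carries each principal curvature on the *perpendicular* tangent
eigendirection (for a cylinder the creases run along the axis but encode
the circumferential bending), which swaps the eigendirections but leaves
the unordered eigenvalue pair unchanged — the pair is reported as
κ1 ≤ κ2 directly. H and K derive from them, so H² ≥ K holds by
construction; `principal_from_HK` clamps negative discriminants (possible
when H and K come from independent estimates) and logs the count.

Vertices are excluded from all densities when their geodesic ball touches
a mesh boundary (open regions at the volume faces would bias the ISD
edges) or when the neighborhood is degenerate — fewer than 4 reached
vertices or area below 10⁻³·πR², which happens at marching-cubes sliver
vertices whose neighborhoods hold almost no area and whose area-normalised
tensors are meaningless.

Geodesic radius presets follow the two working scales (3.5 and 15, in the
mesh's native µm); analytic checks use R = 5 µm. On a smoothed 25 µm air
sphere the median κ matches 1/r within ~6% and K within ~3%; on a 20 µm
cylinder the flat direction is < 10⁻⁵ µm⁻¹ and the bent one within ~4% of
1/r; a flat patch gives exactly zero.

ISD regions: region 1 κ1, κ2 > 0 (ellipsoidal, convex toward tissue —
alveolus-like), region 4 κ1, κ2 < 0 (concave), saddles κ1 < 0 < κ2 split
into region 2 (|κ1| ≥ κ2, ties to 2) and region 3 (|κ1| < κ2); exact
zeros join the adjacent non-saddle region, and boundary-excluded vertices
get label 0. Larger geodesic radii absorb small dimples on a cavity wall
into the surrounding shape class, so the region-1 share of an alveolus
with a dimpled patch is non-decreasing in R. `map_to_slices` rasterises
each vertex to its nearest voxel; a voxel's label is the majority region
among its vertices, ties to the lower index.

## Rigid registration

Volumes acquired at different pressures are related by a Euclidean
transform. `estimate_rigid` solves the orthogonal Procrustes problem from
≥ 3 non-collinear user-provided landmark pairs (Kabsch: SVD with sign
correction — never a reflection). `apply_rigid` resamples the moving
volume into the fixed frame at a common output shape, linear interpolation
for gray volumes and nearest-neighbour for masks (no fractional labels).
A known 10° rotation + translation is recovered to machine precision and
a mask survives a transform round trip with interior Dice ≥ 0.98.

## Phantom: what it emulates, and what it does not

`generate_foam` builds a Voronoi tessellation of seed points drawn by
dart throwing with a minimum separation and a margin from the volume
boundary (so every cell centre lies in air). Tissue consists of walls
within half a wall thickness of a Voronoi facet — computed as
(d₂ − d₁) ≤ wall thickness from the two nearest-seed distances — plus a
boundary shell; a `duct_fraction` of adjacent cell pairs have their shared
wall opened as an alveolar-duct surrogate. Nominal cell diameters are
equivalent-sphere diameters from the in-volume air labels. All operations
are pure functions of (spec, seed).

The default `min_separation` (twice the wall thickness) gives an irregular
Poisson-Voronoi foam. The trend conditions (`trend_spec`) raise it to 70%
of the mean seed spacing: real alveolar parenchyma has a much narrower
cell-size distribution than a Poisson foam, and the narrow distribution is
what lets a ×1.3 inflation move density mass cleanly across the 50 µm
range edge, as in the reported pressure series.

`inflate(truth, factor)` rescales the seed geometry about the volume
centre and regenerates walls at unchanged thickness, keeping the field of
view fixed (the region-of-interest surrogate; border cells are cropped).
Nominal diameters scale by the factor exactly, referring to the generating
tessellation rather than the crop. This mimics septa stretching at
constant thickness; it is a geometric surrogate, not a mechanical model.

`render_image` assigns air/tissue gray values, renders interior septal
voxels at `septa_contrast` of the air-tissue contrast (the
partial-volume / phase-retrieval surrogate for walls at the resolution
limit), adds a per-slice plane `a·x + b·y + c`, Gaussian blur (sigma in
µm), and additive Gaussian noise. Noise is Gaussian, not Poisson:
post-reconstruction noise in phase-retrieved tomograms is approximately
additive, and it is one parameter fewer.

**Default study conditions.** Two optics are modelled: a high-resolution
phantom (1.1 µm pixels, 96³ ≈ 105 µm field of view, 12 cells ≈ 45–65 µm
diameters, 2-voxel septa) as the segmentation test-bed, and a
low-resolution trend phantom (2.9 µm pixels, ~280 µm field of view,
160 cells, 1-voxel walls, baseline thickness mode ≈ 40 µm — the small end
of the adult murine airspace range) for inflation trends, whose larger
field holds enough complete cells that inflation moves real density mass
instead of being clipped. Default imaging (`DEFAULT_IMAGING`:
septa_contrast 0.3, blur 0.55 µm, noise 3, gradient (0.18, 0.12, 0) over
the slice) is calibrated so that a plain global Otsu threshold loses the
interior septa — their rendered peaks fall below the stored threshold —
while the full ridged pipeline recovers them (Dice ≈ 0.96, septal recall
≈ 0.90 across phantom seeds). The loss under plain Otsu is essentially
complete rather than partial: the Otsu optimum is bistable in the septal
contrast, so there is no stable intermediate operating point.

**What passing phantom tests do not show.** The phantom has polyhedral
cells with flat faces, so its interface-shape distribution is dominated
by near-zero and saddle curvatures where real parenchyma shows a clear
region-1 (ellipsoidal) peak; curvature *trends* under inflation transfer,
absolute shape compositions do not. The renderer has no phase-contrast
fringes, ring artifacts, or motion; the gradient is a plane per slice, as
assumed by the correction step — real local-tomography backgrounds are
only approximately planar. Inflation is geometric, not biomechanical.

## Problem sizes

Analyses in the test suite and the acceptance script run at desk scale,
chosen to exercise every claim: 20–24³ volumes for the brute-force
oracle, 96³ phantoms for segmentation and thickness (≈ 10 s per thickness
map), 80³ for mesh analyses (~150 k vertices, a few seconds per curvature
field), 9-variant ensembles for uncertainty bands. The full suite runs in
under ten minutes on one CPU.
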