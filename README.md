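# lungmorph

Quantitative morphometry of high-resolution 3D lung images at the alveolar
scale: a septa-preserving segmentation pipeline for low-dose phase-contrast
tomograms, local air-volume thickness maps (maximum inscribed sphere), and
air-to-tissue interface curvature analysis (normal cycles, interface shape
distributions), plus a synthetic alveolar-foam phantom generator so the
whole chain can be validated without synchrotron data.

The intended users are researchers analysing micro-CT / tomographic
microscopy volumes of lung parenchyma (or any comparable two-phase foam
material) who need to quantify how airspaces inflate and how the
gas-exchange surface is shaped.

## The methods in brief

**Segmentation.** Region-of-interest (local) tomography superimposes a
per-slice background illumination plane, and interalveolar septa — walls
often only 1–2 voxels thick — reconstruct with too little contrast for a
global threshold. The pipeline: per-slice background-plane estimation
(grayscale erosion with a 20 px disk, histogram-extreme masking,
least-squares plane fit) and subtraction; a single Otsu threshold computed
and stored; a "ridged image" in which 1D line profiles along 0°, 45°, 90°
and 135° are scanned for local maxima whose run width and prominence lie in
user bounds, with accepted septum pixels raised to the brightest gray
value; thresholding at the stored Otsu value; removal of free-standing
voxels; and a 3D connected-component size filter. Running several ridge
parameter variants yields a segmentation ensemble whose spread becomes the
uncertainty band of every downstream statistic.

**Local air-volume thickness.** For a point p in the air phase Ω,

&nbsp;&nbsp;&nbsp;&nbsp;τ(p) = 2 · max { r : p ∈ sph(x, r) ⊆ Ω }

— the diameter of the largest sphere containing p that fits in the
airspace. Implemented as Euclidean distance transform → distance-ridge
extraction → sphere propagation, voxelwise identical to a literal
brute-force evaluation of the definition (shipped as the testing oracle).
Per-voxel τ values are summarised as kernel-density estimates (plug-in
bandwidth) and as volumetric fractions over reporting ranges
(20–50, 50–80, 80–110, ≥110 µm).

**Interface curvature.** The air-to-tissue surface is extracted with
marching cubes, smoothed with the umbrella-operator Laplacian, and each
vertex receives a normal-cycle curvature tensor accumulated over a
geodesic neighborhood: Σ β(e)·ℓ(e∩B)·ē ēᵀ normalised by the neighborhood
area, where β(e) is the signed dihedral angle at edge e. Its tangent-plane
eigenvalues are the principal curvatures κ1 ≤ κ2, with
H = (κ1+κ2)/2, K = κ1κ2 and κ1,2 = H ∓ √(H²−K). With normals oriented from
air into tissue, alveolus-like cavities give κ1, κ2 > 0 (region 1 of the
interface shape distribution); the 2D (κ1, κ2) density and the 1D H and K
densities summarise the surface's shape composition.

**Phantom.** A Voronoi-foam phantom with known ground truth (tissue mask,
cell centres, nominal diameters): air cells separated by walls of
controlled physical thickness, optional duct-like openings, isotropic
"inflation" that rescales the cell geometry at fixed wall thickness, and a
renderer that adds the imaging artifacts the pipeline must overcome —
background gradient, blur, noise and reduced septal contrast.

## Worked example

```python
import numpy as np
from lungmorph import (
    PhantomSpec, generate_foam, render_image, segment_volume,
    local_thickness, thickness_density, range_fractions,
    extract_surface, smooth_mesh, normal_cycle_curvature, classify_regions,
)
from lungmorph.phantom import DEFAULT_IMAGING

truth = generate_foam(PhantomSpec(seed=7))     # 96^3 voxels at 1.1 µm
image = render_image(truth, DEFAULT_IMAGING)   # gradient + blur + noise + weak septa
mask = segment_volume(image)                   # full pipeline, default parameters

septal_recall = mask.data[truth.septa].mean()
print(f"septal recall: {septal_recall:.2f}")

tmap = local_thickness(mask, phase="air")
fractions = range_fractions(tmap)
print("range fractions (%):", np.round(fractions, 1))

mesh = smooth_mesh(extract_surface(mask), iterations=20, step=0.5)
field = normal_cycle_curvature(mesh, geodesic_radius=3.5)
labels = classify_regions(field)
region1 = (labels[field.included] == 1).mean()
print(f"region-1 (alveolus-like) vertex share: {region1:.2f}")
```

prints

```
septal recall: 0.93
range fractions (%): [100.   0.   0.   0.]
region-1 (alveolus-like) vertex share: 0.47
```

The septal recall says 93% of the ground-truth interalveolar wall voxels
survive segmentation (a plain Otsu threshold recovers essentially none of
them at these artifact levels). All airspace thicknesses fall in the
20–50 µm range because this high-resolution phantom's 105 µm field of view
holds only a dozen ~45 µm cells. Just under half of the
interface vertices are convex toward the tissue (region 1): a polyhedral
foam mixes alveolus-like patches with flat faces and saddle-like edges.
On the inflation phantoms the interface-shape peak moves toward smaller
curvatures, as expected when airspaces enlarge.

A command-line interface mirrors the library:
`lungmorph phantom`, `lungmorph register`, `lungmorph segment`,
`lungmorph segment-ensemble`, `lungmorph thickness`, `lungmorph curvature`
and `lungmorph dose` (see `lungmorph --help`).

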