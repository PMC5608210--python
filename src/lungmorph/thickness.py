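"""Local air-volume thickness: maximum-inscribed-sphere diameter maps.

The local thickness τ(p) of a point p in a phase Ω is twice the largest
radius r such that some sphere sph(x, r) ⊆ Ω contains p.  On the voxel
lattice the package uses one unambiguous convention shared by the fast
algorithm and the brute-force oracle:

* candidate sphere centres are phase voxel centres x;
* the largest admissible radius at x is r(x) = d(x) − 1/2 voxel, where d(x)
  is the Euclidean distance to the nearest background voxel centre
  (a single isolated voxel therefore has τ = spacing);
* a sphere of radius r covers voxel p iff |center(p) − x| ≤ r.

``local_thickness`` implements the classic pipeline — Euclidean distance
transform, distance-ridge extraction, sphere propagation from ridge points —
where the ridge is the set of centres whose sphere is not contained in a
26-neighbour's sphere.  Containment is transitive, so dropping dominated
centres never changes the maximum and the result is voxelwise identical to
the brute-force evaluation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .density import DensityEstimate, kde_1d
from .volio import BinaryVolume, GrayVolume

#: Analysis floor/cap in µm: structures below 20 µm are smaller than the
#: smallest expected alveolar diameters; above 170 µm, large airways moving
#: through the region of interest bias the distributions.
DEFAULT_FLOOR_UM = 20.0
DEFAULT_CAP_UM = 170.0
#: Table-style reporting ranges, µm (last range is open-ended).
DEFAULT_RANGES = ((20.0, 50.0), (50.0, 80.0), (80.0, 110.0), (110.0, np.inf))
#: Fixed bandwidth (µm) for comparing thickness densities ACROSS inflation
#: states.  Plug-in selectors pick a different bandwidth per state and, at
#: phantom sample sizes, leave per-cell granularity in the density, making
#: the argmax jump between local peaks; a common bandwidth of half a typical
#: cell-to-cell τ spread gives one comparable smooth mode per state.
COMPARISON_BANDWIDTH_UM = 6.0

_NEIGHBOR_OFFSETS = np.array(
    [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
)


@dataclasses.dataclass
class ThicknessMap:
    """Per-voxel local thickness τ in µm on the analysed phase (0 elsewhere)."""

    tau: np.ndarray
    spacing: float
    source_mask: dict = dataclasses.field(default_factory=dict)
    floor: float | None = None
    cap: float | None = None

    @property
    def samples(self) -> np.ndarray:
        """τ values of the analysed-phase voxels."""
        return self.tau[self.tau > 0]

    def samples_excluding_border(self) -> np.ndarray:
        """τ values of interior phase voxels (volume-border layer dropped).

        The conservative alternative for region-of-interest data: spheres
        at the border are truncated by the field of view, biasing τ low.
        """
        interior = np.zeros(self.tau.shape, dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True
        return self.tau[interior & (self.tau > 0)]


def _phase_array(mask: BinaryVolume, phase: str) -> np.ndarray:
    if phase == "air":
        arr = ~mask.data
    elif phase == "tissue":
        arr = mask.data
    else:
        raise ValueError("phase must be 'air' or 'tissue'")
    if not arr.any():
        raise ValueError(f"selected phase '{phase}' is empty")
    if arr.all():
        raise ValueError("selected phase fills the whole volume; thickness is unbounded")
    return arr


def local_thickness(mask: BinaryVolume, phase: str = "air") -> ThicknessMap:
    """Maximum-inscribed-sphere thickness map of the selected phase, in µm.

    The world outside the volume counts as background, so spheres are
    truncated at the field-of-view border and padding the volume with the
    complementary phase leaves every τ unchanged.
    """
    arr = _phase_array(mask, phase)
    # pad with one background layer: the nearest out-of-volume voxel
    padded = np.pad(arr, 1, constant_values=False)
    dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]
    radius = np.where(arr, dist - 0.5, -np.inf)

    # distance ridge: drop centres whose sphere fits inside a neighbour's
    dominated = np.zeros(arr.shape, dtype=bool)
    for off in _NEIGHBOR_OFFSETS:
        step = float(np.linalg.norm(off))
        shifted = np.full(arr.shape, -np.inf)
        src = tuple(slice(max(0, o), n + min(0, o)) for o, n in zip(off, arr.shape))
        dst = tuple(slice(max(0, -o), n + min(0, -o)) for o, n in zip(off, arr.shape))
        shifted[dst] = radius[src]
        dominated |= shifted >= radius + step - 1e-9
    ridge = arr & ~dominated

    # Sphere propagation, largest radius first: paint each ridge sphere's
    # diameter into the voxels it covers, keeping the per-voxel maximum.
    # Balls are painted as bounding-box views with a precomputed spherical
    # mask per radius group (descending, so most voxels are written once).
    tau_vox = np.zeros(arr.shape, dtype=np.float64)
    centers = np.argwhere(ridge)
    radii = radius[ridge]
    order = np.argsort(-radii, kind="stable")
    centers, radii = centers[order], radii[order]
    shape = arr.shape
    group_edges = np.flatnonzero(np.diff(radii)) + 1
    for group in np.split(np.arange(len(radii)), group_edges):
        r = radii[group[0]]
        m = int(np.floor(r + 1e-9))
        rng = np.arange(-m, m + 1)
        zz, yy, xx = np.meshgrid(rng, rng, rng, indexing="ij")
        ball = zz**2 + yy**2 + xx**2 <= r * r + 1e-9
        diam = 2.0 * r
        for c in centers[group]:
            lo = np.maximum(c - m, 0)
            hi = np.minimum(c + m + 1, shape)
            view = tau_vox[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            bview = ball[lo[0] - c[0] + m : hi[0] - c[0] + m, lo[1] - c[1] + m : hi[1] - c[1] + m, lo[2] - c[2] + m : hi[2] - c[2] + m]
            np.maximum(view, diam, out=view, where=bview)
    tau_vox[~arr] = 0.0
    return ThicknessMap(tau_vox * mask.spacing, mask.spacing, {"phase": phase, **mask.meta})


def brute_force_thickness(mask: BinaryVolume, phase: str = "air", guard: int = 200_000) -> ThicknessMap:
    """Literal evaluation of the inscribed-sphere definition (testing oracle).

    For every candidate centre the admissible radius is found by direct
    minimisation over background voxel centres, and every covered voxel
    records the largest diameter.  Quadratic in the phase size; guarded.
    """
    arr = _phase_array(mask, phase)
    padded = np.pad(arr, 1, constant_values=False)  # outside the volume is background
    pts = np.argwhere(padded).astype(float)
    n = len(pts)
    if n > guard:
        raise ValueError(f"phase has {n} voxels, above the brute-force guard of {guard}")
    bg = np.argwhere(~padded).astype(float)
    tau_vox = np.zeros(arr.shape)
    # admissible radius per centre: distance to nearest background centre − 1/2
    radii = np.empty(n)
    chunk = max(1, int(2e7 // max(1, len(bg))))
    for i in range(0, n, chunk):
        d2 = ((pts[i : i + chunk, None, :] - bg[None, :, :]) ** 2).sum(axis=2)
        radii[i : i + chunk] = np.sqrt(d2.min(axis=1)) - 0.5
    best = np.zeros(n)
    chunk = max(1, int(2e7 // n))
    for i in range(0, n, chunk):
        d2 = ((pts[i : i + chunk, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        covered = d2 <= (radii[None, :] ** 2) + 1e-9
        diam = np.where(covered, 2.0 * radii[None, :], 0.0)
        best[i : i + chunk] = diam.max(axis=1)
    z, y, x = (np.argwhere(padded) - 1).T
    tau_vox[z, y, x] = best
    return ThicknessMap(tau_vox * mask.spacing, mask.spacing, {"phase": phase, **mask.meta})


def thickness_density(
    tmap: ThicknessMap,
    floor: float = DEFAULT_FLOOR_UM,
    cap: float = DEFAULT_CAP_UM,
    bandwidth: float | None = None,
    exclude_border: bool = False,
) -> DensityEstimate:
    """KDE of per-voxel τ values truncated to [floor, cap] µm (512-point grid)."""
    samples = tmap.samples_excluding_border() if exclude_border else tmap.samples
    samples = samples[(samples >= floor) & (samples <= cap)]
    if samples.size == 0:
        raise ValueError(f"no τ values inside [{floor}, {cap}] µm")
    grid = np.linspace(floor, cap, 512)
    est = kde_1d(samples, grid, bandwidth)
    tmap.floor, tmap.cap = floor, cap
    return est


def range_fractions(
    tmap: ThicknessMap,
    ranges: tuple[tuple[float, float], ...] = DEFAULT_RANGES,
    exclude_border: bool = False,
) -> np.ndarray:
    """Percentage of in-support air voxels whose τ falls in each [lo, hi) range.

    The support is the union of the (non-overlapping, half-open) ranges, so
    fractions over an exhaustive partition sum to 100%.
    """
    ranges = tuple((float(lo), float(hi)) for lo, hi in ranges)
    for (lo1, hi1) in ranges:
        for (lo2, hi2) in ranges:
            if (lo1, hi1) != (lo2, hi2) and lo1 < hi2 and lo2 < hi1:
                raise ValueError("ranges overlap")
    samples = tmap.samples_excluding_border() if exclude_border else tmap.samples
    support = np.zeros(samples.shape, dtype=bool)
    for lo, hi in ranges:
        support |= (samples >= lo) & (samples < hi)
    n = support.sum()
    if n == 0:
        raise ValueError("no τ values inside the requested ranges")
    return np.array([100.0 * ((samples >= lo) & (samples < hi)).sum() / n for lo, hi in ranges])


def ensemble_stats(values: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample standard deviation across segmentation variants.

    Accepts per-variant arrays of equal shape (densities on a common grid,
    or range-fraction vectors).  A nonzero std needs >= 2 variants.
    """
    if not values:
        raise ValueError("empty ensemble")
    arrs = [np.asarray(v, dtype=float) for v in values]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("ensemble members have inconsistent shapes/grids")
    stack = np.stack(arrs)
    std = stack.std(axis=0, ddof=1) if len(arrs) > 1 else np.zeros(shape)
    return stack.mean(axis=0), std


def export_thickness_overlay(
    tmap: ThicknessMap, vol: GrayVolume, n_bins: int = 255
) -> tuple[GrayVolume, np.ndarray]:
    """Quantise τ to a colour-index volume plus a lookup legend.

    Index 0 is reserved for τ = 0 (transparent); indices 1..n_bins map
    linearly onto [min positive τ, max τ].  The legend is an (n_bins, 3)
    array of (index, bin lower edge µm, bin upper edge µm).
    """
    if tmap.tau.shape != vol.shape:
        raise ValueError("thickness map and volume shapes differ")
    tau = tmap.tau
    pos = tau[tau > 0]
    if pos.size == 0:
        raise ValueError("empty thickness map")
    lo, hi = float(pos.min()), float(pos.max())
    width = max(hi - lo, 1e-12)
    idx = np.zeros(tau.shape, dtype=np.uint8)
    scaled = 1 + np.floor((tau - lo) / width * n_bins)
    idx[tau > 0] = np.clip(scaled[tau > 0], 1, n_bins).astype(np.uint8)
    edges = lo + width * np.arange(n_bins + 1) / n_bins
    legend = np.column_stack([np.arange(1, n_bins + 1), edges[:-1], edges[1:]])
    overlay = GrayVolume(idx, vol.spacing, vol.origin, {"legend_units": "µm", "history": list(vol.meta["history"])})
    overlay.record("export_thickness_overlay", n_bins=n_bins, lo=lo, hi=hi)
    return overlay, legend
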