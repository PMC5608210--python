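"""Septa-preserving semi-automatic segmentation of low-dose lung tomograms.

The pipeline addresses two failure modes of plain global thresholding on
region-of-interest tomography reconstructions: a superimposed per-slice
background illumination gradient, and interalveolar septa whose signal is
only marginally above background.  The steps, applied in order:

1. per-slice background-plane estimation (grayscale erosion with a disk,
   histogram-extreme masking, least-squares plane fit) and subtraction;
2. a single Otsu threshold computed on the corrected volume and stored;
3. a "ridged image": 1D line profiles in four in-plane directions
   (0°, 45°, 90°, 135°) are scanned for local maxima whose run width and
   prominence above the flanking background fall inside user bounds; the
   accepted pixels are set to the brightest gray value so thin septa survive
   the subsequent threshold;
4. thresholding with the stored Otsu value;
5. removal of free-standing (fully isolated) tissue voxels — a single
   isolated voxel is always an artifact, since real septa connect to tissue;
6. 3D connected-component filtering of small tissue specks.

The ensemble runner produces several segmentations per volume by sweeping
the ridge parameters; downstream statistics consume the list and report
mean ± std bands as segmentation uncertainty.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.morphology import disk

from .volio import BinaryVolume, GrayVolume


@dataclasses.dataclass
class PlaneModel:
    """background(x, y) = a·x + b·y + c (x = column, y = row index; gray units)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.a, self.b, self.c])):
            raise ValueError("plane coefficients must be finite")

    def evaluate(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        return self.a * xx + self.b * yy + self.c


@dataclasses.dataclass
class RidgeParams:
    """Acceptance window for septum-like line-profile maxima."""

    min_width: int = 1
    max_width: int = 11
    min_margin: float = 12.0
    max_margin: float = np.inf
    directions: tuple[int, ...] = (0, 45, 90, 135)

    def __post_init__(self) -> None:
        if not 1 <= self.min_width <= self.max_width:
            raise ValueError("need 1 <= min_width <= max_width")
        if not 0 <= self.min_margin <= self.max_margin:
            raise ValueError("need 0 <= min_margin <= max_margin")
        bad = set(self.directions) - {0, 45, 90, 135}
        if bad:
            raise ValueError(f"directions must be from {{0, 45, 90, 135}}, got {bad}")


@dataclasses.dataclass
class SegmentationParams:
    erosion_radius: int = 20
    ridge: RidgeParams = dataclasses.field(default_factory=RidgeParams)
    min_component: int = 27
    variant_id: str = "default"

    def __post_init__(self) -> None:
        if self.erosion_radius < 1:
            raise ValueError("erosion_radius must be >= 1")
        if self.min_component < 1:
            raise ValueError("min_component must be >= 1")


def estimate_background_plane(slice2d: np.ndarray, erosion_radius: int = 20) -> PlaneModel:
    """Fit the background-illumination plane of one tomographic slice.

    Grayscale erosion with a disk of the given radius suppresses thin bright
    structures (septa) so the background gradient comes into prominence;
    histogram extremes (outside the [5th, 95th] percentile of the eroded
    slice) are masked out and a plane is least-squares fitted to the rest.
    """
    img = np.asarray(slice2d, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D slice")
    if min(img.shape) <= 2 * erosion_radius:
        raise ValueError("slice smaller than the structuring element")
    eroded = ndimage.grey_erosion(img, footprint=disk(erosion_radius))
    # only the interior sees the full structuring element; border pixels
    # are minima over clipped disks and would bias the slope low
    r = erosion_radius
    valid = np.zeros(img.shape, dtype=bool)
    valid[r:-r, r:-r] = True
    p5, p95 = np.percentile(eroded[valid], [5, 95])
    keep = valid & (eroded >= p5) & (eroded <= p95)
    if not keep.any():
        raise ValueError("histogram-extreme masking removed every pixel")
    yy, xx = np.nonzero(keep)
    design = np.column_stack([xx, yy, np.ones_like(xx)])
    coef, *_ = np.linalg.lstsq(design, eroded[keep], rcond=None)
    return PlaneModel(*map(float, coef))


def correct_background(vol: GrayVolume, erosion_radius: int = 20) -> GrayVolume:
    """Per-slice background-plane subtraction.

    The gradient terms a·x + b·y are removed while the constant c is kept,
    so the gray scale stays comparable across slices.
    """
    out = np.empty(vol.shape, dtype=np.float64)
    planes = []
    for k in range(vol.shape[0]):
        plane = estimate_background_plane(vol.data[k], erosion_radius)
        out[k] = vol.data[k] - (plane.evaluate(vol.shape[1:]) - plane.c)
        planes.append((plane.a, plane.b, plane.c))
    result = vol.replace(out, "correct_background", erosion_radius=erosion_radius)
    result.meta["background_planes"] = planes
    return result


def otsu_threshold(vol: GrayVolume | np.ndarray) -> float:
    """Otsu threshold over a 256-bin histogram of the whole volume.

    Maximizes the between-class variance; ties break toward the lower bin.
    Returns the gray value (bin centre) separating air (<) from tissue (>=).
    """
    data = vol.data if isinstance(vol, GrayVolume) else np.asarray(vol)
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise ValueError("constant volume has no Otsu threshold")
    counts, edges = np.histogram(data, bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = counts.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    # ties (e.g. plateaus across empty bins) break toward the lower bin;
    # the tolerance makes the plateau detection robust to rounding
    top = sigma_b.max()
    k = int(np.flatnonzero(sigma_b >= top - 1e-9 * max(1.0, abs(top)))[0])
    # threshold between class k and k+1: first bin centre of the upper class
    return float(centers[min(k + 1, 255)])


def _run_bounds(profile: np.ndarray, peak: int, threshold: float) -> tuple[int, int]:
    left = peak
    while left > 0 and profile[left - 1] > threshold:
        left -= 1
    right = peak
    while right < profile.size - 1 and profile[right + 1] > threshold:
        right += 1
    return left, right


def _scan_profile(profile: np.ndarray, params: RidgeParams) -> np.ndarray:
    """Mark septum-accepted samples of one 1D line profile.

    A local maximum is accepted when its prominence over the flanking minima
    lies in [min_margin, max_margin] and the contiguous run of samples
    exceeding (flank base + min_margin) has width in [min_width, max_width].
    Of an accepted peak, the core samples — those above the flank base plus
    half the prominence (at least min_margin) — are marked, so the marked
    line stays as thin as the septum itself even when the acceptance run is
    broadened by blur or an oblique crossing.
    """
    mark = np.zeros(profile.size, dtype=bool)
    if profile.size < 3:
        return mark
    upper = None if np.isinf(params.max_margin) else params.max_margin
    peaks, props = find_peaks(profile, prominence=(params.min_margin, upper))
    for i, pk in enumerate(peaks):
        base = profile[pk] - props["prominences"][i]  # higher of the two flank minima
        left, right = _run_bounds(profile, pk, base + params.min_margin)
        if not params.min_width <= right - left + 1 <= params.max_width:
            continue
        core = base + max(params.min_margin, props["prominences"][i] / 2.0)
        left, right = _run_bounds(profile, pk, core)
        mark[left : right + 1] = True
    return mark


def _ridge_slice(img: np.ndarray, params: RidgeParams) -> np.ndarray:
    """Boolean map of accepted septum pixels for one slice, all directions."""
    mark = np.zeros(img.shape, dtype=bool)
    ny, nx = img.shape
    if 0 in params.directions:  # along rows (x)
        for y in range(ny):
            mark[y, :] |= _scan_profile(img[y, :], params)
    if 90 in params.directions:  # along columns (y)
        for x in range(nx):
            mark[:, x] |= _scan_profile(img[:, x], params)
    if 45 in params.directions:  # array diagonals, step sqrt(2) px
        for off in range(-ny + 1, nx):
            d = np.diagonal(img, offset=off)
            m = _scan_profile(np.ascontiguousarray(d), params)
            if m.any():
                idx = np.arange(d.size)
                yy = idx if off >= 0 else idx - off
                xx = idx + off if off >= 0 else idx
                mark[yy[m], xx[m]] = True
    if 135 in params.directions:  # anti-diagonals via left-right flip
        flipped = img[:, ::-1]
        for off in range(-ny + 1, nx):
            d = np.diagonal(flipped, offset=off)
            m = _scan_profile(np.ascontiguousarray(d), params)
            if m.any():
                idx = np.arange(d.size)
                yy = idx if off >= 0 else idx - off
                xx = idx + off if off >= 0 else idx
                mark[yy[m], nx - 1 - xx[m]] = True
    return mark


def ridge_enhance(vol: GrayVolume, params: RidgeParams) -> GrayVolume:
    """Create the "ridged image": accepted septum pixels set to the brightest value.

    Profiles run per slice in four in-plane directions; everything else is
    left unchanged, so ridging can only add tissue after thresholding.
    """
    brightest = float(vol.data.max())
    out = np.array(vol.data, dtype=np.float64, copy=True)
    for k in range(vol.shape[0]):
        mark = _ridge_slice(out[k], params)
        out[k][mark] = brightest
    return vol.replace(out, "ridge_enhance", **{f: getattr(params, f) for f in ("min_width", "max_width", "min_margin", "max_margin", "directions")})


def threshold_with(vol: GrayVolume, threshold: float) -> BinaryVolume:
    """Binary threshold: tissue = voxels with gray value >= threshold."""
    mask = BinaryVolume(vol.data >= threshold, vol.spacing, vol.origin, {**vol.meta, "history": list(vol.meta["history"])})
    mask.record("threshold_with", threshold=threshold)
    return mask


def remove_isolated(mask: BinaryVolume) -> BinaryVolume:
    """Remove free-standing tissue voxels (zero tissue 26-neighbours)."""
    kernel = np.ones((3, 3, 3), dtype=np.uint8)
    kernel[1, 1, 1] = 0
    neighbors = ndimage.convolve(mask.data.astype(np.uint8), kernel, mode="constant", cval=0)
    return mask.replace(mask.data & (neighbors > 0), "remove_isolated")


def component_filter(mask: BinaryVolume, min_component: int = 27) -> BinaryVolume:
    """Drop 26-connected tissue components smaller than ``min_component`` voxels."""
    if min_component < 1:
        raise ValueError("min_component must be >= 1")
    if min_component == 1:
        return mask.replace(mask.data.copy(), "component_filter", min_component=1)
    labels, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
    if n == 0:
        return mask.replace(mask.data.copy(), "component_filter", min_component=min_component)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_component
    keep[0] = False
    return mask.replace(keep[labels], "component_filter", min_component=min_component)


def segment_volume(vol: GrayVolume, params: SegmentationParams | None = None) -> BinaryVolume:
    """Full segmentation pipeline; parameters are recorded in the mask's meta."""
    params = params or SegmentationParams()
    corrected = correct_background(vol, params.erosion_radius)
    threshold = otsu_threshold(corrected)
    ridged = ridge_enhance(corrected, params.ridge)
    mask = threshold_with(ridged, threshold)
    mask = remove_isolated(mask)
    mask = component_filter(mask, params.min_component)
    mask.meta["segmentation"] = {
        "variant_id": params.variant_id,
        "erosion_radius": params.erosion_radius,
        "otsu_threshold": threshold,
        "ridge": dataclasses.asdict(params.ridge),
        "min_component": params.min_component,
    }
    return mask


def segmentation_ensemble(vol: GrayVolume, variants: list[SegmentationParams]) -> list[BinaryVolume]:
    """One mask per parameter variant, tagged with its ``variant_id``.

    Variants sharing an erosion radius reuse the background-corrected volume
    and its Otsu value (pure caching; identical results to segment_volume).
    """
    if not variants:
        raise ValueError("at least one variant is required")
    cache: dict[int, tuple[GrayVolume, float]] = {}
    masks = []
    for p in variants:
        if p.erosion_radius not in cache:
            corrected = correct_background(vol, p.erosion_radius)
            cache[p.erosion_radius] = (corrected, otsu_threshold(corrected))
        corrected, threshold = cache[p.erosion_radius]
        ridged = ridge_enhance(corrected, p.ridge)
        mask = threshold_with(ridged, threshold)
        mask = remove_isolated(mask)
        mask = component_filter(mask, p.min_component)
        mask.meta["segmentation"] = {
            "variant_id": p.variant_id,
            "erosion_radius": p.erosion_radius,
            "otsu_threshold": threshold,
            "ridge": dataclasses.asdict(p.ridge),
            "min_component": p.min_component,
        }
        masks.append(mask)
    return masks
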