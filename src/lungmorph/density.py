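"""Kernel density estimation shared by the thickness and curvature analyses.

1D densities use a Gaussian kernel with a plug-in bandwidth (Botev's
improved-Sheather-Jones diffusion selector, with a Silverman fallback for
degenerate samples); evaluation is linear binning on the fixed output grid
followed by discrete Gaussian convolution, then renormalisation on the
(possibly truncated) support.  2D interface-shape densities use a diagonal
normal-reference bandwidth matrix on a binned grid.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import fft as _fft
from scipy import ndimage, optimize


@dataclasses.dataclass
class DensityEstimate:
    """1D probability density evaluated on a fixed grid (integral = 1)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_samples: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must have the same shape")

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclasses.dataclass
class ISDensity:
    """2D probability density over (κ1, κ2); mass restricted to κ1 ≤ κ2."""

    grid_k1: np.ndarray
    grid_k2: np.ndarray
    density: np.ndarray
    bandwidth: tuple[float, float]
    n_vertices: int

    @property
    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.grid_k2, axis=1), self.grid_k1))

    @property
    def peak(self) -> tuple[float, float]:
        """(κ1, κ2) location of the density maximum."""
        i, j = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return float(self.grid_k1[i]), float(self.grid_k2[j])


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a Gaussian kernel."""
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    if n < 2:
        return 1.0
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    scale = min(samples.std(ddof=1), iqr / 1.349) if iqr > 0 else samples.std(ddof=1)
    if scale <= 0:
        return max(1e-3, abs(float(samples[0])) * 1e-3 + 1e-6)
    return 0.9 * scale * n ** (-0.2)


def _isj_fixed_point(t: float, n: int, i2: np.ndarray, a2: np.ndarray) -> float:
    # Botev, Grotowski & Kroese (2010) diffusion-KDE fixed-point equation.
    ell = 7
    f = 2.0 * np.pi ** (2 * ell) * np.sum(i2**ell * a2 * np.exp(-i2 * np.pi**2 * t))
    for s in range(ell - 1, 1, -1):
        k0 = np.prod(np.arange(1, 2 * s, 2)) / np.sqrt(2 * np.pi)
        const = (1 + (0.5) ** (s + 0.5)) / 3.0
        time = (2 * const * k0 / (n * f)) ** (2.0 / (3 + 2 * s))
        f = 2.0 * np.pi ** (2 * s) * np.sum(i2**s * a2 * np.exp(-i2 * np.pi**2 * time))
    return t - (2 * n * np.sqrt(np.pi) * f) ** (-0.4)


def isj_bandwidth(samples: np.ndarray, n_bins: int = 1024) -> float:
    """Plug-in bandwidth via the improved-Sheather-Jones fixed point.

    Falls back to Silverman's rule when the sample is too small or the fixed
    point has no root in the search bracket.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    n = samples.size
    if n < 30 or samples.std() == 0:
        return silverman_bandwidth(samples)
    lo, hi = samples.min(), samples.max()
    span = hi - lo
    lo -= span / 10
    hi += span / 10
    span = hi - lo
    hist, _ = np.histogram(samples, bins=n_bins, range=(lo, hi))
    a = _fft.dct(hist / n, type=2)
    i2 = np.arange(1, n_bins, dtype=float) ** 2
    a2 = (a[1:] / 2.0) ** 2
    n_unique = min(n, np.unique(samples).size)
    try:
        t_star = optimize.brentq(_isj_fixed_point, 1e-12, 0.1, args=(n_unique, i2, a2))
        bw = float(np.sqrt(t_star) * span)
    except ValueError:
        bw = silverman_bandwidth(samples)
    if not np.isfinite(bw) or bw <= 0:
        bw = silverman_bandwidth(samples)
    return bw


def _linear_binning(samples: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Distribute unit mass per sample onto the two bracketing grid points."""
    step = grid[1] - grid[0]
    pos = np.clip((samples - grid[0]) / step, 0.0, grid.size - 1.0)
    left = np.floor(pos).astype(np.intp)
    right = np.minimum(left + 1, grid.size - 1)
    w_right = pos - left
    counts = np.zeros(grid.size)
    np.add.at(counts, left, 1.0 - w_right)
    np.add.at(counts, right, w_right)
    return counts


def kde_1d(samples: np.ndarray, grid: np.ndarray, bandwidth: float | None = None) -> DensityEstimate:
    """Gaussian KDE of ``samples`` on a uniform ``grid``, renormalised there.

    The density integrates to 1 over the grid (trapezoidal rule), i.e. it is
    the KDE truncated to and renormalised on the grid's support.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float)
    samples = samples[(samples >= grid[0]) & (samples <= grid[-1])]
    if samples.size == 0:
        raise ValueError("no samples on the evaluation grid")
    step = grid[1] - grid[0]
    if bandwidth is None:
        bandwidth = isj_bandwidth(samples)
    bandwidth = max(float(bandwidth), step / 2)  # never narrower than the grid can resolve
    counts = _linear_binning(samples, grid)
    half = int(np.ceil(6 * bandwidth / step))
    offsets = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (offsets / bandwidth) ** 2)
    density = np.convolve(counts, kernel, mode="full")[half:-half]
    area = np.trapezoid(density, grid)
    if area <= 0:
        raise ValueError("degenerate density (no mass on grid)")
    return DensityEstimate(grid, density / area, bandwidth, samples.size)


def kde_2d(
    x: np.ndarray,
    y: np.ndarray,
    grid_x: np.ndarray | None = None,
    grid_y: np.ndarray | None = None,
    n_grid: int = 256,
    bandwidth: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[float, float]]:
    """Binned 2D Gaussian KDE; returns (grid_x, grid_y, density, bandwidth)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size == 0:
        raise ValueError("x and y must be non-empty and of equal length")
    if grid_x is not None or grid_y is not None:
        gx0 = -np.inf if grid_x is None else grid_x[0]
        gx1 = np.inf if grid_x is None else grid_x[-1]
        gy0 = -np.inf if grid_y is None else grid_y[0]
        gy1 = np.inf if grid_y is None else grid_y[-1]
        keep = (x >= gx0) & (x <= gx1) & (y >= gy0) & (y <= gy1)
        x, y = x[keep], y[keep]
        if x.size == 0:
            raise ValueError("no samples on the evaluation grid")
    if bandwidth is None:
        # normal-reference diagonal bandwidth matrix for a 2D Gaussian kernel
        n = x.size
        factor = n ** (-1.0 / 6.0)
        bandwidth = (max(x.std(ddof=1), 1e-12) * factor, max(y.std(ddof=1), 1e-12) * factor)
    bx, by = bandwidth
    if grid_x is None:
        grid_x = np.linspace(x.min() - 3 * bx, x.max() + 3 * bx, n_grid)
    if grid_y is None:
        grid_y = np.linspace(y.min() - 3 * by, y.max() + 3 * by, n_grid)
    dx = grid_x[1] - grid_x[0]
    dy = grid_y[1] - grid_y[0]
    edges_x = np.concatenate([grid_x - dx / 2, [grid_x[-1] + dx / 2]])
    edges_y = np.concatenate([grid_y - dy / 2, [grid_y[-1] + dy / 2]])
    counts, _, _ = np.histogram2d(x, y, bins=(edges_x, edges_y))
    density = ndimage.gaussian_filter(counts, sigma=(bx / dx, by / dy), mode="constant")
    area = np.trapezoid(np.trapezoid(density, grid_y, axis=1), grid_x)
    if area <= 0:
        raise ValueError("degenerate 2D density")
    return grid_x, grid_y, density / area, (float(bx), float(by))


def _common_grid(grids: list[np.ndarray]) -> np.ndarray:
    g0 = np.asarray(grids[0])
    for g in grids[1:]:
        if np.asarray(g).shape != g0.shape or not np.allclose(g, g0):
            raise ValueError("ensemble members were evaluated on inconsistent grids")
    return g0


def density_ensemble_stats(densities: list[DensityEstimate]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise (grid, mean, sample std) across segmentation-variant densities."""
    if not densities:
        raise ValueError("empty ensemble")
    grid = _common_grid([d.grid for d in densities])
    stack = np.stack([d.density for d in densities])
    std = stack.std(axis=0, ddof=1) if len(densities) > 1 else np.zeros_like(stack[0])
    return grid, stack.mean(axis=0), std
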