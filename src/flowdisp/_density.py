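"""Binned kernel density estimation shared by the gating steps.

Densities are evaluated on fixed grids via histogram binning followed by
Gaussian smoothing, which is the usual fast approximation to a Gaussian-kernel
KDE and keeps the 2-D gates tractable on pooled batches of ~1e5 events.
Bandwidths default to Silverman's rule.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a 1-D sample."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points for a bandwidth")
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        raise ValueError("degenerate (constant) sample")
    return 0.9 * scale * n ** (-0.2)


def kde_1d(
    x: np.ndarray,
    grid_size: int = 512,
    bandwidth: float | None = None,
    pad: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned Gaussian KDE on a regular grid.

    Returns ``(grid, density)`` with the density normalised to integrate to 1
    over the grid. The grid spans the data range padded by ``pad`` bandwidths.
    """
    x = np.asarray(x, dtype=float)
    if bandwidth is None:
        bandwidth = silverman_bandwidth(x)
    lo = x.min() - pad * bandwidth
    hi = x.max() + pad * bandwidth
    grid = np.linspace(lo, hi, grid_size)
    step = grid[1] - grid[0]
    counts, _ = np.histogram(x, bins=grid_size, range=(lo, hi))
    dens = gaussian_filter1d(counts.astype(float), sigma=bandwidth / step, mode="constant")
    area = dens.sum() * step
    if area <= 0:
        raise ValueError("empty density")
    return grid + step / 2.0, dens / area


def kde_2d(
    x: np.ndarray,
    y: np.ndarray,
    grid_size: int = 256,
    bandwidths: tuple[float, float] | None = None,
    pad: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned 2-D Gaussian KDE on a ``grid_size`` x ``grid_size`` grid.

    Returns ``(x_edges, y_edges, density)`` where ``density[i, j]`` covers the
    cell ``x_edges[i]:x_edges[i+1]`` x ``y_edges[j]:y_edges[j+1]``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if bandwidths is None:
        bandwidths = (silverman_bandwidth(x), silverman_bandwidth(y))
    bx, by = bandwidths
    x_lo, x_hi = x.min() - pad * bx, x.max() + pad * bx
    y_lo, y_hi = y.min() - pad * by, y.max() + pad * by
    counts, x_edges, y_edges = np.histogram2d(
        x, y, bins=grid_size, range=[[x_lo, x_hi], [y_lo, y_hi]]
    )
    sx = bx / (x_edges[1] - x_edges[0])
    sy = by / (y_edges[1] - y_edges[0])
    dens = gaussian_filter(counts, sigma=(sx, sy), mode="constant")
    return x_edges, y_edges, dens


def density_peaks(grid: np.ndarray, dens: np.ndarray, min_rel_height: float = 0.05) -> np.ndarray:
    """Indices of local density maxima, tallest-first filtered by relative height.

    A peak must reach ``min_rel_height`` of the global maximum; returned in
    left-to-right grid order.
    """
    d = np.asarray(dens, dtype=float)
    interior = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
    idx = np.flatnonzero(interior) + 1
    idx = idx[d[idx] >= min_rel_height * d.max()]
    return idx


def first_valley(grid: np.ndarray, dens: np.ndarray, left: int, right: int) -> int:
    """Index of the density minimum strictly between two peak indices."""
    if right <= left + 1:
        raise ValueError("peaks are adjacent; no interior valley")
    segment = dens[left + 1 : right]
    return left + 1 + int(np.argmin(segment))
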