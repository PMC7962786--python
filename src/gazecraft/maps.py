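"""Gaussian fixation-density maps over the image pixel grid.

Each fixation contributes a truncated isotropic Gaussian (default sigma
1.5 degrees, truncated at 4 sigma, no edge renormalization) evaluated at
its exact sub-pixel center. Maps are computed over the image rectangle,
optionally on a decimated grid for speed (``grid_step``); decimation keeps
relative quantities (z-scores, dispersion ratios) unchanged to within grid
quantization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import ImageFrame, ScreenGeometry, px_per_degree

__all__ = ["KernelSpec", "FixationMap", "build_fixation_map", "difference_map"]


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel in visual degrees."""

    sigma_deg: float = 1.5
    truncation_radius_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma_deg <= 0:
            raise ValueError("sigma_deg must be strictly positive")
        if self.truncation_radius_sigmas <= 0:
            raise ValueError("truncation_radius_sigmas must be strictly positive")


@dataclass
class FixationMap:
    """A 2D density grid over the image rectangle.

    ``grid[row, col]`` covers the image pixel at
    ``(frame.origin_x_px + col*grid_step, frame.origin_y_px + row*grid_step)``.
    """

    grid: np.ndarray
    px_per_deg: float
    normalization: str = "raw"
    grid_step: int = 1

    def z_normalized(self) -> "FixationMap":
        """Map rescaled to mean 0 and variance 1 over grid pixels."""
        g = self.grid
        sd = g.std()
        if sd == 0:
            raise ValueError("cannot z-normalize a constant map")
        return FixationMap((g - g.mean()) / sd, self.px_per_deg, "zscore", self.grid_step)

    def max_normalized(self) -> "FixationMap":
        m = self.grid.max()
        if m <= 0:
            raise ValueError("cannot max-normalize an empty map")
        return FixationMap(self.grid / m, self.px_per_deg, "max1", self.grid_step)

    def mass_normalized(self) -> "FixationMap":
        s = self.grid.sum()
        if s <= 0:
            raise ValueError("cannot mass-normalize an empty map")
        return FixationMap(self.grid / s, self.px_per_deg, "mass1", self.grid_step)

    def value_at(self, x_px: float, y_px: float, frame: ImageFrame) -> float:
        """Nearest-grid-pixel lookup for a screen-coordinate point."""
        col = int(round((x_px - frame.origin_x_px) / self.grid_step))
        row = int(round((y_px - frame.origin_y_px) / self.grid_step))
        row = min(max(row, 0), self.grid.shape[0] - 1)
        col = min(max(col, 0), self.grid.shape[1] - 1)
        return float(self.grid[row, col])

    def write(self, path: str | Path) -> None:
        """Portable plain-text grid with a JSON sidecar of metadata."""
        path = Path(path)
        np.savetxt(path, self.grid, fmt="%.8g")
        sidecar = {
            "shape": list(self.grid.shape),
            "px_per_deg": self.px_per_deg,
            "normalization": self.normalization,
            "grid_step": self.grid_step,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "FixationMap":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        grid = np.loadtxt(path).reshape(meta["shape"])
        return cls(grid, meta["px_per_deg"], meta["normalization"], meta["grid_step"])


def build_fixation_map(
    points_px: np.ndarray,
    weights: np.ndarray | None,
    kernel: KernelSpec,
    frame: ImageFrame,
    geom: ScreenGeometry,
    grid_step: int = 1,
) -> FixationMap:
    """Sum of weighted Gaussians centered at the given screen-coordinate points.

    Parameters
    ----------
    points_px
        (n, 2) array of fixation centers in screen coordinates.
    weights
        Per-point non-negative weights; None means unweighted (all ones).
    grid_step
        Compute the map every ``grid_step`` image pixels (1 = full resolution).

    The kernel has unit peak amplitude; absolute scale is irrelevant for all
    downstream normalizations. Mass falling outside the image rectangle is
    lost (no edge renormalization).
    """
    points = np.atleast_2d(np.asarray(points_px, dtype=float))
    if points.size == 0:
        raise ValueError("cannot build a fixation map from zero fixations")
    if points.shape[1] != 2:
        raise ValueError("points_px must have shape (n, 2)")
    if weights is None:
        weights = np.ones(len(points))
    else:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(points):
            raise ValueError("weights must match points in length")
        if (weights < 0).any():
            raise ValueError("weights must be non-negative")

    ppd = px_per_degree(geom, check_isotropy=False)
    sigma_px = kernel.sigma_deg * ppd
    radius_px = kernel.truncation_radius_sigmas * sigma_px

    n_rows = int(np.ceil(frame.height_px / grid_step))
    n_cols = int(np.ceil(frame.width_px / grid_step))
    grid = np.zeros((n_rows, n_cols))

    # grid coordinates in image-pixel units
    for (x, y), w in zip(points, weights):
        if w == 0:
            continue
        cx = (x - frame.origin_x_px) / grid_step  # center in grid units
        cy = (y - frame.origin_y_px) / grid_step
        r = radius_px / grid_step
        c0 = max(int(np.floor(cx - r)), 0)
        c1 = min(int(np.ceil(cx + r)) + 1, n_cols)
        r0 = max(int(np.floor(cy - r)), 0)
        r1 = min(int(np.ceil(cy + r)) + 1, n_rows)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        dx2 = ((cols - cx) * grid_step) ** 2
        dy2 = ((rows - cy) * grid_step) ** 2
        d2 = dy2[:, None] + dx2[None, :]
        patch = np.exp(-d2 / (2.0 * sigma_px**2))
        patch[d2 > radius_px**2] = 0.0
        grid[r0:r1, c0:c1] += w * patch

    return FixationMap(grid, px_per_deg=ppd, normalization="raw", grid_step=grid_step)


def difference_map(map_a: FixationMap, map_b: FixationMap) -> np.ndarray:
    """Elementwise ``a - b`` of two mass-normalized maps (sums to ~0)."""
    if map_a.grid.shape != map_b.grid.shape:
        raise ValueError("difference_map requires equal grid shapes")
    if map_a.normalization != map_b.normalization:
        raise ValueError("difference_map requires equal normalization states")
    return map_a.grid - map_b.grid
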