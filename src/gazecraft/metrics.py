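"""Inter-observer gaze congruence (leave-one-out NSS), spatial dispersion and
duration-weighted group heatmaps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import FixationEvent
from .geometry import ImageFrame, ScreenGeometry
from .maps import FixationMap, KernelSpec, build_fixation_map

__all__ = [
    "NssRecord",
    "DispersionRecord",
    "nss_loo",
    "dispersion",
    "group_heatmap",
    "fixation_points",
]


@dataclass
class NssRecord:
    subject_id: str
    image_id: str
    task: str
    group: str
    nss: float  # NaN when undefined (zero kept fixations)
    n_fixations_used: int

    @property
    def defined(self) -> bool:
        return self.n_fixations_used >= 1 and np.isfinite(self.nss)


@dataclass
class DispersionRecord:
    subject_id: str
    image_id: str
    task: str
    group: str
    dispersion: float
    n_fixations: int

    @property
    def defined(self) -> bool:
        return self.n_fixations >= 1 and np.isfinite(self.dispersion)


def fixation_points(fixations: list[FixationEvent]) -> np.ndarray:
    """(n, 2) array of fixation centroids in screen coordinates."""
    return np.array([[f.centroid_x_px, f.centroid_y_px] for f in fixations], dtype=float).reshape(
        -1, 2
    )


def nss_loo(
    observer_fixations: list[tuple[str, np.ndarray]],
    kernel: KernelSpec,
    frame: ImageFrame,
    geom: ScreenGeometry,
    aggregate: str = "mean",
    grid_step: int = 1,
    meta: dict[str, dict[str, str]] | None = None,
) -> list[NssRecord]:
    """Leave-one-out normalized scanpath saliency per observer.

    For each observer, an unweighted Gaussian fixation map is built from all
    *other* observers' fixations, z-normalized over image pixels (mean 0,
    variance 1), and read at the left-out observer's fixation pixels
    (nearest-pixel lookup). Values are aggregated by ``"mean"`` (standard
    NSS) or ``"sum"``.

    Parameters
    ----------
    observer_fixations
        ``(observer_id, points)`` pairs, one per observer, where ``points``
        is an (n, 2) array of fixation centers in screen coordinates. All
        entries share one image and task.
    meta
        Optional per-observer ``{"image_id":…, "task":…, "group":…}`` labels
        copied onto the returned records.

    Positive scores mean congruent gaze, ~0 uncorrelated, negative
    incoherent. Observers with zero fixations receive an undefined (NaN)
    record and contribute nothing to the reference maps.
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    contributing = [(oid, pts) for oid, pts in observer_fixations if len(pts) > 0]
    if len(contributing) < 2:
        raise ValueError("leave-one-out NSS needs >= 2 observers with fixations")

    # total map minus own map == map of all other observers (linearity)
    own_maps: dict[str, FixationMap] = {
        oid: build_fixation_map(pts, None, kernel, frame, geom, grid_step)
        for oid, pts in contributing
    }
    total = np.zeros_like(next(iter(own_maps.values())).grid)
    for m in own_maps.values():
        total += m.grid

    records: list[NssRecord] = []
    for oid, pts in observer_fixations:
        labels = (meta or {}).get(oid, {})
        image_id = labels.get("image_id", "")
        task = labels.get("task", "")
        group = labels.get("group", "")
        if len(pts) == 0:
            records.append(NssRecord(oid, image_id, task, group, float("nan"), 0))
            continue
        loo = FixationMap(
            total - own_maps[oid].grid,
            px_per_deg=own_maps[oid].px_per_deg,
            grid_step=grid_step,
        )
        z = loo.z_normalized()
        values = [z.value_at(x, y, frame) for x, y in pts]
        score = float(np.sum(values)) if aggregate == "sum" else float(np.mean(values))
        records.append(NssRecord(oid, image_id, task, group, score, len(values)))
    return records


def dispersion(
    points_px: np.ndarray,
    kernel: KernelSpec,
    frame: ImageFrame,
    geom: ScreenGeometry,
    grid_step: int = 1,
) -> float:
    """Spatial extent of a fixation set, in (0, 1].

    The unweighted Gaussian sum over the image grid is normalized to a
    maximum of 1; the score is its total divided by the number of grid
    pixels, so tighter fixation clusters give smaller values.
    """
    points = np.atleast_2d(np.asarray(points_px, dtype=float))
    if points.size == 0:
        raise ValueError("dispersion undefined for zero fixations")
    m = build_fixation_map(points, None, kernel, frame, geom, grid_step).max_normalized()
    return float(m.grid.sum() / m.grid.size)


def group_heatmap(
    fixation_sets: list[tuple[np.ndarray, np.ndarray]],
    kernel: KernelSpec,
    frame: ImageFrame,
    geom: ScreenGeometry,
    grid_step: int = 1,
) -> FixationMap:
    """Duration-weighted fixation density map for a group of trials.

    ``fixation_sets`` holds ``(points, durations_ms)`` per contributing
    trial. Gaussians are weighted by fixation duration and the accumulated
    map is divided by the total fixation duration, giving unit mass up to
    kernel truncation; doubling every duration leaves the map unchanged.
    """
    pts = [p for p, _ in fixation_sets if len(p) > 0]
    durs = [d for p, d in fixation_sets if len(p) > 0]
    if not pts:
        raise ValueError("group_heatmap needs at least one trial with fixations")
    points = np.vstack(pts)
    weights = np.concatenate([np.asarray(d, dtype=float) for d in durs])
    if (weights <= 0).any():
        raise ValueError("fixation durations must be positive")
    raw = build_fixation_map(points, weights, kernel, frame, geom, grid_step)
    grid = raw.grid / weights.sum()
    # rescale to unit mass over the grid: "mass1" convention used by
    # difference maps (kernel-mass constant divided out)
    s = grid.sum()
    return FixationMap(grid / s, raw.px_per_deg, "mass1", grid_step)
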