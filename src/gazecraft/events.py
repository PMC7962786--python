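"""Oculomotor event detection and exclusion rules.

Saccades are detected from smoothed sample velocities/accelerations with a
combined threshold (velocity 30 deg/s OR acceleration 8000 deg/s^2, the OR
matching the vendor algorithm family). Fixations are everything that is not
a saccade or a blink, so the three event classes partition each trial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import ImageFrame, ScreenGeometry, px_per_degree
from .io import Samples

__all__ = [
    "DetectionParams",
    "FilterParams",
    "SaccadeEvent",
    "FixationEvent",
    "BlinkInterval",
    "detect_blinks",
    "detect_saccades",
    "derive_fixations",
    "filter_fixations",
    "filter_saccade_artifacts",
    "sample_velocity",
]


@dataclass(frozen=True)
class DetectionParams:
    """Saccade-detection thresholds and conditioning parameters.

    ``velocity_thresh`` (deg/s) and ``acceleration_thresh`` (deg/s^2) are
    combined with OR. ``smoothing_halfwidth`` is the half-width of the
    moving-average position smoother in samples (1 -> 3-sample window).
    ``min_saccade_ms`` / ``min_fixation_ms`` are conventional floors that
    suppress jitter events; sub-floor still intervals between threshold
    crossings are merged into the surrounding saccade.
    """

    velocity_thresh: float = 30.0
    acceleration_thresh: float = 8000.0
    smoothing_halfwidth: int = 1
    min_saccade_ms: float = 4.0
    min_fixation_ms: float = 20.0
    blink_pad_ms: float = 25.0  # saccade runs within this margin of a blink are discarded

    def __post_init__(self) -> None:
        if self.velocity_thresh <= 0 or self.acceleration_thresh <= 0:
            raise ValueError("detection thresholds must be strictly positive")
        if self.smoothing_halfwidth < 0:
            raise ValueError("smoothing_halfwidth must be >= 0")


@dataclass(frozen=True)
class FilterParams:
    """Ratio-based saccade artifact exclusion thresholds.

    duration/amplitude > ``duration_amplitude_ratio_max`` or
    path_length/amplitude > ``distance_amplitude_ratio_max`` excludes a
    saccade. ``duration_units`` selects the unit of the duration ratio's
    numerator; the printed thresholds are unit-ambiguous, so both the
    thresholds and the unit are configuration.
    """

    duration_amplitude_ratio_max: float = 1.5
    distance_amplitude_ratio_max: float = 3.5
    duration_units: str = "ms"

    def __post_init__(self) -> None:
        if self.duration_amplitude_ratio_max <= 0 or self.distance_amplitude_ratio_max <= 0:
            raise ValueError("ratio thresholds must be strictly positive")
        if self.duration_units not in ("ms", "s"):
            raise ValueError("duration_units must be 'ms' or 's'")


@dataclass
class BlinkInterval:
    onset_ms: float
    offset_ms: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    start_xy_px: tuple[float, float]
    end_xy_px: tuple[float, float]
    amplitude_deg: float
    path_length_deg: float
    peak_velocity_deg_s: float
    ordinal: int

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class FixationEvent:
    onset_ms: float
    offset_ms: float
    centroid_x_px: float
    centroid_y_px: float
    ordinal: int
    blink_adjacent: bool = False
    on_image: bool = True

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as inclusive (start, stop) index pairs."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size - 1)
    return list(zip(starts, stops))


def _dt_ms(samples: Samples) -> float:
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    return float(np.median(np.diff(samples.t_ms)))


def detect_blinks(samples: Samples) -> list[BlinkInterval]:
    """Maximal runs of invalid samples as blink / track-loss intervals."""
    if len(samples) == 0:
        return []
    dt = _dt_ms(samples) if len(samples) > 1 else 1.0
    return [
        BlinkInterval(onset_ms=float(samples.t_ms[i0]), offset_ms=float(samples.t_ms[i1]) + dt)
        for i0, i1 in _runs(~samples.valid)
    ]


def _moving_average(a: np.ndarray, halfwidth: int) -> np.ndarray:
    if halfwidth == 0:
        return a
    w = 2 * halfwidth + 1
    padded = np.pad(a, halfwidth, mode="edge")
    kernel = np.ones(w) / w
    return np.convolve(padded, kernel, mode="valid")


def sample_velocity(
    samples: Samples, geom: ScreenGeometry, smoothing_halfwidth: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample gaze speed (deg/s) and acceleration magnitude (deg/s^2).

    Positions are moving-average smoothed, then differentiated with central
    differences; samples whose stencil touches invalid data get NaN.
    """
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples for velocity estimation")
    ppd = px_per_degree(geom, check_isotropy=False)
    x = _moving_average(samples.x_px, smoothing_halfwidth)
    y = _moving_average(samples.y_px, smoothing_halfwidth)
    t_s = samples.t_ms / 1000.0

    vx = np.gradient(x, t_s) / ppd
    vy = np.gradient(y, t_s) / ppd
    speed = np.hypot(vx, vy)
    ax = np.gradient(vx, t_s)
    ay = np.gradient(vy, t_s)
    accel = np.hypot(ax, ay)

    # poison everything an invalid sample can reach through smoothing + two
    # gradient stencils (reach = halfwidth + 2)
    reach = smoothing_halfwidth + 2
    bad = ~samples.valid
    if bad.any():
        kernel = np.ones(2 * reach + 1)
        infected = np.convolve(bad.astype(float), kernel, mode="same") > 0
        speed[infected] = np.nan
        accel[infected] = np.nan
    return speed, accel


def detect_saccades(
    samples: Samples,
    params: DetectionParams,
    geom: ScreenGeometry,
    blinks: list[BlinkInterval] | None = None,
) -> list[SaccadeEvent]:
    """Detect saccades as maximal above-threshold runs.

    A sample belongs to a saccade when speed > velocity_thresh OR
    acceleration > acceleration_thresh. Above-threshold runs separated by a
    sub-``min_fixation_ms`` still interval are merged (turnaround points of
    curved saccades have momentarily zero speed). Runs overlapping a blink
    are discarded; runs shorter than ``min_saccade_ms`` are dropped.
    """
    n = len(samples)
    if n < 2 * params.smoothing_halfwidth + 3:
        raise ValueError("trial shorter than the smoothing window")
    if blinks is None:
        blinks = detect_blinks(samples)
    dt = _dt_ms(samples)
    ppd = px_per_degree(geom, check_isotropy=False)

    speed, accel = sample_velocity(samples, geom, params.smoothing_halfwidth)
    with np.errstate(invalid="ignore"):
        mask = (speed > params.velocity_thresh) | (accel > params.acceleration_thresh)
    mask &= ~np.isnan(speed)

    runs = _runs(mask)

    # merge runs separated by gaps too short to be a fixation
    merged: list[tuple[int, int]] = []
    for i0, i1 in runs:
        if merged and (samples.t_ms[i0] - (samples.t_ms[merged[-1][1]] + dt)) < params.min_fixation_ms:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))

    events: list[SaccadeEvent] = []
    for i0, i1 in merged:
        onset = float(samples.t_ms[i0])
        offset = float(samples.t_ms[i1]) + dt
        if offset - onset < params.min_saccade_ms:
            continue
        pad = params.blink_pad_ms
        if any(onset < b.offset_ms + pad and b.onset_ms - pad < offset for b in blinks):
            continue
        seg_x = samples.x_px[i0 : i1 + 1]
        seg_y = samples.y_px[i0 : i1 + 1]
        amplitude = float(np.hypot(seg_x[-1] - seg_x[0], seg_y[-1] - seg_y[0])) / ppd
        path = float(np.sum(np.hypot(np.diff(seg_x), np.diff(seg_y)))) / ppd
        peak = float(np.nanmax(speed[i0 : i1 + 1]))
        events.append(
            SaccadeEvent(
                onset_ms=onset,
                offset_ms=offset,
                start_xy_px=(float(seg_x[0]), float(seg_y[0])),
                end_xy_px=(float(seg_x[-1]), float(seg_y[-1])),
                amplitude_deg=amplitude,
                path_length_deg=max(path, amplitude),
                peak_velocity_deg_s=peak,
                ordinal=0,
            )
        )
    for k, ev in enumerate(events, start=1):
        ev.ordinal = k
    return events


def derive_fixations(
    samples: Samples,
    saccades: list[SaccadeEvent],
    blinks: list[BlinkInterval],
) -> list[FixationEvent]:
    """Complement intervals of (saccades U blinks) within the trial.

    Centroid is the mean position of valid samples in the interval;
    ``blink_adjacent`` marks fixations that immediately precede or follow a
    blink (within one sample period).
    """
    if len(samples) == 0:
        return []
    dt = _dt_ms(samples) if len(samples) > 1 else 1.0
    t0 = float(samples.t_ms[0])
    t1 = float(samples.t_ms[-1]) + dt

    occupied = sorted(
        [(s.onset_ms, s.offset_ms) for s in saccades] + [(b.onset_ms, b.offset_ms) for b in blinks]
    )
    gaps: list[tuple[float, float]] = []
    cursor = t0
    for a, b in occupied:
        if a > cursor:
            gaps.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < t1:
        gaps.append((cursor, t1))

    fixations: list[FixationEvent] = []
    for k, (a, b) in enumerate(gaps, start=1):
        sel = (samples.t_ms >= a) & (samples.t_ms < b) & samples.valid
        if sel.any():
            cx = float(np.mean(samples.x_px[sel]))
            cy = float(np.mean(samples.y_px[sel]))
        else:  # positional info lost; keep interval for the partition, flag centroid NaN
            cx = cy = float("nan")
        adjacent = any(
            abs(a - blink.offset_ms) <= dt or abs(blink.onset_ms - b) <= dt for blink in blinks
        )
        fixations.append(
            FixationEvent(
                onset_ms=a,
                offset_ms=b,
                centroid_x_px=cx,
                centroid_y_px=cy,
                ordinal=k,
                blink_adjacent=adjacent,
            )
        )
    return fixations


# ---------------------------------------------------------------------------
# Exclusion rules
# ---------------------------------------------------------------------------


def filter_fixations(
    fixations: list[FixationEvent], image: ImageFrame
) -> tuple[list[FixationEvent], list[tuple[FixationEvent, str]]]:
    """Drop off-image and blink-adjacent fixations.

    Ordinals of kept fixations are preserved, not renumbered. Each removal
    carries a machine-readable reason (``"off_image"`` / ``"blink_adjacent"``).
    """
    kept: list[FixationEvent] = []
    removed: list[tuple[FixationEvent, str]] = []
    for f in fixations:
        if f.blink_adjacent:
            removed.append((f, "blink_adjacent"))
        elif np.isnan(f.centroid_x_px) or not image.contains(f.centroid_x_px, f.centroid_y_px):
            removed.append((replace(f, on_image=False), "off_image"))
        else:
            kept.append(f)
    return kept, removed


def filter_saccade_artifacts(
    saccades: list[SaccadeEvent], params: FilterParams | None = None
) -> tuple[list[SaccadeEvent], list[tuple[SaccadeEvent, str, float, float]]]:
    """Ratio-based artifact exclusion.

    Excludes saccades with duration/amplitude or path_length/amplitude above
    the configured maxima; zero-amplitude events are excluded as
    ``"degenerate"``. Each exclusion records both ratios alongside the
    triggering rule. Idempotent.
    """
    if params is None:
        params = FilterParams()
    dur_scale = 1.0 if params.duration_units == "ms" else 1e-3
    kept: list[SaccadeEvent] = []
    excluded: list[tuple[SaccadeEvent, str, float, float]] = []
    for s in saccades:
        if s.amplitude_deg <= 0:
            excluded.append((s, "degenerate", float("inf"), float("inf")))
            continue
        dur_ratio = s.duration_ms * dur_scale / s.amplitude_deg
        dist_ratio = s.path_length_deg / s.amplitude_deg
        if dur_ratio > params.duration_amplitude_ratio_max:
            excluded.append((s, "duration_ratio", dur_ratio, dist_ratio))
        elif dist_ratio > params.distance_amplitude_ratio_max:
            excluded.append((s, "distance_ratio", dur_ratio, dist_ratio))
        else:
            kept.append(s)
    return kept, excluded
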