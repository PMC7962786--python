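"""Synthetic gaze-study generator.

Produces complete studies — balanced design, sample-level gaze traces,
behavioral responses and exact ground truth — with the statistical
structure the analysis stages assume: a long central first fixation and a
small first saccade, lognormal fixation durations drifting upward with
ordinal number, saccade amplitudes drifting downward, group and task
offsets, a congruence parameter controlling how strongly observers share
image regions, plus injected blinks and hook-shaped artifact saccades.

One global seed expands into independent per-trial substreams through
``numpy.random.SeedSequence`` spawn keys, so any subset of trials can be
regenerated without generating the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ImageFrame, ScreenGeometry, DEFAULT_GEOMETRY, px_per_degree
from .io import Samples, TrialRecord, GROUPS, TASKS

__all__ = [
    "StudyDesign",
    "GenerativeParams",
    "TruthFixation",
    "TruthSaccade",
    "TrialTruth",
    "GroundTruth",
    "generate_study",
    "sample_trial_events",
    "render_trial",
    "inject_artifacts",
    "balanced_assignment",
    "simulate_metric_table",
]


@dataclass(frozen=True)
class StudyDesign:
    """Cohort and trial layout of a simulated study."""

    n_experts: int = 13
    n_nonexperts: int = 14
    n_images: int = 36
    tasks: tuple[str, ...] = TASKS
    trial_ms: float = 5000.0
    sample_rate_hz: float = 1000.0
    image_width_px: int = 1300
    image_height_px: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images % len(self.tasks) != 0:
            raise ValueError("n_images must be divisible by the number of tasks for a balanced design")
        if self.n_experts < 0 or self.n_nonexperts < 0 or self.trial_ms <= 0:
            raise ValueError("invalid study design")

    @property
    def subjects(self) -> list[tuple[str, str]]:
        experts = [(f"s{si:02d}", "expert") for si in range(self.n_experts)]
        non = [(f"s{si:02d}", "nonexpert") for si in range(self.n_experts, self.n_experts + self.n_nonexperts)]
        return experts + non


@dataclass(frozen=True)
class GenerativeParams:
    """Ground-truth parameters of the gaze process.

    Durations in ms, amplitudes/spreads in visual degrees. ``congruence_kappa``
    is the probability that a fixation target is drawn from the image's
    shared regions of interest rather than an observer-private direction.
    """

    n_rois_per_image: int = 4
    congruence_kappa: float = 0.5
    spread_sigma_deg: float = 1.0
    fixdur_lognorm: tuple[float, float] = (5.482, 0.45)  # mean ~ 266 ms
    fixdur_ordinal_slope_ms: float = 3.0
    amp_mean_deg: float = 5.3
    amp_sd_deg: float = 1.5
    amp_ordinal_slope_deg: float = -0.08
    expert_amp_delta_deg: float = 0.5
    medium_task_dur_delta_ms: float = 20.0
    medium_task_amp_delta_deg: float = -0.3
    first_fix_mu_ms: float = 385.0
    first_fix_sd_ms: float = 80.0
    first_sacc_amp_deg: float = 3.2
    first_sacc_sd_deg: float = 0.6
    blink_rate: float = 0.2
    artifact_rate: float = 0.1
    fixation_jitter_sd_deg: float = 0.1
    expert_accuracy: float = 0.50
    nonexpert_accuracy: float = 0.36
    confidence_familiarity_r: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.congruence_kappa <= 1.0:
            raise ValueError("congruence_kappa must lie in [0, 1]")
        if self.spread_sigma_deg <= 0 or self.amp_mean_deg <= 0 or self.fixdur_lognorm[1] <= 0:
            raise ValueError("scale parameters must be strictly positive")

    @property
    def fixdur_base_mean_ms(self) -> float:
        """Closed-form mean of the lognormal duration component."""
        mu, sigma = self.fixdur_lognorm
        return math.exp(mu + sigma**2 / 2.0)


@dataclass
class TruthFixation:
    onset_ms: float
    duration_ms: float
    x_px: float
    y_px: float
    ordinal: int
    from_roi: bool = False


@dataclass
class TruthSaccade:
    onset_ms: float
    duration_ms: float
    start_xy_px: tuple[float, float]
    end_xy_px: tuple[float, float]
    amplitude_deg: float
    ordinal: int


@dataclass
class TrialTruth:
    trial_id: str
    fixations: list[TruthFixation]
    saccades: list[TruthSaccade]
    n_blinks_injected: int = 0
    n_artifacts_injected: int = 0


@dataclass
class GroundTruth:
    design: StudyDesign
    params: GenerativeParams
    roi_centers: dict[str, np.ndarray]
    trials: dict[str, TrialTruth] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


def balanced_assignment(design: StudyDesign) -> dict[str, dict[str, str]]:
    """Per-subject image -> task map.

    Images are split into one set per task; subject ``s`` rotates the
    set-task pairing by ``s mod n_tasks``. Every subject sees each image
    exactly once, and across the cohort each image occurs under every task.
    """
    n_tasks = len(design.tasks)
    set_size = design.n_images // n_tasks
    image_ids = [f"img{i:02d}" for i in range(design.n_images)]
    sets = [image_ids[k * set_size : (k + 1) * set_size] for k in range(n_tasks)]
    out: dict[str, dict[str, str]] = {}
    for s_idx, (sid, _group) in enumerate(design.subjects):
        rot = s_idx % n_tasks
        mapping: dict[str, str] = {}
        for j, task in enumerate(design.tasks):
            for img in sets[(j + rot) % n_tasks]:
                mapping[img] = task
        out[sid] = mapping
    return out


def _roi_centers(design: StudyDesign, params: GenerativeParams, frame: ImageFrame) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 7001]))
    out = {}
    mx, my = frame.width_px * 0.15, frame.height_px * 0.15  # keep ROIs off the border
    for i in range(design.n_images):
        xs = rng.uniform(frame.origin_x_px + mx, frame.origin_x_px + frame.width_px - mx, params.n_rois_per_image)
        ys = rng.uniform(frame.origin_y_px + my, frame.origin_y_px + frame.height_px - my, params.n_rois_per_image)
        out[f"img{i:02d}"] = np.column_stack([xs, ys])
    return out


# ---------------------------------------------------------------------------
# Event-level scanpath sampling (ground truth)
# ---------------------------------------------------------------------------


def _main_sequence_duration_ms(amplitude_deg: float) -> float:
    # conventional main-sequence relation for saccade durations
    return 2.2 * amplitude_deg + 21.0


def sample_trial_events(
    rng: np.random.Generator,
    params: GenerativeParams,
    frame: ImageFrame,
    geom: ScreenGeometry,
    group: str,
    task: str,
    rois: np.ndarray,
    trial_ms: float,
) -> tuple[list[TruthFixation], list[TruthSaccade]]:
    """Draw the ground-truth fixation/saccade sequence for one trial.

    The first fixation sits near image center (central bias) with a long
    duration; each later fixation target is a shared ROI draw with
    probability ``congruence_kappa``, otherwise an observer-private random
    direction, with the realized saccade amplitude carrying the group, task
    and ordinal effects.
    """
    ppd = px_per_degree(geom, check_isotropy=False)
    cx, cy = frame.center
    margin = 10.0  # px inset keeping fixations inside the frame

    def clamp(x: float, y: float) -> tuple[float, float]:
        x = min(max(x, frame.origin_x_px + margin), frame.origin_x_px + frame.width_px - 1 - margin)
        y = min(max(y, frame.origin_y_px + margin), frame.origin_y_px + frame.height_px - 1 - margin)
        return x, y

    amp_delta = (params.expert_amp_delta_deg if group == "expert" else 0.0) + (
        params.medium_task_amp_delta_deg if task == "medium" else 0.0
    )
    dur_delta = params.medium_task_dur_delta_ms if task == "medium" else 0.0
    mu, sigma = params.fixdur_lognorm

    fixations: list[TruthFixation] = []
    saccades: list[TruthSaccade] = []

    pos = clamp(cx + rng.normal(0, 0.3 * ppd), cy + rng.normal(0, 0.3 * ppd))
    first_dur = max(rng.normal(params.first_fix_mu_ms, params.first_fix_sd_ms), 120.0)
    t = 0.0
    ordinal = 1
    fixations.append(TruthFixation(t, first_dur, pos[0], pos[1], ordinal))
    t += first_dur

    while True:
        k = ordinal  # saccade ordinal
        if k == 1:
            base = rng.normal(params.first_sacc_amp_deg, params.first_sacc_sd_deg)
        else:
            base = rng.normal(
                params.amp_mean_deg + params.amp_ordinal_slope_deg * (k - 1), params.amp_sd_deg
            )
        amp = float(np.clip(base + amp_delta, 0.7, 15.0))
        amp_px = amp * ppd

        from_roi = bool(rng.random() < params.congruence_kappa)
        target = None
        if from_roi:
            roi = rois[rng.integers(len(rois))]
            jx, jy = rng.normal(0, params.spread_sigma_deg * ppd, 2)
            aim = (roi[0] + jx, roi[1] + jy)
            d = math.hypot(aim[0] - pos[0], aim[1] - pos[1])
            if d > 1e-9:
                u = ((aim[0] - pos[0]) / d, (aim[1] - pos[1]) / d)
                cand = (pos[0] + amp_px * u[0], pos[1] + amp_px * u[1])
                if frame.contains(*clamp(*cand)) and clamp(*cand) == cand:
                    target = cand
        if target is None:
            for _ in range(25):
                theta = rng.uniform(0, 2 * math.pi)
                cand = (pos[0] + amp_px * math.cos(theta), pos[1] + amp_px * math.sin(theta))
                if clamp(*cand) == cand:
                    target = cand
                    break
            if target is None:  # corner case: aim back toward center, accept the clamp
                d = math.hypot(cx - pos[0], cy - pos[1]) or 1.0
                target = clamp(pos[0] + amp_px * (cx - pos[0]) / d, pos[1] + amp_px * (cy - pos[1]) / d)

        sacc_dur = _main_sequence_duration_ms(amp)
        fix_dur = float(
            rng.lognormal(mu, sigma) + params.fixdur_ordinal_slope_ms * ordinal + dur_delta
        )
        fix_dur = max(fix_dur, 40.0)
        if t + sacc_dur + 60.0 >= trial_ms:
            break
        real_amp = math.hypot(target[0] - pos[0], target[1] - pos[1]) / ppd
        saccades.append(TruthSaccade(t, sacc_dur, pos, target, real_amp, k))
        t += sacc_dur
        ordinal += 1
        fix_dur = min(fix_dur, trial_ms - t)
        fixations.append(TruthFixation(t, fix_dur, target[0], target[1], ordinal, from_roi))
        t += fix_dur
        pos = target
        if t >= trial_ms - 1.0:
            break
    # stretch the last fixation to the trial end so events tile the trial
    last = fixations[-1]
    last.duration_ms = trial_ms - last.onset_ms
    return fixations, saccades


# ---------------------------------------------------------------------------
# Sample-level rendering
# ---------------------------------------------------------------------------


def _minjerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def render_trial(
    rng: np.random.Generator,
    fixations: list[TruthFixation],
    saccades: list[TruthSaccade],
    params: GenerativeParams,
    geom: ScreenGeometry,
    trial_ms: float,
    sample_rate_hz: float = 1000.0,
) -> Samples:
    """Render ground-truth events into a 1-sample-per-ms gaze trace.

    Fixations get slow sinusoidal drift (SD ~= ``fixation_jitter_sd_deg``,
    velocity well below detection thresholds); saccades follow a smooth
    minimum-jerk displacement profile between the flanking fixation centers.
    """
    dt_ms = 1000.0 / sample_rate_hz
    n = int(round(trial_ms / dt_ms))
    t = np.arange(n) * dt_ms
    x = np.zeros(n)
    y = np.zeros(n)
    ppd = px_per_degree(geom, check_isotropy=False)
    jitter_amp = params.fixation_jitter_sd_deg * ppd * math.sqrt(2)  # sine SD = A/sqrt(2)

    # events tile the trial; fill sample ranges without gaps so no index is
    # left uninitialized even when float onsets do not land on the grid
    timeline = sorted(
        [("fix", f) for f in fixations] + [("sacc", s) for s in saccades],
        key=lambda kv: kv[1].onset_ms,
    )
    bounds = [int(round(ev.onset_ms / dt_ms)) for _, ev in timeline] + [n]
    for (kind, ev), i0, i1 in zip(timeline, bounds[:-1], bounds[1:]):
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            continue
        if kind == "fix":
            tt = (t[i0:i1] - t[i0]) / 1000.0
            dur_s = max((i1 - i0) * dt_ms / 1000.0, 1e-6)
            fx, fy = rng.uniform(0.4, 2.0, 2)
            phx, phy = rng.uniform(0, 2 * math.pi, 2)
            # ramp jitter to zero at the edges so saccades join continuously
            ramp = np.minimum(np.minimum(tt, dur_s - tt) / 0.05, 1.0).clip(min=0.0)
            x[i0:i1] = ev.x_px + ramp * jitter_amp * np.sin(2 * math.pi * fx * tt + phx)
            y[i0:i1] = ev.y_px + ramp * jitter_amp * np.sin(2 * math.pi * fy * tt + phy)
        else:
            tau = np.linspace(0.0, 1.0, i1 - i0, endpoint=False)
            prof = _minjerk(tau)
            x[i0:i1] = ev.start_xy_px[0] + (ev.end_xy_px[0] - ev.start_xy_px[0]) * prof
            y[i0:i1] = ev.start_xy_px[1] + (ev.end_xy_px[1] - ev.start_xy_px[1]) * prof

    return Samples(t, x, y, np.ones(n, dtype=bool))


def inject_artifacts(
    samples: Samples,
    artifact_rate: float,
    blink_rate: float,
    seed: int | np.random.Generator,
) -> tuple[Samples, dict[str, int]]:
    """Insert blink runs and hook-shaped artifact saccades into a trace.

    Blinks are runs of ``valid=False``. Each hook is an out-and-back
    minimum-jerk excursion with a large detour relative to its net
    displacement (path/amplitude well above 3.5), shifting all later samples
    by the small net offset so the trace stays continuous. Returns the
    modified trace and injection counts.
    """
    if artifact_rate < 0 or blink_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(samples)
    if n == 0 or (artifact_rate == 0 and blink_rate == 0):
        return samples, {"blinks": 0, "artifacts": 0}
    t = samples.t_ms.copy()
    x = samples.x_px.copy()
    y = samples.y_px.copy()
    valid = samples.valid.copy()
    dt = float(np.median(np.diff(t))) if n > 1 else 1.0

    occupied = np.zeros(n, dtype=bool)  # injection windows already used

    def free_window(width: int, margin: int) -> int | None:
        for _ in range(50):
            i0 = int(rng.integers(margin, max(n - width - margin, margin + 1)))
            if not occupied[max(i0 - margin, 0) : i0 + width + margin].any():
                return i0
        return None

    # cap by what can physically fit in the trace
    max_events = max(n // int(round(200.0 / dt)), 1)
    n_hooks = min(int(rng.poisson(artifact_rate)), max_events)
    n_blinks = min(int(rng.poisson(blink_rate)), max_events)
    hooks_done = 0
    for _ in range(n_hooks):
        width = int(round(80.0 / dt))
        i0 = free_window(width, int(round(150.0 / dt)))
        if i0 is None:
            continue
        theta = rng.uniform(0, 2 * math.pi)
        u = np.array([math.cos(theta), math.sin(theta)])
        net_px = 1.5 * 39.0  # ~1.5 deg net amplitude at study geometry
        detour_px = 4.0 * net_px  # path/amplitude ~ 7
        half = width // 2
        tau1 = np.linspace(0, 1, half, endpoint=False)
        tau2 = np.linspace(0, 1, width - half)
        out = detour_px * _minjerk(tau1)
        back = detour_px + (net_px - detour_px) * _minjerk(tau2)
        disp = np.concatenate([out, back])
        x[i0 : i0 + width] += disp * u[0]
        y[i0 : i0 + width] += disp * u[1]
        x[i0 + width :] += net_px * u[0]
        y[i0 + width :] += net_px * u[1]
        occupied[i0 : i0 + width] = True
        hooks_done += 1
    blinks_done = 0
    for _ in range(n_blinks):
        width = int(round(rng.uniform(80.0, 150.0) / dt))
        i0 = free_window(width, int(round(100.0 / dt)))
        if i0 is None:
            continue
        valid[i0 : i0 + width] = False
        occupied[i0 : i0 + width] = True
        blinks_done += 1

    return Samples(t, x, y, valid), {"blinks": blinks_done, "artifacts": hooks_done}


# ---------------------------------------------------------------------------
# Full study generation
# ---------------------------------------------------------------------------


def generate_study(
    design: StudyDesign,
    params: GenerativeParams | None = None,
    render_samples: bool = True,
) -> tuple[list[TrialRecord], GroundTruth]:
    """Generate a complete synthetic study.

    Returns trial records (with rendered samples unless ``render_samples``
    is False) and the exact ground truth. Same design/params/seed gives a
    bit-identical study.
    """
    if params is None:
        params = GenerativeParams()
    geom = DEFAULT_GEOMETRY
    frame = ImageFrame.centered(geom, design.image_width_px, design.image_height_px)
    assignment = balanced_assignment(design)
    rois = _roi_centers(design, params, frame)
    truth = GroundTruth(design=design, params=params, roi_centers=rois)

    trials: list[TrialRecord] = []
    for s_idx, (sid, group) in enumerate(design.subjects):
        acc = params.expert_accuracy if group == "expert" else params.nonexpert_accuracy
        for i_idx in range(design.n_images):
            image_id = f"img{i_idx:02d}"
            task = assignment[sid][image_id]
            trial_id = f"{sid}_{image_id}"
            rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1, s_idx, i_idx]))

            fixations, saccades = sample_trial_events(
                rng, params, frame, geom, group, task, rois[image_id], design.trial_ms
            )
            n_blinks = n_artifacts = 0
            samples = None
            if render_samples:
                samples = render_trial(
                    rng, fixations, saccades, params, geom, design.trial_ms, design.sample_rate_hz
                )
                samples, counts = inject_artifacts(
                    samples, params.artifact_rate, params.blink_rate, rng
                )
                n_blinks, n_artifacts = counts["blinks"], counts["artifacts"]

            task_acc = float(np.clip(acc + (-0.12 if task == "date" else 0.0), 0.02, 0.98))
            correct = bool(rng.random() < task_acc)
            familiarity = float(np.clip(rng.normal(2.0 if group == "expert" else 1.5, 1.2), 1, 6))
            conf_latent = (
                params.confidence_familiarity_r * familiarity
                + (0.9 if group == "expert" else 0.0)
                + rng.normal(3.0, 1.1)
            )
            confidence = int(np.clip(round(conf_latent), 1, 6))
            trials.append(
                TrialRecord(
                    trial_id=trial_id,
                    subject_id=sid,
                    group=group,
                    image_id=image_id,
                    task=task,
                    presentation_ms=design.trial_ms,
                    answer="sim",
                    correct=correct,
                    confidence_raw=7 - confidence,  # stored raw, reversed downstream
                    familiarity_raw=7 - int(np.clip(round(familiarity), 1, 6)),
                    samples=samples,
                )
            )
            truth.trials[trial_id] = TrialTruth(
                trial_id, fixations, saccades, n_blinks, n_artifacts
            )
    return trials, truth


# ---------------------------------------------------------------------------
# Direct metric-table simulation (for the mixed-model test harness)
# ---------------------------------------------------------------------------


def simulate_metric_table(
    n_subjects: int,
    n_images: int,
    rng: np.random.Generator,
    grand_mean: float = 5.3,
    task_effects: dict[str, float] | None = None,
    expertise_effect: float = 0.0,
    sd_subject: float = 0.4,
    sd_image: float = 0.3,
    sd_noise: float = 1.0,
    tasks: tuple[str, ...] = TASKS,
):
    """Trial-level metric table drawn directly from the crossed-intercepts LMM.

    Balanced subject x image design with rotating task assignment; subjects
    alternate expertise groups. Used to calibrate type-I error and power of
    the likelihood-ratio harness without rendering gaze traces.
    """
    import pandas as pd

    task_effects = task_effects or {}
    b_subj = rng.normal(0, sd_subject, n_subjects)
    b_img = rng.normal(0, sd_image, n_images)
    rows = []
    for s in range(n_subjects):
        group = "expert" if s % 2 == 0 else "nonexpert"
        for i in range(n_images):
            task = tasks[(s + i) % len(tasks)]
            yv = (
                grand_mean
                + task_effects.get(task, 0.0)
                + (expertise_effect if group == "expert" else 0.0)
                + b_subj[s]
                + b_img[i]
                + rng.normal(0, sd_noise)
            )
            rows.append(
                {"subject": f"s{s}", "image": f"i{i}", "task": task, "expertise": group, "value": yv}
            )
    return pd.DataFrame(rows)
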