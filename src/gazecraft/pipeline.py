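"""End-to-end orchestration: samples -> events -> metrics -> statistics -> report."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import (
    DetectionParams,
    FilterParams,
    detect_blinks,
    detect_saccades,
    derive_fixations,
    filter_fixations,
    filter_saccade_artifacts,
)
from .geometry import DEFAULT_GEOMETRY, ImageFrame, ScreenGeometry
from .io import Samples, TrialRecord, read_samples, read_trials
from .maps import KernelSpec
from .metrics import dispersion, fixation_points, group_heatmap, nss_loo
from .simulate import GenerativeParams, StudyDesign, generate_study
from .stats import (
    ModelSpec,
    lrt_effect,
    ordinal_profile,
    reverse_rating,
    rmcorr,
    summarize_behavior,
)

log = logging.getLogger("gazecraft")

__all__ = ["RunConfig", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Exactly one of synthetic mode (``synthetic=True``) or real input paths
    must be active. The saccade ratio filter defaults to seconds per degree
    here (the printed thresholds exclude essentially all physiological
    saccades when read as ms/deg; the unit stays configurable and the
    exclusion fraction is logged with a warning above 50%).
    """

    synthetic: bool = True
    samples_path: str | None = None
    trials_path: str | None = None
    samples_dialect: str = "csv"
    out_dir: str = "gazecraft_out"
    seed: int = 0
    log_level: str = "INFO"

    # geometry / stimulus placement
    screen: dict = field(
        default_factory=lambda: dict(
            width_px=1920, height_px=1080, width_cm=51.5, height_cm=29.0, viewing_distance_cm=60.0
        )
    )
    image_width_px: int = 1300
    image_height_px: int = 800

    # stage parameters
    detection: dict = field(default_factory=dict)
    filters: dict = field(default_factory=lambda: dict(duration_units="s"))
    kernel: dict = field(default_factory=dict)
    nss_aggregate: str = "mean"
    grid_step: int = 2
    write_heatmaps: bool = False
    downsample_from_2k: bool = False

    # synthetic mode
    design: dict = field(default_factory=dict)
    generative: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.synthetic and (self.samples_path or self.trials_path):
            raise ValueError("choose either synthetic mode or real input paths, not both")
        if not self.synthetic and not (self.samples_path and self.trials_path):
            raise ValueError("real-input mode needs samples_path and trials_path")
        if self.nss_aggregate not in ("mean", "sum"):
            raise ValueError("nss_aggregate must be 'mean' or 'sum'")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- materialized parameter objects -------------------------------------
    @property
    def geometry(self) -> ScreenGeometry:
        return ScreenGeometry(**self.screen)

    @property
    def frame(self) -> ImageFrame:
        return ImageFrame.centered(self.geometry, self.image_width_px, self.image_height_px)

    @property
    def detection_params(self) -> DetectionParams:
        return DetectionParams(**self.detection)

    @property
    def filter_params(self) -> FilterParams:
        return FilterParams(**self.filters)

    @property
    def kernel_spec(self) -> KernelSpec:
        return KernelSpec(**self.kernel)

    @property
    def study_design(self) -> StudyDesign:
        d = dict(self.design)
        d.setdefault("seed", self.seed)
        d.setdefault("image_width_px", self.image_width_px)
        d.setdefault("image_height_px", self.image_height_px)
        return StudyDesign(**d)

    @property
    def generative_params(self) -> GenerativeParams:
        return GenerativeParams(**self.generative)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def process_trial(
    samples: Samples,
    config: RunConfig,
) -> dict:
    """Detect and filter events for one trial; returns all event products."""
    geom = config.geometry
    frame = config.frame
    blinks = detect_blinks(samples)
    saccades = detect_saccades(samples, config.detection_params, geom, blinks)
    fixations = derive_fixations(samples, saccades, blinks)
    kept_fix, removed_fix = filter_fixations(fixations, frame)
    kept_sacc, excluded_sacc = filter_saccade_artifacts(saccades, config.filter_params)
    return {
        "blinks": blinks,
        "saccades": saccades,
        "fixations": fixations,
        "kept_fixations": kept_fix,
        "removed_fixations": removed_fix,
        "kept_saccades": kept_sacc,
        "excluded_saccades": excluded_sacc,
    }


def _events_frame(trial: TrialRecord, products: dict) -> pd.DataFrame:
    rows = []
    excluded_ids = {id(s) for s, *_ in products["excluded_saccades"]}
    reasons = {id(s): reason for s, reason, *_ in products["excluded_saccades"]}
    removed = {id(f): reason for f, reason in products["removed_fixations"]}
    for s in products["saccades"]:
        rows.append(
            dict(
                trial_id=trial.trial_id,
                event_type="saccade",
                ordinal=s.ordinal,
                onset_ms=s.onset_ms,
                offset_ms=s.offset_ms,
                duration_ms=s.duration_ms,
                x_px=s.end_xy_px[0],
                y_px=s.end_xy_px[1],
                amplitude_deg=s.amplitude_deg,
                path_length_deg=s.path_length_deg,
                peak_vel=s.peak_velocity_deg_s,
                excluded=int(id(s) in excluded_ids),
                reason=reasons.get(id(s), ""),
            )
        )
    for f in products["fixations"]:
        rows.append(
            dict(
                trial_id=trial.trial_id,
                event_type="fixation",
                ordinal=f.ordinal,
                onset_ms=f.onset_ms,
                offset_ms=f.offset_ms,
                duration_ms=f.duration_ms,
                x_px=f.centroid_x_px,
                y_px=f.centroid_y_px,
                amplitude_deg=np.nan,
                path_length_deg=np.nan,
                peak_vel=np.nan,
                excluded=int(id(f) in removed),
                reason=removed.get(id(f), ""),
            )
        )
    for b in products["blinks"]:
        rows.append(
            dict(
                trial_id=trial.trial_id,
                event_type="blink",
                ordinal=0,
                onset_ms=b.onset_ms,
                offset_ms=b.offset_ms,
                duration_ms=b.duration_ms,
                x_px=np.nan,
                y_px=np.nan,
                amplitude_deg=np.nan,
                path_length_deg=np.nan,
                peak_vel=np.nan,
                excluded=0,
                reason="",
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all artifacts to ``config.out_dir``.

    Stages: load/generate -> (downsample) -> detect -> filter -> metrics
    (leave-one-out NSS, dispersion, heatmaps) -> statistics (mixed-model
    LRTs, rmcorr, behavioral summary, ordinal profiles). A manifest records
    the config hash, seed, package version and per-stage record counts.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    invalid_marker = out / "INVALID"
    invalid_marker.write_text("run in progress / aborted\n")

    try:
        artifacts = _run_stages(config, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    invalid_marker.unlink()
    return artifacts


def _run_stages(config: RunConfig, out: Path) -> dict:
    geom = config.geometry
    frame = config.frame
    kernel = config.kernel_spec

    # -- stage: load / generate --------------------------------------------
    if config.synthetic:
        log.info("generating synthetic study (seed=%d)", config.seed)
        trials, _truth = generate_study(config.study_design, config.generative_params)
        samples_by_trial = {t.trial_id: t.samples for t in trials}
    else:
        samples_by_trial = read_samples(config.samples_path, config.samples_dialect)
        trials = read_trials(config.trials_path)
        missing = [t.trial_id for t in trials if t.trial_id not in samples_by_trial]
        if missing:
            raise ValueError(f"trials without samples: {missing[:5]}...")

    if config.downsample_from_2k:
        from .io import downsample_2k_to_1k

        samples_by_trial = {k: downsample_2k_to_1k(v) for k, v in samples_by_trial.items()}

    # -- stage: events ------------------------------------------------------
    log.info("detecting events in %d trials", len(trials))
    products_by_trial: dict[str, dict] = {}
    event_frames = []
    n_sacc_total = n_sacc_excluded = 0
    for t in trials:
        products = process_trial(samples_by_trial[t.trial_id], config)
        products_by_trial[t.trial_id] = products
        event_frames.append(_events_frame(t, products))
        n_sacc_total += len(products["saccades"])
        n_sacc_excluded += len(products["excluded_saccades"])
    events_df = pd.concat(event_frames, ignore_index=True)
    events_df.to_csv(out / "events.csv", index=False)
    if n_sacc_total and n_sacc_excluded / n_sacc_total > 0.5:
        warnings.warn(
            f"saccade ratio filter excluded {n_sacc_excluded}/{n_sacc_total} "
            f"({n_sacc_excluded / n_sacc_total:.0%}) of saccades; check duration_units",
            stacklevel=2,
        )

    # -- stage: metrics -----------------------------------------------------
    log.info("computing NSS and dispersion")
    trial_index = {t.trial_id: t for t in trials}
    by_cell: dict[tuple[str, str], list[TrialRecord]] = {}
    for t in trials:
        by_cell.setdefault((t.image_id, t.task), []).append(t)

    metric_rows = []
    for (image_id, task), cell_trials in sorted(by_cell.items()):
        observer_sets = []
        meta = {}
        for t in cell_trials:
            pts = fixation_points(products_by_trial[t.trial_id]["kept_fixations"])
            observer_sets.append((t.subject_id, pts))
            meta[t.subject_id] = dict(image_id=image_id, task=task, group=t.group)
        n_with_fix = sum(1 for _, p in observer_sets if len(p) > 0)
        nss_records = (
            nss_loo(observer_sets, kernel, frame, geom, config.nss_aggregate, config.grid_step, meta)
            if n_with_fix >= 2
            else []
        )
        nss_by_subject = {r.subject_id: r for r in nss_records}
        for t in cell_trials:
            pts = fixation_points(products_by_trial[t.trial_id]["kept_fixations"])
            disp = (
                dispersion(pts, kernel, frame, geom, config.grid_step)
                if len(pts) > 0
                else float("nan")
            )
            rec = nss_by_subject.get(t.subject_id)
            metric_rows.append(
                dict(
                    subject_id=t.subject_id,
                    image_id=image_id,
                    task=task,
                    group=t.group,
                    nss=rec.nss if rec else float("nan"),
                    dispersion=disp,
                    n_fixations=len(pts),
                )
            )
    metrics_df = pd.DataFrame(metric_rows)
    metrics_df.to_csv(out / "metrics.csv", index=False)

    if config.write_heatmaps:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for (image_id, task), cell_trials in sorted(by_cell.items()):
            for grp in sorted({t.group for t in cell_trials}):
                sets = []
                for t in cell_trials:
                    if t.group != grp:
                        continue
                    kept = products_by_trial[t.trial_id]["kept_fixations"]
                    if kept:
                        sets.append(
                            (
                                fixation_points(kept),
                                np.array([f.duration_ms for f in kept]),
                            )
                        )
                if sets:
                    hm = group_heatmap(sets, kernel, frame, geom, config.grid_step)
                    hm.write(maps_dir / f"{image_id}_{task}_{grp}.txt")

    # -- stage: statistics --------------------------------------------------
    log.info("fitting mixed models")
    stats_out = _run_stats(trials, products_by_trial, metrics_df, out)

    # -- manifest -----------------------------------------------------------
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    # hash the analysis-relevant config only: output location and verbosity
    # do not change results
    hashed = {k: v for k, v in config.to_dict().items() if k not in ("out_dir", "log_level")}
    manifest = {
        "gazecraft_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(yaml.safe_dump(hashed, sort_keys=True).encode()).hexdigest(),
        "n_trials": len(trials),
        "n_saccades_detected": n_sacc_total,
        "n_saccades_excluded": n_sacc_excluded,
        "n_fixations_detected": int((events_df["event_type"] == "fixation").sum()),
        "n_fixations_removed": int(
            ((events_df["event_type"] == "fixation") & (events_df["excluded"] == 1)).sum()
        ),
        "n_blinks": int((events_df["event_type"] == "blink").sum()),
        "n_tests": len(stats_out["tests"]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "config.yaml").write_text(cfg_yaml)

    artifacts = {
        "config": config,
        "events": events_df,
        "metrics": metrics_df,
        "manifest": manifest,
        **stats_out,
    }
    report = make_report(artifacts)
    (out / "report.txt").write_text(report)
    artifacts["report"] = report
    return artifacts


def _kept_event_table(trials, products_by_trial) -> pd.DataFrame:
    """Event-level analysis table: one row per kept fixation/saccade."""
    rows = []
    for t in trials:
        p = products_by_trial[t.trial_id]
        for f in p["kept_fixations"]:
            rows.append(
                dict(
                    subject=t.subject_id,
                    image=t.image_id,
                    task=t.task,
                    expertise=t.group,
                    event="fixation",
                    ordinal=f.ordinal,
                    fixation_duration=f.duration_ms,
                    saccade_amplitude=np.nan,
                )
            )
        for s in p["kept_saccades"]:
            rows.append(
                dict(
                    subject=t.subject_id,
                    image=t.image_id,
                    task=t.task,
                    expertise=t.group,
                    event="saccade",
                    ordinal=s.ordinal,
                    fixation_duration=np.nan,
                    saccade_amplitude=s.amplitude_deg,
                )
            )
    return pd.DataFrame(rows)


def _run_stats(trials, products_by_trial, metrics_df: pd.DataFrame, out: Path) -> dict:
    behavior = pd.DataFrame(
        [
            dict(
                subject=t.subject_id,
                image=t.image_id,
                group=t.group,
                task=t.task,
                expertise=t.group,
                correct=int(t.correct),
                confidence=reverse_rating(t.confidence_raw),
                familiarity=reverse_rating(t.familiarity_raw),
            )
            for t in trials
        ]
    )
    events = _kept_event_table(trials, products_by_trial)

    tests = []

    def _test(name: str, data: pd.DataFrame, response: str, effect: str, fixed=("task", "expertise")):
        try:
            res = lrt_effect(data.dropna(subset=[response]), ModelSpec(response, tuple(fixed)), effect)
            tests.append(
                dict(response=name, effect=effect, chi2=res.chi2, df=res.df, p=res.p)
            )
        except Exception as exc:  # aborted tests are reported, not fatal
            log.warning("LRT %s/%s failed: %s", name, effect, exc)
            tests.append(dict(response=name, effect=effect, error=str(exc)))

    # four primary models: task and expertise as fixed effects, no interaction
    for effect in ("task", "expertise"):
        _test("accuracy", behavior.assign(value=behavior["correct"].astype(float)), "value", effect)
        _test("confidence", behavior.assign(value=behavior["confidence"].astype(float)), "value", effect)
        fx = events[events["event"] == "fixation"].assign(
            value=np.log(events.loc[events["event"] == "fixation", "fixation_duration"])
        )
        _test("log_fixation_duration", fx, "value", effect)
        sc = events[events["event"] == "saccade"].assign(
            value=events.loc[events["event"] == "saccade", "saccade_amplitude"]
        )
        _test("saccade_amplitude", sc, "value", effect)

    # NSS / dispersion models (image random intercept only, as reported)
    mtab = metrics_df.rename(columns={"subject_id": "subject", "image_id": "image"}).assign(
        expertise=metrics_df["group"]
    )
    for response in ("nss", "dispersion"):
        sub = mtab.dropna(subset=[response]).assign(value=lambda d: d[response])
        for effect in ("task", "expertise"):
            try:
                res = lrt_effect(
                    sub,
                    ModelSpec("value", (effect,), random_intercepts=("image",)),
                    effect,
                )
                tests.append(dict(response=response, effect=effect, chi2=res.chi2, df=res.df, p=res.p))
            except Exception as exc:
                log.warning("LRT %s/%s failed: %s", response, effect, exc)
                tests.append(dict(response=response, effect=effect, error=str(exc)))

    rm = rmcorr(behavior.rename(columns={"confidence": "x", "familiarity": "y"}), "subject", "x", "y")

    fix_events = events[events["event"] == "fixation"].rename(columns={"fixation_duration": "value"})
    sacc_events = events[events["event"] == "saccade"].rename(columns={"saccade_amplitude": "value"})
    profiles = {
        "fixation_duration": ordinal_profile(fix_events, "fixation_duration"),
        "saccade_amplitude": ordinal_profile(sacc_events, "saccade_amplitude"),
    }

    summary = summarize_behavior(behavior)
    summary.to_csv(out / "behavior_summary.csv", index=False)

    stats_report = {
        "tests": tests,
        "rmcorr": dict(r=rm.r, df=rm.df, p=rm.p),
        "ordinal_profiles": {
            k: dict(
                ordinals=v.ordinals,
                means=v.means,
                ci_low=v.ci_low,
                ci_high=v.ci_high,
                first_event_mean=v.first_event_mean,
                first_event_sd=v.first_event_sd,
            )
            for k, v in profiles.items()
        },
    }
    (out / "stats.json").write_text(json.dumps(stats_report, indent=1))
    return {
        "tests": tests,
        "rmcorr": rm,
        "profiles": profiles,
        "behavior": behavior,
        "behavior_summary": summary,
        "event_table": events,
    }


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def _cell_stats(df: pd.DataFrame, value: str) -> str:
    if df.empty or df[value].dropna().empty:
        return "absent"
    v = df[value].dropna()
    return f"{v.mean():8.3f} (SD {v.std(ddof=1):6.3f}, n={len(v)})"


def make_report(artifacts: dict) -> str:
    """Human-readable group x task summary tables of all key measures."""
    lines = ["gazecraft run report", "=" * 60]
    manifest = artifacts.get("manifest", {})
    for k in ("n_trials", "n_saccades_detected", "n_saccades_excluded", "n_fixations_detected"):
        if k in manifest:
            lines.append(f"{k}: {manifest[k]}")
    lines.append("")

    behavior = artifacts.get("behavior")
    events = artifacts.get("event_table")
    metrics = artifacts.get("metrics")

    sections: list[tuple[str, pd.DataFrame | None, str, str]] = [
        ("Accuracy", behavior, "correct", "group"),
        ("Confidence", behavior, "confidence", "group"),
        ("Fixation duration (ms)", events, "fixation_duration", "expertise"),
        ("Saccade amplitude (deg)", events, "saccade_amplitude", "expertise"),
        ("NSS", metrics, "nss", "group"),
        ("Dispersion", metrics, "dispersion", "group"),
    ]
    for title, df, col, group_col in sections:
        lines.append(title)
        if df is None or col not in getattr(df, "columns", []):
            lines.append("  [section absent]")
            lines.append("")
            continue
        for grp in sorted(df[group_col].dropna().unique()):
            sub = df[df[group_col] == grp]
            lines.append(f"  {grp:<10} all tasks: {_cell_stats(sub, col)}")
            for task in sorted(sub['task'].dropna().unique()):
                lines.append(f"    {task:<9}: {_cell_stats(sub[sub['task'] == task], col)}")
        lines.append("")

    tests = artifacts.get("tests", [])
    if tests:
        lines.append("Likelihood-ratio tests")
        for tst in tests:
            if "error" in tst:
                lines.append(f"  {tst['response']:<22} {tst['effect']:<10} FAILED: {tst['error']}")
            else:
                lines.append(
                    f"  {tst['response']:<22} {tst['effect']:<10} "
                    f"chi2({tst['df']}) = {tst['chi2']:.2f}, p = {tst['p']:.4g}"
                )
        lines.append("")
    rm = artifacts.get("rmcorr")
    if rm is not None:
        lines.append(f"rmcorr(confidence, familiarity): r({rm.df}) = {rm.r:.3f}, p = {rm.p:.4g}")
    return "\n".join(lines) + "\n"
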