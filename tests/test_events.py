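import numpy as np
import pytest

from gazecraft.events import (
    DetectionParams,
    FilterParams,
    SaccadeEvent,
    detect_blinks,
    detect_saccades,
    derive_fixations,
    filter_fixations,
    filter_saccade_artifacts,
)
from gazecraft.io import Samples

from conftest import brute_force_saccade_scan, make_saccade_trial, make_still_trial

PPD = 39.041154024075055


class TestDetectBlinks:
    def test_all_valid_trial_gives_empty(self):
        assert detect_blinks(make_still_trial(300)) == []

    def test_single_invalid_run_length(self):
        s = make_still_trial(500)
        s.valid[100:180] = False
        (blink,) = detect_blinks(s)
        assert blink.onset_ms == 100.0
        assert blink.duration_ms == pytest.approx(80.0)

    def test_two_runs_sorted_nonoverlapping_matches_scan(self, rng):
        s = make_still_trial(600)
        s.valid[50:90] = False
        s.valid[400:430] = False
        blinks = detect_blinks(s)
        # brute-force run-length scan
        expected = []
        run = None
        for i, v in enumerate(s.valid):
            if not v and run is None:
                run = [i, i]
            elif not v:
                run[1] = i
            elif run is not None:
                expected.append(tuple(run))
                run = None
        assert [(b.onset_ms, b.offset_ms - 1.0) for b in blinks] == [(a, b) for a, b in expected]
        assert blinks[0].offset_ms <= blinks[1].onset_ms


class TestDetectSaccades:
    def test_constant_position_gives_none(self, geom):
        assert detect_saccades(make_still_trial(400), DetectionParams(), geom) == []

    def test_single_sigmoid_saccade_matches_brute_force(self, geom):
        s = make_saccade_trial(amplitude_deg=5.0, sacc_dur_ms=40)
        events = detect_saccades(s, DetectionParams(), geom)
        assert len(events) == 1
        (ev,) = events
        assert ev.amplitude_deg == pytest.approx(5.0, abs=0.05)
        # peak velocity of a minimum-jerk 5 deg / 40 ms profile is ~234 deg/s
        assert ev.peak_velocity_deg_s == pytest.approx(1.875 * 5.0 / 0.040, rel=0.05)
        runs = brute_force_saccade_scan(s, geom)
        assert len(runs) == 1
        assert abs(ev.onset_ms - s.t_ms[runs[0][0]]) <= 2.0

    def test_two_separated_saccades_get_ordinals(self, geom):
        s = make_saccade_trial(amplitude_deg=4.0, still_ms=300, n_saccades=2)
        events = detect_saccades(s, DetectionParams(), geom)
        assert [e.ordinal for e in events] == [1, 2]
        runs = brute_force_saccade_scan(s, geom)
        assert len(runs) == 2
        for ev, (i0, i1) in zip(events, runs):
            assert abs(ev.onset_ms - s.t_ms[i0]) <= 2.0
            assert abs(ev.offset_ms - (s.t_ms[i1] + 1.0)) <= 2.0

    def test_trial_shorter_than_window_rejected(self, geom):
        s = make_still_trial(3)
        with pytest.raises(ValueError, match="smoothing"):
            detect_saccades(s, DetectionParams(smoothing_halfwidth=5), geom)

    def test_saccade_overlapping_blink_discarded(self, geom):
        s = make_saccade_trial(amplitude_deg=5.0)
        s.valid[310:330] = False  # inside the displacement
        events = detect_saccades(s, DetectionParams(), geom)
        assert events == []

    def test_path_length_at_least_amplitude(self, geom):
        s = make_saccade_trial(amplitude_deg=6.0)
        (ev,) = detect_saccades(s, DetectionParams(), geom)
        assert ev.path_length_deg >= ev.amplitude_deg


class TestDeriveFixations:
    def test_one_central_saccade_two_fixations(self, geom):
        s = make_saccade_trial()
        sacc = detect_saccades(s, DetectionParams(), geom)
        fix = derive_fixations(s, sacc, [])
        assert len(fix) == 2
        assert [f.ordinal for f in fix] == [1, 2]
        assert fix[0].centroid_x_px == pytest.approx(700.0, abs=1.0)
        assert fix[1].centroid_x_px == pytest.approx(700.0 + 5 * PPD, abs=1.0)

    def test_fixation_bordering_blink_flagged(self, geom):
        s = make_still_trial(600)
        s.valid[200:300] = False
        blinks = detect_blinks(s)
        fix = derive_fixations(s, [], blinks)
        assert len(fix) == 2
        assert all(f.blink_adjacent for f in fix)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_k_saccades_give_k_plus_1_fixations(self, geom, k):
        s = make_saccade_trial(amplitude_deg=3.0, still_ms=250, n_saccades=k)
        sacc = detect_saccades(s, DetectionParams(), geom)
        assert len(sacc) == k
        fix = derive_fixations(s, sacc, [])
        # interval-complement oracle: k occupied runs inside the trial leave k+1 gaps
        assert len(fix) == k + 1

    def test_events_partition_trial(self, geom):
        s = make_saccade_trial(amplitude_deg=4.0, n_saccades=3, still_ms=220)
        s.valid[120:170] = False
        blinks = detect_blinks(s)
        sacc = detect_saccades(s, DetectionParams(), geom, blinks)
        fix = derive_fixations(s, sacc, blinks)
        total = (
            sum(f.duration_ms for f in fix)
            + sum(x.duration_ms for x in sacc)
            + sum(b.duration_ms for b in blinks)
        )
        assert total == pytest.approx(s.duration_ms, abs=1.0)

    def test_no_event_straddles_blink(self, geom):
        s = make_saccade_trial(amplitude_deg=4.0, n_saccades=2, still_ms=300)
        s.valid[450:520] = False
        blinks = detect_blinks(s)
        sacc = detect_saccades(s, DetectionParams(), geom, blinks)
        fix = derive_fixations(s, sacc, blinks)
        for b in blinks:
            for ev in list(sacc) + list(fix):
                # either entirely before or entirely after the blink
                assert ev.offset_ms <= b.onset_ms + 1e-9 or ev.onset_ms >= b.offset_ms - 1e-9


class TestFilterFixations:
    def test_identity_when_all_inside_no_blinks(self, geom, frame):
        s = make_saccade_trial(amplitude_deg=3.0, start=(800.0, 540.0))
        sacc = detect_saccades(s, DetectionParams(), geom)
        fix = derive_fixations(s, sacc, [])
        kept, removed = filter_fixations(fix, frame)
        assert kept == fix
        assert removed == []

    def test_off_image_centroid_removed(self, geom, frame):
        s = make_still_trial(300, x=50.0, y=540.0)  # on grey background, left of image
        fix = derive_fixations(s, [], [])
        kept, removed = filter_fixations(fix, frame)
        assert kept == []
        assert [r for _, r in removed] == ["off_image"]

    def test_blink_adjacent_removed(self, geom, frame):
        s = make_still_trial(600)
        s.valid[250:330] = False
        blinks = detect_blinks(s)
        fix = derive_fixations(s, [], blinks)
        kept, removed = filter_fixations(fix, frame)
        assert kept == []
        assert all(r == "blink_adjacent" for _, r in removed)

    def test_ordinals_preserved_not_renumbered(self, geom, frame):
        s = make_saccade_trial(amplitude_deg=3.0, n_saccades=2, still_ms=250)
        s.valid[40:80] = False  # first fixation becomes blink-adjacent
        blinks = detect_blinks(s)
        sacc = detect_saccades(s, DetectionParams(), geom, blinks)
        fix = derive_fixations(s, sacc, blinks)
        kept, _ = filter_fixations(fix, frame)
        kept_ordinals = [f.ordinal for f in kept]
        assert kept_ordinals == sorted(kept_ordinals)
        assert 1 not in kept_ordinals  # removed ordinal leaves a hole

    def test_idempotent(self, geom, frame):
        s = make_saccade_trial(amplitude_deg=3.0, n_saccades=2, still_ms=250)
        sacc = detect_saccades(s, DetectionParams(), geom)
        fix = derive_fixations(s, sacc, [])
        kept, _ = filter_fixations(fix, frame)
        kept2, removed2 = filter_fixations(kept, frame)
        assert kept2 == kept and removed2 == []


def _mk_saccade(duration_ms=40.0, amplitude=5.0, path=None, ordinal=1):
    return SaccadeEvent(
        onset_ms=0.0,
        offset_ms=duration_ms,
        start_xy_px=(0, 0),
        end_xy_px=(amplitude * PPD, 0),
        amplitude_deg=amplitude,
        path_length_deg=path if path is not None else amplitude,
        peak_velocity_deg_s=200.0,
        ordinal=ordinal,
    )


class TestFilterSaccadeArtifacts:
    def test_straight_compliant_saccade_kept(self):
        # path == amplitude (distance ratio exactly 1.0), duration ratio compliant in s/deg
        s = _mk_saccade(duration_ms=40, amplitude=5.0)
        kept, excluded = filter_saccade_artifacts([s], FilterParams(duration_units="s"))
        assert kept == [s] and excluded == []

    def test_hook_excluded_by_distance_rule(self):
        # constructed curved path: 4x the straight-line amplitude
        s = _mk_saccade(duration_ms=40, amplitude=2.0, path=8.0)
        assert s.path_length_deg / s.amplitude_deg == pytest.approx(4.0)  # oracle recomputation
        assert s.duration_ms / 1000.0 / s.amplitude_deg < 1.5
        kept, excluded = filter_saccade_artifacts([s], FilterParams(duration_units="s"))
        assert kept == []
        ((ev, reason, dur_ratio, dist_ratio),) = excluded
        assert reason == "distance_ratio"
        assert dist_ratio == pytest.approx(4.0)

    def test_duration_rule_in_ms_units(self):
        s = _mk_saccade(duration_ms=40, amplitude=5.0)
        kept, excluded = filter_saccade_artifacts([s], FilterParams(duration_units="ms"))
        # 40 ms / 5 deg = 8 > 1.5: the printed threshold read as ms/deg excludes it
        assert kept == []
        assert excluded[0][1] == "duration_ratio"

    def test_degenerate_zero_amplitude(self):
        s = _mk_saccade(amplitude=0.0, path=1.0)
        kept, excluded = filter_saccade_artifacts([s], FilterParams(duration_units="s"))
        assert kept == [] and excluded[0][1] == "degenerate"

    def test_idempotent(self):
        events = [
            _mk_saccade(40, 5.0),
            _mk_saccade(40, 2.0, path=8.0),
            _mk_saccade(30, 4.0, path=4.4),
        ]
        params = FilterParams(duration_units="s")
        kept, excluded = filter_saccade_artifacts(events, params)
        kept2, excluded2 = filter_saccade_artifacts(kept, params)
        assert kept2 == kept and excluded2 == []
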