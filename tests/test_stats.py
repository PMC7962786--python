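import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gazecraft.simulate import simulate_metric_table
from gazecraft.stats import (
    ConvergenceError,
    ModelSpec,
    chance_level,
    chance_level_display,
    fit_lmm,
    lrt_effect,
    ordinal_profile,
    reverse_rating,
    rmcorr,
    summarize_behavior,
)


class TestReverseRating:
    def test_endpoints(self):
        assert reverse_rating(1) == 6
        assert reverse_rating(6) == 1

    @given(st.integers(min_value=1, max_value=6))
    def test_involution(self, raw):
        assert reverse_rating(reverse_rating(raw)) == raw

    @pytest.mark.parametrize("bad", [0, 7, -3, 100])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            reverse_rating(bad)


class TestChanceLevel:
    def test_six_alternatives_displays_as_016(self):
        assert chance_level(6) == pytest.approx(1 / 6)
        assert chance_level_display(6) == 0.16  # truncated, not rounded

    @pytest.mark.parametrize("n,expected", [(2, 0.5), (4, 0.25), (5, 0.2)])
    def test_simple_cases(self, n, expected):
        assert chance_level(n) == pytest.approx(expected)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            chance_level(1)


class TestFitLmm:
    def test_matches_statsmodels_crossed_vc(self, rng):
        """Independent route: statsmodels MixedLM with crossed variance components."""
        import statsmodels.formula.api as smf

        df = simulate_metric_table(8, 6, rng, task_effects={"date": 0.5}, expertise_effect=0.3)
        mine = fit_lmm(df, "value", ("task", "expertise"))
        md = smf.mixedlm(
            "value ~ C(task) + C(expertise)",
            df,
            groups=np.ones(len(df)),
            vc_formula={"subject": "0 + C(subject)", "image": "0 + C(image)"},
            re_formula="0",
        )
        sm_fit = md.fit(reml=False, method="lbfgs")
        assert mine["loglik"] == pytest.approx(sm_fit.llf, abs=1e-5)
        assert mine["beta"]["intercept"] == pytest.approx(sm_fit.params["Intercept"], abs=1e-5)
        assert mine["beta"]["expertise[nonexpert]"] == pytest.approx(
            sm_fit.params["C(expertise)[T.nonexpert]"], abs=1e-5
        )

    def test_reduced_model_matches_statsmodels(self, rng):
        import statsmodels.formula.api as smf

        df = simulate_metric_table(8, 6, rng)
        mine = fit_lmm(df, "value", ("task",))
        md = smf.mixedlm(
            "value ~ C(task)",
            df,
            groups=np.ones(len(df)),
            vc_formula={"subject": "0 + C(subject)", "image": "0 + C(image)"},
            re_formula="0",
        )
        assert mine["loglik"] == pytest.approx(md.fit(reml=False, method="lbfgs").llf, abs=1e-5)


class TestLrtEffect:
    def test_df_counts_parameters(self, rng):
        df = simulate_metric_table(8, 6, rng, task_effects={"date": 0.3})
        spec = ModelSpec("value", ("task", "expertise"))
        assert lrt_effect(df, spec, "task").df == 2  # 3 task levels
        assert lrt_effect(df, spec, "expertise").df == 1  # 2 groups

    def test_chi2_nonnegative_p_in_unit_interval(self, rng):
        df = simulate_metric_table(6, 6, rng)
        res = lrt_effect(df, ModelSpec("value", ("task", "expertise")), "task")
        assert res.chi2 >= 0
        assert 0 <= res.p <= 1
        assert res.full_loglik >= res.reduced_loglik - 1e-8

    def test_affine_rescaling_invariance(self, rng):
        df = simulate_metric_table(8, 6, rng, task_effects={"medium": 0.6})
        spec = ModelSpec("value", ("task", "expertise"))
        base = lrt_effect(df, spec, "task")
        scaled = df.assign(value=3.7 * df["value"] - 11.0)
        res = lrt_effect(scaled, spec, "task")
        assert res.chi2 == pytest.approx(base.chi2, abs=1e-5)

    def test_strong_effect_detected(self, rng):
        df = simulate_metric_table(20, 9, rng, expertise_effect=1.0, sd_subject=0.2, sd_noise=0.5)
        res = lrt_effect(df, ModelSpec("value", ("task", "expertise")), "expertise")
        assert res.p < 0.001

    def test_unknown_effect_rejected(self, rng):
        df = simulate_metric_table(4, 4, rng)
        with pytest.raises(ValueError):
            lrt_effect(df, ModelSpec("value", ("task",)), "expertise")


class TestRmcorr:
    def test_within_subject_identity_gives_r_one(self):
        rows = []
        for s, offset in enumerate([0.0, 10.0, -3.0]):
            for x in [1.0, 2.0, 3.0, 4.0]:
                rows.append({"subject": f"s{s}", "x": x, "y": x + offset})
        res = rmcorr(pd.DataFrame(rows), "subject", "x", "y")
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_df_formula_study_size(self, rng):
        # 27 subjects x 36 observations -> df = 972 - 27 - 1 = 944
        rows = [
            {"subject": f"s{s}", "x": rng.normal(), "y": rng.normal()}
            for s in range(27)
            for _ in range(36)
        ]
        assert rmcorr(pd.DataFrame(rows), "subject", "x", "y").df == 944

    def test_small_table_matches_residualization_oracle(self, rng):
        rows = []
        for s in range(3):
            for _ in range(4):
                x = rng.normal()
                rows.append({"subject": f"s{s}", "x": x, "y": 0.5 * x + rng.normal(0, 0.8) + s})
        df = pd.DataFrame(rows)
        res = rmcorr(df, "subject", "x", "y")
        # oracle: residualize subject means, correlate residuals, adjust df
        xr = np.concatenate(
            [g["x"].to_numpy() - g["x"].mean() for _, g in df.groupby("subject")]
        )
        yr = np.concatenate(
            [g["y"].to_numpy() - g["y"].mean() for _, g in df.groupby("subject")]
        )
        r_oracle = float(np.corrcoef(xr, yr)[0, 1])
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.df == 12 - 3 - 1

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        rows = []
        for s in range(6):
            for _ in range(8):
                x = rng.normal()
                rows.append({"subject": f"s{s}", "x": x, "y": 0.4 * x + rng.normal() + 2 * s})
        df = pd.DataFrame(rows)
        res = rmcorr(df, "subject", "x", "y")
        pg = pingouin.rm_corr(data=df, x="x", y="y", subject="subject")
        assert res.r == pytest.approx(float(pg["r"].iloc[0]), abs=1e-6)
        assert res.df == int(pg["dof"].iloc[0])
        assert res.p == pytest.approx(float(pg["pval"].iloc[0]), rel=1e-6)

    def test_constant_x_rejected(self):
        df = pd.DataFrame(
            {"subject": ["a"] * 3 + ["b"] * 3, "x": [1.0] * 6, "y": [1.0, 2, 3, 4, 5, 6]}
        )
        with pytest.raises(ValueError, match="variance"):
            rmcorr(df, "subject", "x", "y")


class TestOrdinalProfile:
    def test_all_first_events_give_empty_profile(self):
        events = pd.DataFrame({"ordinal": [1, 1, 1], "value": [380.0, 390.0, 400.0]})
        prof = ordinal_profile(events, "fixation_duration")
        assert prof.ordinals == []
        assert prof.first_event_mean == pytest.approx(390.0)
        assert prof.first_event_n == 3

    def test_matches_brute_force_groupby_on_20_event_fixture(self, rng):
        ordinals = rng.integers(1, 15, 20)
        values = rng.uniform(100, 500, 20)
        events = pd.DataFrame({"ordinal": ordinals, "value": values})
        prof = ordinal_profile(events, "fixation_duration")
        for k, m in zip(prof.ordinals, prof.means):
            expected = values[(ordinals == k)].mean()
            assert m == pytest.approx(expected, rel=1e-12)
        assert all(2 <= k <= 13 for k in prof.ordinals)

    def test_empty_bins_flagged_not_imputed(self):
        events = pd.DataFrame({"ordinal": [2, 3, 5], "value": [1.0, 2.0, 3.0]})
        prof = ordinal_profile(events, "saccade_amplitude")
        assert 4 in prof.empty_ordinals
        assert 4 not in prof.ordinals

    def test_slope_recovery_from_generator(self):
        from gazecraft.simulate import GenerativeParams, StudyDesign, generate_study

        slopes = []
        for seed in range(20):
            design = StudyDesign(n_experts=3, n_nonexperts=3, n_images=6, seed=seed)
            params = GenerativeParams(fixdur_ordinal_slope_ms=5.0, medium_task_dur_delta_ms=0.0)
            trials, truth = generate_study(design, params, render_samples=False)
            rows = [
                {"ordinal": f.ordinal, "value": f.duration_ms}
                for t in trials
                for f in truth.trials[t.trial_id].fixations
            ]
            prof = ordinal_profile(pd.DataFrame(rows), "fixation_duration")
            slopes.append(np.polyfit(prof.ordinals, prof.means, 1)[0])
        assert np.mean(slopes) == pytest.approx(5.0, abs=1.0)


class TestSummarizeBehavior:
    @pytest.fixture
    def fixture_12(self):
        rows = []
        for g, base_conf in (("expert", 5), ("nonexpert", 3)):
            for task in ("movement", "date", "medium"):
                for j in range(2):
                    rows.append(
                        {
                            "group": g,
                            "task": task,
                            "correct": 1 if (g == "expert" or j == 0) else 0,
                            "confidence": base_conf - j,
                            "familiarity": 2 + j,
                        }
                    )
        return pd.DataFrame(rows)

    def test_all_correct_gives_accuracy_one(self, fixture_12):
        df = fixture_12.assign(correct=1)
        summary = summarize_behavior(df)
        assert (summary["accuracy_mean"] == 1.0).all()

    def test_known_cell_means_reproduced(self, fixture_12):
        summary = summarize_behavior(fixture_12)
        cell = summary[(summary.group == "expert") & (summary.task == "date")].iloc[0]
        assert cell["accuracy_mean"] == 1.0
        assert cell["confidence_mean"] == pytest.approx(4.5)  # (5 + 4) / 2
        assert cell["familiarity_mean"] == pytest.approx(2.5)
        non = summary[(summary.group == "nonexpert") & (summary.task == "all")].iloc[0]
        assert non["accuracy_mean"] == pytest.approx(0.5)

    def test_above_chance_flag_is_binomial_test(self, rng):
        from scipy.stats import binomtest

        rows = [
            {"group": "expert", "task": "movement", "correct": int(i < 40), "confidence": 3, "familiarity": 3}
            for i in range(100)
        ]
        summary = summarize_behavior(pd.DataFrame(rows))
        cell = summary[(summary.group == "expert") & (summary.task == "movement")].iloc[0]
        expected = binomtest(40, 100, 1 / 6, alternative="greater").pvalue < 0.05
        assert cell["above_chance"] == expected

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            summarize_behavior(pd.DataFrame({"group": [], "task": []}))
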