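"""Generative model checks: noise-free limits, determinism, parameter recovery."""
import numpy as np
import pandas as pd
import pytest

from ambias import (
    CohortConfig,
    ParadigmDesign,
    ParticipantParams,
    clean_dotprobe,
    make_paradigm_schedule,
    make_rir_schedule,
    score_am_cohort,
    simulate_cohort,
    simulate_dotprobe_rts,
    simulate_rir_responses,
)
from ambias.rir_scoring import clean_rir, compute_interference


def _noise_free(**kw) -> ParticipantParams:
    base = dict(
        participant_id="P1",
        sigma_ms=0.0,
        tau_ms=0.0,
        error_rate=0.0,
        anticipation_rate=0.0,
        omission_rate=0.0,
    )
    base.update(kw)
    return ParticipantParams(**base)


def _raw_ab(trials: pd.DataFrame, block: int) -> float:
    b = trials[trials.block_index == block]
    return b.loc[~b.congruent, "rt_ms"].mean() - b.loc[b.congruent, "rt_ms"].mean()


class TestDotProbeGenerator:
    def test_noise_free_bias_is_exact(self):
        """With zero RT noise, every incongruent-congruent split equals the bias."""
        params = _noise_free(ab_base_ms=30.0, shift_towards_ms=40.0, shift_away_ms=-40.0)
        design = ParadigmDesign(training_order="towards_first")
        trials = simulate_dotprobe_rts(make_paradigm_schedule(design, seed=0), params, seed=1)
        assert _raw_ab(trials, 1) == pytest.approx(30.0, abs=1e-12)
        assert _raw_ab(trials, 3) == pytest.approx(70.0, abs=1e-12)  # +towards shift
        assert _raw_ab(trials, 5) == pytest.approx(30.0, abs=1e-12)  # away shift undoes it

    def test_training_order_controls_which_shift_applies_first(self):
        params = _noise_free(ab_base_ms=0.0, shift_towards_ms=40.0, shift_away_ms=-10.0)
        design = ParadigmDesign(training_order="away_first")
        trials = simulate_dotprobe_rts(make_paradigm_schedule(design, seed=0), params, seed=1)
        assert _raw_ab(trials, 3) == pytest.approx(-10.0, abs=1e-12)
        assert _raw_ab(trials, 5) == pytest.approx(30.0, abs=1e-12)

    def test_malleability_scales_shifts(self):
        params = _noise_free(ab_base_ms=0.0, malleability=0.5, shift_towards_ms=40.0)
        design = ParadigmDesign(training_order="towards_first")
        trials = simulate_dotprobe_rts(make_paradigm_schedule(design, seed=0), params, seed=1)
        assert _raw_ab(trials, 3) == pytest.approx(20.0, abs=1e-12)

    def test_same_seed_reproduces_trials(self):
        params = ParticipantParams("P1", ab_base_ms=12.0)
        sched = make_paradigm_schedule(seed=2)
        a = simulate_dotprobe_rts(sched, params, seed=3)
        b = simulate_dotprobe_rts(sched, params, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestRIRGenerator:
    def test_all_timed_when_rates_zero(self):
        params = _noise_free(rir_base_ms=300.0)
        trials = simulate_rir_responses(make_rir_schedule(seed=0), params, seed=1)
        assert (trials.response_class == "timed").all()
        assert trials.rt_ms.notna().all()

    def test_noise_free_interference_is_exact(self):
        params = _noise_free(rir_base_ms=300.0, interference_ms=50.0)
        trials = simulate_rir_responses(make_rir_schedule(seed=0), params, seed=1)
        assert trials.loc[trials.pain, "rt_ms"].eq(350.0).all()
        assert trials.loc[~trials.pain, "rt_ms"].eq(300.0).all()

    def test_interference_recovered_at_large_n(self):
        """Ten thousand tones: the cleaned pain/no-pain RT delta sits within
        3 Monte-Carlo SEs of the configured 50-ms interference."""
        sched = make_rir_schedule(total_ms=12_000_000, episode_ms=24_000, seed=3)
        params = ParticipantParams("P1", interference_ms=50.0)
        trials = simulate_rir_responses(sched, params, seed=4)
        clean, _ = clean_rir(trials)
        scores = compute_interference(clean, trials)
        pain = clean.loc[clean.pain, "rt_ms"]
        nopain = clean.loc[~clean.pain, "rt_ms"]
        se = np.sqrt(pain.var(ddof=1) / len(pain) + nopain.var(ddof=1) / len(nopain))
        assert abs(scores.delta_rt_ms - 50.0) < 3 * se

    def test_anticipation_and_omission_rates_respected(self):
        params = ParticipantParams(
            "P1", anticipation_rate=0.1, omission_rate=0.2, rir_base_ms=400.0
        )
        sched = make_rir_schedule(total_ms=12_000_000, episode_ms=24_000, seed=5)
        trials = simulate_rir_responses(sched, params, seed=6)
        frac = trials.response_class.value_counts(normalize=True)
        assert frac["anticipation"] == pytest.approx(0.1, abs=0.02)
        assert frac["omission"] == pytest.approx(0.2, abs=0.02)
        anticip = trials[trials.response_class == "anticipation"]
        assert anticip.rt_ms.isna().all()


class TestCohort:
    def test_identical_config_reproduces_dataset(self, small_cohort_config):
        a = simulate_cohort(small_cohort_config)
        b = simulate_cohort(small_cohort_config)
        pd.testing.assert_frame_equal(a.dotprobe, b.dotprobe)
        pd.testing.assert_frame_equal(a.rir, b.rir)
        pd.testing.assert_frame_equal(a.questionnaire_items, b.questionnaire_items)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_counterbalancing_alternates(self, small_cohort_config):
        ds = simulate_cohort(small_cohort_config)
        orders = ds.participants.training_order.tolist()
        assert orders[:4] == ["towards_first", "away_first", "towards_first", "away_first"]
        assert ds.participants.list_order.nunique() == 6

    def test_zero_noise_zero_shift_gives_zero_am(self, small_design):
        cfg = CohortConfig(
            n_participants=4,
            seed=9,
            design=small_design,
            include_rir=False,
            sigma_mean=0.0, sigma_sd=0.0, tau_mean=0.0, tau_sd=0.0,
            ab_base_mean=10.0, ab_base_sd=5.0,
            shift_towards_mean=0.0, shift_towards_sd=0.0,
            shift_away_mean=0.0, shift_away_sd=0.0,
            error_rate_mean=0.0, error_rate_sd=0.0,
        )
        ds = simulate_cohort(cfg)
        clean, _ = clean_dotprobe(ds.dotprobe)
        idx = score_am_cohort(
            clean, ds.participants.set_index("participant_id")["training_order"]
        )
        assert np.allclose(idx.am_overall_ms, 0.0, atol=1e-12)
        assert np.allclose(
            np.sort(idx.ab1_ms), np.sort(ds.truth.ab_base_ms), atol=1e-12
        )

    def test_training_shift_recovery(self):
        """n=200, fixed +-40-ms shifts: mean recovered directional indices sit
        within 3 SEs of the configured truths after the full cleaning pipeline."""
        cfg = CohortConfig(
            n_participants=200, seed=42, include_rir=False,
            malleability_mean=1.0, malleability_sd=0.0,
            shift_towards_mean=40.0, shift_towards_sd=0.0,
            shift_away_mean=-40.0, shift_away_sd=0.0,
        )
        ds = simulate_cohort(cfg)
        clean, _ = clean_dotprobe(ds.dotprobe)
        idx = score_am_cohort(
            clean, ds.participants.set_index("participant_id")["training_order"]
        )
        for col, truth in (("am_towards_ms", 40.0), ("am_away_ms", -40.0)):
            se = idx[col].std(ddof=1) / np.sqrt(len(idx))
            assert abs(idx[col].mean() - truth) < 3 * se, col

    def test_null_outcome_link(self, small_design):
        cfg = CohortConfig(
            n_participants=60, seed=17, design=small_design,
            include_rir=False, beta_disability=0.0, beta_intensity=0.0,
        )
        ds = simulate_cohort(cfg)
        r = np.corrcoef(ds.truth.true_am_overall_ms, ds.truth.disability_target)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(ds.truth))

    def test_questionnaire_scores_match_population(self, small_design):
        from ambias import score_item_table

        cfg = CohortConfig(n_participants=300, seed=31, design=small_design, include_rir=False)
        ds = simulate_cohort(cfg)
        scores = score_item_table(ds.questionnaire_items)
        checks = (
            ("pcs_total", cfg.pcs_mean, cfg.pcs_sd),
            ("dass_anxiety", cfg.dass_anxiety_mean, cfg.dass_anxiety_sd),
            ("dass_depression", cfg.dass_depression_mean, cfg.dass_depression_sd),
            ("attention_to_pain", cfg.attention_to_pain_mean, cfg.attention_to_pain_sd),
        )
        for col, mean, sd in checks:
            # 3 SEs plus a unit of slack for range clipping and item rounding
            tol = 3 * sd / np.sqrt(len(scores)) + 1.0
            assert abs(scores[col].mean() - mean) < tol, col
        assert abs(scores.gcps_intensity.mean() - cfg.intensity_mean) < 4.0
        assert abs(scores.gcps_disability.mean() - cfg.disability_mean) < 4.0
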