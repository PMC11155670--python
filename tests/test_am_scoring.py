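"""Dot-probe cleaning rules and AB/AM index computation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ambias import (
    CleaningRules,
    CohortConfig,
    EmptyCellError,
    ScoringError,
    clean_dotprobe,
    cohort_indices_table,
    compute_ab_index,
    compute_am_indices,
    score_am_cohort,
    simulate_cohort,
)
from conftest import make_dotprobe_trials


class TestCleaning:
    def test_mad_rule_removes_distant_outlier(self):
        """Block {480,490,500,510,520,900}: median 505, raw MAD 15 -> only 900 falls
        outside the deviation bound."""
        trials = make_dotprobe_trials([480, 490, 500, 510, 520, 900], [1, 0, 1, 0, 1, 0])
        clean, report = clean_dotprobe(trials)
        assert sorted(clean.rt_ms) == [480, 490, 500, 510, 520]
        row = report.per_block.iloc[0]
        assert row.n_mad == 1 and row.n_retained == 5

    def test_mad_rule_matches_raw_criterion_too(self):
        trials = make_dotprobe_trials([480, 490, 500, 510, 520, 900], [1, 0, 1, 0, 1, 0])
        clean, _ = clean_dotprobe(trials, CleaningRules(mad_scale=1.0))
        assert sorted(clean.rt_ms) == [480, 490, 500, 510, 520]

    def test_identical_rts_skip_degenerate_mad(self):
        trials = make_dotprobe_trials([500] * 8, [1, 0] * 4)
        clean, report = clean_dotprobe(trials)
        assert len(clean) == 8
        assert report.per_block.iloc[0].mad_skipped

    def test_rt_window_and_incorrect_removed_first(self):
        rts = [150, 500, 510, 520, 530, 2500]
        correct = [True, True, False, True, True, True]
        trials = make_dotprobe_trials(rts, [1, 0, 1, 0, 1, 0], correct)
        clean, report = clean_dotprobe(trials)
        assert sorted(clean.rt_ms) == [500, 520, 530]
        row = report.per_block.iloc[0]
        assert row.n_incorrect == 1 and row.n_rt_window == 2

    def test_low_accuracy_participant_excluded(self):
        correct = [True] * 14 + [False] * 6  # accuracy 0.70
        trials = make_dotprobe_trials([500] * 20, [1, 0] * 10, correct)
        clean, report = clean_dotprobe(trials)
        assert report.excluded == {"P1": "accuracy"}
        assert len(clean) == 0

    def test_mad_applies_only_to_assessment_blocks(self):
        assess = make_dotprobe_trials([480, 490, 500, 510, 520, 900], [1, 0, 1, 0, 1, 0])
        train = make_dotprobe_trials(
            [480, 490, 500, 510, 520, 900], [1] * 6, block_index=2, block_type="training"
        )
        clean, _ = clean_dotprobe(pd.concat([assess, train], ignore_index=True))
        kept_train = clean[clean.block_type == "training"]
        assert sorted(kept_train.rt_ms) == [480, 490, 500, 510, 520, 900]

    def test_empty_cell_flagged(self):
        # both congruent trials incorrect -> cell empties, accuracy still 0.9
        trials = make_dotprobe_trials(
            [500] * 20, [1, 1] + [0] * 18, [False, False] + [True] * 18
        )
        _, report = clean_dotprobe(trials)
        assert ("P1", 1) in report.flagged_empty

    def test_empty_input_raises(self):
        with pytest.raises(ScoringError):
            clean_dotprobe(make_dotprobe_trials([], []))

    def test_accounting_adds_up(self):
        ds = simulate_cohort(CohortConfig(n_participants=6, seed=3, include_rir=False))
        _, report = clean_dotprobe(ds.dotprobe)
        pb = report.per_block
        assert (
            pb.n_incorrect + pb.n_rt_window + pb.n_mad + pb.n_retained == pb.n_input
        ).all()
        assert report.n_input == len(ds.dotprobe)

    def test_non_mad_rules_are_idempotent(self):
        """A second cleaning pass triggers no correctness/window/accuracy removals
        (the data-driven MAD bound is a single-pass rule by construction)."""
        ds = simulate_cohort(CohortConfig(n_participants=6, seed=4, include_rir=False))
        clean, _ = clean_dotprobe(ds.dotprobe)
        _, second = clean_dotprobe(clean)
        pb = second.per_block
        assert pb.n_incorrect.sum() == 0
        assert pb.n_rt_window.sum() == 0
        assert second.excluded == {}


class TestABIndex:
    def test_symmetric_data_gives_zero(self):
        trials = make_dotprobe_trials([500, 500, 500, 500], [1, 1, 0, 0])
        assert compute_ab_index(trials) == 0.0

    def test_hand_computed_example(self):
        trials = make_dotprobe_trials([500, 510, 520, 530, 540, 550], [1, 1, 1, 1, 0, 0])
        assert compute_ab_index(trials) == pytest.approx(30.0)

    def test_empty_cell_raises_named_error(self):
        trials = make_dotprobe_trials([500, 510], [1, 1], block_index=3)
        with pytest.raises(EmptyCellError, match="P1.*3"):
            compute_ab_index(trials)


class TestAMIndices:
    def test_towards_first_assignment(self):
        r = compute_am_indices(0.0, 10.0, -5.0, "towards_first")
        assert (r.am_towards_ms, r.am_away_ms, r.am_overall_ms) == (10.0, -15.0, 25.0)

    def test_away_first_relabels(self):
        r = compute_am_indices(0.0, 10.0, -5.0, "away_first")
        assert (r.am_away_ms, r.am_towards_ms, r.am_overall_ms) == (10.0, -15.0, 25.0)

    def test_null_case(self):
        r = compute_am_indices(0.0, 0.0, 0.0, "towards_first")
        assert (r.am_towards_ms, r.am_away_ms, r.am_overall_ms) == (0.0, 0.0, 0.0)

    def test_unknown_training_order(self):
        with pytest.raises(ScoringError):
            compute_am_indices(0.0, 1.0, 2.0, "mixed")

    @settings(max_examples=200, deadline=None)
    @given(
        ab=st.tuples(*[st.floats(-1e6, 1e6, allow_nan=False)] * 3),
        order=st.sampled_from(["towards_first", "away_first"]),
    )
    def test_overall_is_absolute_sum_of_directional(self, ab, order):
        r = compute_am_indices(*ab, order)
        assert r.am_overall_ms == abs(r.am_towards_ms) + abs(r.am_away_ms)
        assert r.am_overall_ms >= max(abs(r.am_towards_ms), abs(r.am_away_ms))
        assert {r.am_towards_ms, r.am_away_ms} == {ab[1] - ab[0], ab[2] - ab[1]}


class TestCohortScoring:
    def _brute_force_indices(self, trials: pd.DataFrame, rules: CleaningRules, order: str):
        """Independent plain-loop reimplementation of cleaning + scoring."""
        rows = [dict(r._asdict()) for r in trials.itertuples(index=False)]
        kept = [r for r in rows if r["correct"]]
        kept = [r for r in kept if rules.rt_min_ms <= r["rt_ms"] <= rules.rt_max_ms]
        out = []
        for blk in (1, 3, 5):
            cell = [r for r in kept if r["block_index"] == blk]
            rts = sorted(r["rt_ms"] for r in cell)
            med = float(np.median(rts))
            mad = float(np.median([abs(x - med) for x in rts]))
            if mad > 0:
                bound = rules.mad_multiplier * rules.mad_scale * mad
                cell = [r for r in cell if abs(r["rt_ms"] - med) <= bound]
            cong = [r["rt_ms"] for r in cell if r["congruent"]]
            incong = [r["rt_ms"] for r in cell if not r["congruent"]]
            out.append(sum(incong) / len(incong) - sum(cong) / len(cong))
        ab1, ab2, ab3 = out
        first, second = ab2 - ab1, ab3 - ab2
        towards, away = (first, second) if order == "towards_first" else (second, first)
        return ab1, ab2, ab3, towards, away, abs(first) + abs(second)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pipeline_matches_brute_force_oracle(self, seed):
        """On small random datasets the vectorised pipeline equals an
        independently coded loop-based recomputation of every rule."""
        rng = np.random.default_rng(seed)
        frames = []
        for blk in (1, 2, 3, 4, 5):
            is_train = blk in (2, 4)
            n = 10
            frames.append(
                make_dotprobe_trials(
                    rng.integers(150, 2200, n).astype(float),
                    [True] * n if is_train else [True, False] * 5,
                    rng.random(n) > 0.05,
                    block_index=blk,
                    block_type="training" if is_train else "assessment",
                )
            )
        trials = pd.concat(frames, ignore_index=True)
        rules = CleaningRules()
        clean, _ = clean_dotprobe(trials, rules)
        idx = score_am_cohort(clean, {"P1": "towards_first"}).iloc[0]
        expected = self._brute_force_indices(trials, rules, "towards_first")
        got = (
            idx.ab1_ms, idx.ab2_ms, idx.ab3_ms,
            idx.am_towards_ms, idx.am_away_ms, idx.am_overall_ms,
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_missing_training_order_raises(self):
        trials = make_dotprobe_trials([500, 510] * 6, [1, 0] * 6)
        trials["block_index"] = [1, 1, 1, 1, 3, 3, 3, 3, 5, 5, 5, 5]
        clean, _ = clean_dotprobe(trials)
        with pytest.raises(ScoringError):
            score_am_cohort(clean, {})


class TestIndicesTable:
    def _indices(self, values):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(len(values))],
                "ab1_ms": values,
                "am_away_ms": values,
                "am_towards_ms": values,
                "am_overall_ms": values,
            }
        )

    def test_mean_and_sample_sd(self):
        table = cohort_indices_table(self._indices([10.0, 30.0]))
        row = table[table["index"] == "AM_Overall"].iloc[0]
        assert row["mean"] == pytest.approx(20.0)
        assert row["sd"] == pytest.approx(14.142, abs=1e-3)

    def test_identical_participants_zero_sd(self):
        table = cohort_indices_table(self._indices([7.0, 7.0, 7.0]))
        assert (table["sd"] == 0.0).all()

    def test_fewer_than_two_raises(self):
        with pytest.raises(ScoringError):
            cohort_indices_table(self._indices([1.0]))

    def test_row_layout(self):
        table = cohort_indices_table(self._indices([1.0, 2.0]))
        assert table["index"].tolist() == ["AB_Baseline", "AM_Away", "AM_Towards", "AM_Overall"]
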