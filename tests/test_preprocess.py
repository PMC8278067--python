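import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facelearn.preprocess import (
    add_condition_trial_number,
    filter_trials,
    learning_curves,
    reversal_early_late,
    rt_cutoff_ms,
    summarize_behaviour,
)

from conftest import make_records


class TestCutoff:
    def test_paper_components_give_626(self):
        assert rt_cutoff_ms(500, 126) == 626

    def test_additive_identity(self):
        assert rt_cutoff_ms(0, 0) == 0

    def test_general_sum(self):
        assert rt_cutoff_ms(500, 200) == 700

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rt_cutoff_ms(-1, 126)


class TestFilterTrials:
    def test_six_record_fixture(self):
        rec = make_records(
            [600.0, 626.0, 700.0, 5100.0, np.nan, 4999.0],
            responses=["smile", "smile", "smile", "smile", None, "smile"],
        )
        kept, report = filter_trials(rec)
        # strict boundaries: 626 and 4999 retained; 600 fast, 5100 slow, NaN none
        assert sorted(kept["rt_ms"]) == [626.0, 700.0, 4999.0]
        assert report.n_fast_excluded == 1
        assert report.n_slow_excluded == 1
        assert report.n_no_response_excluded == 1
        assert report.n_retained == 3

    def test_all_clean_retained(self):
        rec = make_records([1000.0] * 10)
        kept, report = filter_trials(rec)
        assert len(kept) == 10
        assert report.n_fast_excluded == report.n_slow_excluded == 0
        assert report.n_no_response_excluded == 0

    def test_empty_input(self):
        kept, report = filter_trials(make_records([]))
        assert len(kept) == 0 and report.n_input == 0 and report.n_retained == 0

    def test_idempotent(self):
        rec = make_records([100.0, 700.0, 900.0, 6000.0, np.nan])
        kept, _ = filter_trials(rec)
        kept2, report2 = filter_trials(kept)
        assert kept2.equals(kept)
        assert report2.n_retained == report2.n_input

    def test_injected_artifact_counts_match_labels(self, labelled_dataset):
        ds = labelled_dataset
        kept, report = filter_trials(ds.records)
        labels = ds.artifact_labels
        assert report.n_no_response_excluded == (labels == "no_response").sum()
        assert report.n_fast_excluded == (labels == "fast").sum()
        assert report.n_slow_excluded == (labels == "slow").sum()
        assert report.n_retained == (labels == "clean").sum()

    @given(
        rts=st.lists(
            st.one_of(st.floats(min_value=0, max_value=10000), st.just(np.nan)),
            max_size=60,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_report_partitions_input(self, rts):
        responses = ["smile" if r == r else None for r in rts]
        kept, report = filter_trials(make_records(rts, responses=responses))
        assert report.n_input == len(rts)
        assert len(kept) == report.n_retained
        assert (
            report.n_fast_excluded
            + report.n_slow_excluded
            + report.n_no_response_excluded
            + report.n_retained
            == report.n_input
        )


class TestSummaries:
    def test_all_correct_gives_cr_one(self, clean_rl_dataset):
        rec = clean_rl_dataset.records.copy()
        rec["correct"] = 1
        summary = summarize_behaviour(rec)
        filled = summary[summary["n"] > 0]
        assert (filled["mean_cr"] == 1.0).all()

    def test_alternating_gives_half(self):
        rec = make_records([1000.0] * 8, correct=[0, 1] * 4)
        summary = summarize_behaviour(rec)
        cell = summary[(summary.condition == "congruent") & (summary.n > 0)]
        assert cell["mean_cr"].iloc[0] == 0.5

    def test_empty_cell_marked_unavailable(self):
        rec = make_records([1000.0] * 4)  # only congruent smile cells
        summary = summarize_behaviour(rec)
        empty = summary[summary["n"] == 0]
        assert len(empty) == 3
        assert empty["mean_cr"].isna().all()

    def test_cell_ns_sum_to_records(self, clean_rl_dataset):
        rec = clean_rl_dataset.records
        assert summarize_behaviour(rec)["n"].sum() == len(rec)

    def test_copy_bias_population_favours_congruent(self, clean_rl_dataset):
        # generator truth has zeta_pop > 0
        summary = summarize_behaviour(clean_rl_dataset.records)
        by_cond = summary.groupby("condition")["mean_cr"].mean()
        assert by_cond["congruent"] > by_cond["incongruent"]


class TestConditionTrialNumber:
    def test_numbering_is_per_clip_per_block(self, clean_rl_dataset):
        rec = add_condition_trial_number(clean_rl_dataset.records)
        counts = rec.groupby(
            ["participant_id", "block", "interactant", "target_expression"]
        )["cond_trial"].max()
        assert (counts == 12).all()
        assert rec["cond_trial_overall"].max() == 24

    def test_learning_curves_shape(self, clean_rl_dataset):
        curves = learning_curves(clean_rl_dataset.records)
        assert set(curves["block"]) == {1, 2}
        assert curves["cond_trial"].max() == 12


class TestReversalEarlyLate:
    def test_identical_blocks_degenerate(self):
        # same data in both blocks: zero difference, flagged, p = 1
        rows = []
        for pid in ("p1", "p2", "p3"):
            for block in (1, 2):
                for i in range(12):
                    rows.append(
                        {
                            "participant_id": pid,
                            "trial_index": i + 1 + (block - 1) * 12,
                            "block": block,
                            "interactant": 1,
                            "target_expression": "smile",
                            "condition": "congruent",
                            "correct_response": "smile",
                            "response": "smile",
                            "rt_ms": 1000.0,
                            "shock": 0,
                            "correct": i % 2,
                        }
                    )
        table = reversal_early_late(pd.DataFrame(rows))
        row = table[(table.condition == "congruent") & (table.window == "first")].iloc[0]
        assert row["mean_diff"] == pytest.approx(0.0)
        assert row["zero_variance"]
        assert row["p"] == pytest.approx(1.0)

    def test_block_difference_of_one(self):
        rows = []
        for pid in ("p1", "p2", "p3", "p4"):
            for block in (1, 2):
                for i in range(12):
                    rows.append(
                        {
                            "participant_id": pid,
                            "trial_index": i + 1 + (block - 1) * 12,
                            "block": block,
                            "interactant": 1,
                            "target_expression": "smile",
                            "condition": "congruent",
                            "correct_response": "smile",
                            "response": "smile",
                            "rt_ms": 1000.0,
                            "shock": 0,
                            "correct": 1 if block == 1 else 0,
                        }
                    )
        table = reversal_early_late(pd.DataFrame(rows))
        row = table[(table.condition == "congruent") & (table.window == "first")].iloc[0]
        assert row["mean_diff"] == pytest.approx(1.0)

    def test_t_statistic_matches_textbook_formula(self):
        # 5-participant fixture; oracle: t = mean(d) / (sd(d) / sqrt(n))
        b1 = np.array([1.0, 1.0, 2 / 3, 1.0, 2 / 3])
        b2 = np.array([2 / 3, 1 / 3, 1 / 3, 2 / 3, 1 / 3])
        rows = []
        for p, (v1, v2) in enumerate(zip(b1, b2)):
            for block, v in ((1, v1), (2, v2)):
                n_correct = round(v * 3)
                for i in range(3):
                    rows.append(
                        {
                            "participant_id": f"p{p}",
                            "trial_index": i + 1 + (block - 1) * 3,
                            "block": block,
                            "interactant": 1,
                            "target_expression": "smile",
                            "condition": "congruent",
                            "correct_response": "smile",
                            "response": "smile",
                            "rt_ms": 1000.0,
                            "shock": 0,
                            "correct": 1 if i < n_correct else 0,
                        }
                    )
        table = reversal_early_late(pd.DataFrame(rows), window=3)
        row = table[(table.condition == "congruent") & (table.window == "first")].iloc[0]
        d = b1 - b2
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert row["t"] == pytest.approx(t_oracle, rel=1e-10)
        assert row["df"] == 4
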