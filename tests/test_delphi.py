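"""Consensus statistics, decision rules, round orchestration, panel summary."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrf import (
    LikertMatrix,
    decide,
    item_stats,
    panel_summary,
    round_half_away_from_zero,
    run_round,
)

from conftest import oracle_median, oracle_quartile, oracle_verdict


def all_response_multisets(max_n):
    """Every multiset of Likert responses with 1 <= n <= max_n.

    Statistics and verdicts are order-invariant, so multisets cover the full
    integer response space."""
    for n in range(1, max_n + 1):
        yield from itertools.combinations_with_replacement([1, 2, 3, 4, 5], n)


class TestItemStats:
    def test_unanimous_strong_agreement(self):
        stats = item_stats([5] * 22)
        assert stats.agreement_pct == 100.0
        assert stats.median == 5 and stats.p25 == 5 and stats.iqr == 0

    def test_worked_example_seven_raters(self):
        """[2,3,4,4,4,5,5]: agreement 5/7, median 4, P25 at position
        (7+1)/4 = 2 -> the 2nd sorted value, 3."""
        stats = item_stats([2, 3, 4, 4, 4, 5, 5])
        assert stats.agreement_pct == pytest.approx(100 * 5 / 7)
        assert round_half_away_from_zero(stats.agreement_pct) == 71.4
        assert stats.median == 4 and stats.p25 == 3 and stats.p75 == 5

    def test_seventeen_of_twentytwo_agree(self):
        """17/22 agreeing reports as 77.3% — 'approximately three-quarters'."""
        responses = [5] * 9 + [4] * 8 + [3] * 3 + [2] * 2
        stats = item_stats(responses)
        assert stats.n_responses == 22
        assert round_half_away_from_zero(stats.agreement_pct) == 77.3

    def test_missing_excluded_from_numerator_and_denominator(self):
        with_missing = item_stats([4, 4, None, np.nan, 2])
        assert with_missing.n_responses == 3
        assert with_missing.agreement_pct == pytest.approx(100 * 2 / 3)
        assert with_missing.agreement_pct == item_stats([4, 4, 2]).agreement_pct

    def test_all_missing_is_error_naming_item(self):
        with pytest.raises(ValueError, match="item_007"):
            item_stats([None, np.nan], item_id="item_007")

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError):
            item_stats([4, 6])

    def test_quantiles_match_hand_oracle(self):
        for combo in all_response_multisets(8):
            stats = item_stats(combo)
            assert stats.median == pytest.approx(oracle_median(combo))
            assert stats.p25 == pytest.approx(oracle_quartile(combo, 0.25))
            assert stats.p75 == pytest.approx(oracle_quartile(combo, 0.75))
            assert stats.p25 <= stats.median <= stats.p75

    def test_alternative_quantile_method(self):
        # linear interpolation on [2,3,4,4,4,5,5] puts P25 at 3.5, not 3
        assert item_stats([2, 3, 4, 4, 4, 5, 5], "linear").p25 == 3.5

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="quantile method"):
            item_stats([4, 4], "spline")


class TestDecide:
    def _stats(self, median, p25):
        from mrf.delphi import ItemStats
        return ItemStats(n_responses=22, agreement_pct=80.0,
                         median=median, p25=p25, p75=5.0)

    @pytest.mark.parametrize(
        "median, p25, final, verdict",
        [
            (5, 4.25, False, "retain"),
            (5, 4.25, True, "retain"),
            (4, 4.0, True, "retain"),
            (3, 2.0, False, "exclude"),
            (3, 2.0, True, "exclude"),
            (4, 3.8, False, "modify"),
            # the published final-round edge: median 4 but P25 = 3.8 -> out
            (4, 3.8, True, "exclude"),
            (3.5, 3.0, False, "modify"),  # even-n median between 3 and 4
            (3.5, 3.0, True, "exclude"),
        ],
    )
    def test_rule_clauses(self, median, p25, final, verdict):
        decision = decide(self._stats(median, p25), final_round=final)
        assert decision.verdict == verdict
        assert decision.rule_trace.startswith(verdict)

    def test_half_median_retains_with_consensus(self):
        decision = decide(self._stats(4.5, 4.0), final_round=True)
        assert decision.verdict == "retain"
        assert "non-integer median" in decision.rule_trace

    def test_exhaustive_enumeration_matches_oracle(self):
        """Every integer response multiset up to n=8, both round types,
        against the brute-force rule oracle."""
        for combo in all_response_multisets(8):
            stats = item_stats(combo)
            for final in (False, True):
                assert (
                    decide(stats, final_round=final).verdict
                    == oracle_verdict(combo, final)
                ), combo

    def test_p25_rule_vs_75pct_gloss_boundary(self):
        """The P25 >= 4 rule is described as 'at least 75% agreeing or
        strongly agreeing'. Under weighted-average interpolation the two
        tests disagree on 83 of the 1286 response multisets up to n=8 —
        always in the same direction: agreement reaches 75% but P25 < 4,
        so the operative P25 rule is strictly stricter."""
        disagreements = []
        for combo in all_response_multisets(8):
            stats = item_stats(combo)
            if (stats.p25 >= 4) != (stats.agreement_pct >= 75):
                disagreements.append(combo)
                assert stats.agreement_pct >= 75 and stats.p25 < 4
        assert len(disagreements) == 83
        assert (3, 4, 4, 4) in disagreements  # P25 = 3.25, agreement 75%
        assert (2, 4, 4, 4, 4) in disagreements  # P25 = 3.0, agreement 80%

    @given(st.lists(st.integers(1, 5), min_size=2, max_size=12),
           st.integers(0, 11), st.booleans())
    @settings(max_examples=200, deadline=None)
    def test_raising_a_response_never_demotes_retain(self, responses, idx, final):
        """Monotonicity: raising one response cannot flip retain to
        modify/exclude."""
        before = decide(item_stats(responses), final_round=final)
        raised = list(responses)
        raised[idx % len(raised)] = 5
        after = decide(item_stats(raised), final_round=final)
        if before.verdict == "retain":
            assert after.verdict == "retain"


def _matrix(rows: dict) -> LikertMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"p{i + 1}" for i in range(df.shape[1])]
    return LikertMatrix(df)


class TestRunRound:
    def test_unanimous_round_retains_everything(self):
        matrix = _matrix({"a": [5] * 6, "b": [5] * 6})
        result = run_round(matrix, 1, 3, new_items=["c_suggested"])
        assert result.retained == ["a", "b"] and result.excluded == []
        assert result.carried_forward == ["c_suggested"]

    def test_final_round_excludes_sub_consensus_item(self):
        """Median 4 with P25 3.8 in round 3 of 3 -> excluded, nothing carried."""
        # 22 integer responses whose P25 under (n+1)p interpolation is 3.75 < 4
        responses = [3] * 5 + [4] * 9 + [5] * 8
        stats = item_stats(responses)
        assert stats.median == 4 and stats.p25 < 4
        result = run_round(_matrix({"dopaminergics": responses}), 3, 3)
        assert result.excluded == ["dopaminergics"]
        assert result.carried_forward == []

    def test_same_item_modified_in_round2_not_final(self):
        responses = [3] * 5 + [4] * 9 + [5] * 8
        result = run_round(_matrix({"dopaminergics": responses}), 2, 3)
        assert result.carried_forward == ["dopaminergics"]

    def test_round_conservation(self):
        matrix = _matrix({
            "keep": [4, 4, 5, 5, 5],
            "drop": [1, 2, 3, 3, 3],
            "revise": [3, 3, 4, 4, 5],
        })
        result = run_round(matrix, 1, 3)
        decided = (set(result.retained) | set(result.excluded)
                   | set(result.carried_forward))
        assert decided == set(matrix.items)
        assert not set(result.retained) & set(result.carried_forward)
        assert not set(result.excluded) & set(result.carried_forward)

    def test_three_round_synthetic_replication_ends_with_19(self):
        """A three-round campaign built to satisfy the rules ends with 19
        retained items, mirroring the published campaign's final tool size."""
        unanimous = [5] * 22
        divided = [3] * 6 + [4] * 8 + [5] * 8      # median 4, P25 < 4
        rejected = [1] * 8 + [2] * 8 + [3] * 6     # median <= 3
        round1 = {f"item{i:02d}": unanimous for i in range(16)}
        round1["m1"] = divided
        round1["m2"] = divided
        round1["x1"] = rejected
        r1 = run_round(_matrix(round1), 1, 3, new_items=["new1", "new2"])
        assert len(r1.retained) == 16
        assert sorted(r1.carried_forward) == ["m1", "m2", "new1", "new2"]

        round2 = {"m1": unanimous, "m2": divided, "new1": unanimous,
                  "new2": divided}
        r2 = run_round(_matrix(round2), 2, 3, closed_items=r1.retained + r1.excluded)
        assert sorted(r2.retained) == ["m1", "new1"]

        round3 = {"m2": unanimous, "new2": divided}
        r3 = run_round(_matrix(round3), 3, 3,
                       closed_items=r1.retained + r1.excluded + r2.retained)
        assert r3.retained == ["m2"] and r3.excluded == ["new2"]
        assert r3.carried_forward == []
        total_retained = len(r1.retained) + len(r2.retained) + len(r3.retained)
        assert total_retained == 19

    def test_reopened_item_is_error(self):
        matrix = _matrix({"a": [5] * 5})
        with pytest.raises(ValueError, match="prior round"):
            run_round(matrix, 2, 3, closed_items=["a"])

    def test_feedback_shapes(self):
        matrix = _matrix({"a": [5, 4, 3], "b": [2, 2, 4]})
        result = run_round(matrix, 1, 3)
        assert list(result.group_feedback.index) == ["a", "b"]
        assert set(result.individual_feedback) == {"p1", "p2", "p3"}
        own = result.individual_feedback["p1"]["own_response"]
        assert own["a"] == 5 and own["b"] == 2


class TestLikertMatrixIO:
    def test_wide_csv_round_trip(self, tmp_path):
        matrix = _matrix({"a": [5, 4, None], "b": [2, 2, 4]})
        path = tmp_path / "wide.csv"
        matrix.to_csv(path)
        loaded = LikertMatrix.from_csv(path)
        pd.testing.assert_frame_equal(
            loaded.responses, matrix.responses, check_names=False)

    def test_long_csv(self, tmp_path):
        path = tmp_path / "long.csv"
        path.write_text(
            "item_id,panellist_id,response\n"
            "a,p1,5\na,p2,4\nb,p1,3\nb,p2,\n"
        )
        loaded = LikertMatrix.from_csv(path)
        assert loaded.item_responses("b").tolist() == [3.0]

    def test_out_of_scale_matrix_rejected(self):
        with pytest.raises(ValueError, match="1..5"):
            _matrix({"a": [0, 5]})


class TestPanelSummary:
    def test_published_panel_percentages(self):
        """Printed counts out of the 22-member panel reproduce the printed
        percentages under one-decimal half-away-from-zero rounding."""
        table = panel_summary(
            {"United Kingdom": 7, "Canada": 5, "USA": 2, "Ireland": 2,
             "Australia": 1, "Belgium": 1, "Sweden": 1, "Malaysia": 1,
             "Turkey": 1, "France": 1}
        )
        assert table.loc["United Kingdom", "percentage"] == 31.8
        assert table.loc["Canada", "percentage"] == 22.7
        assert table.loc["USA", "percentage"] == 9.1
        assert table.loc["Australia", "percentage"] == 4.5
        assert table["count"].sum() == 22

    def test_experience_and_education_rows(self):
        exp = panel_summary(
            {"1-5 years": 2, "6-10 years": 4, "11-15 years": 2,
             "More than 15 years": 14})
        assert exp.loc["More than 15 years", "percentage"] == 63.6
        edu = panel_summary({"PhD": 11}, total=22)
        assert edu.loc["PhD", "percentage"] == 50.0

    def test_zero_count_and_zero_total(self):
        assert panel_summary({"X": 0}, total=22).loc["X", "percentage"] == 0.0
        with pytest.raises(ValueError, match="total"):
            panel_summary({"X": 0})

    def test_rounding_half_away_from_zero(self):
        # 5/22 = 22.727... -> 22.7 ; half cases go away from zero
        assert round_half_away_from_zero(22.727272) == 22.7
        assert round_half_away_from_zero(0.25, 1) == 0.3
        assert round_half_away_from_zero(4.545454) == 4.5
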