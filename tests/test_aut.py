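"""AUT scoring: normalization, the four indices, inter-rater reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ebrdt import (ResponseSimConfig, compute_icc, normalize_response,
                   score_fb_originality, score_flexibility_fluency,
                   score_participants, score_rb_originality,
                   simulate_aut_responses)


def _table(rows):
    return pd.DataFrame(rows, columns=["participant_id", "object_id",
                                       "raw_text", "category_label",
                                       "rater1_score", "rater2_score"])


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [
        ("used for a vase", "vase"),
        ("Vases", "vase"),
        ("vase", "vase"),
        ("Used as a doorstop!", "doorstop"),
        ("the hammers", "hammer"),
        ("glasses", "glass"),
        ("  paper   weight ", "paper weight"),
    ])
    def test_examples(self, raw, expected):
        assert normalize_response(raw) == expected

    @settings(derandomize=True, database=None, max_examples=200)
    @given(st.text(max_size=40))
    def test_idempotent_and_deterministic(self, s):
        once = normalize_response(s)
        assert normalize_response(once) == once
        assert normalize_response(s) == once

    def test_empty_after_cleaning_is_invalid(self):
        assert normalize_response("used for") == ""
        assert normalize_response("   ") == ""


class TestFBOriginality:
    def test_worked_example_eight_of_twenty(self):
        # 8 identical responses among 20 for one object -> infrequency 0.60
        rows = [(f"P{i}", "brick", "vase", "c1", 3, 3) for i in range(8)]
        rows += [(f"P{i+8}", "brick", f"unique {i}", "c1", 3, 3)
                 for i in range(12)]
        infreq, _ = score_fb_originality(_table(rows))
        assert infreq.iloc[0] == pytest.approx(0.60)

    def test_unique_response_closed_form(self):
        n = 25
        rows = [(f"P{i}", "hat", f"resp {i}", "c1", 3, 3) for i in range(n)]
        infreq, _ = score_fb_originality(_table(rows))
        assert np.allclose(infreq, 1 - 1 / n)

    def test_all_identical_scores_zero(self):
        rows = [(f"P{i}", "hat", "bucket", "c1", 3, 3) for i in range(20)]
        infreq, per = score_fb_originality(_table(rows))
        assert np.allclose(infreq, 0.0)
        assert np.allclose(per, 0.0)

    def test_record_order_invariance(self, responses):
        _, a = score_fb_originality(responses)
        shuffled = responses.sample(frac=1.0, random_state=1)
        _, b = score_fb_originality(shuffled)
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_scores_in_unit_interval(self, responses):
        infreq, per = score_fb_originality(responses)
        assert ((infreq >= 0) & (infreq < 1)).all()
        assert ((per >= 0) & (per < 1)).all()


class TestFlexibilityFluency:
    def test_three_categories_each_object(self):
        rows = [("P1", f"obj{o}", f"r{o}{k}", f"cat{k}", 3, 3)
                for o in range(5) for k in range(3)]
        ff = score_flexibility_fluency(_table(rows))
        assert ff.loc["P1", "flexibility"] == 3.0
        assert ff.loc["P1", "fluency"] == 15

    def test_single_category_floor(self):
        rows = [("P1", f"obj{o}", f"r{o}{k}", "same", 3, 3)
                for o in range(5) for k in range(4)]
        ff = score_flexibility_fluency(_table(rows))
        assert ff.loc["P1", "flexibility"] == 1.0

    def test_invalid_responses_excluded_from_fluency(self):
        rows = [("P1", "obj", f"resp {k}", "c", 3, 3) for k in range(12)]
        rows += [("P1", "obj", "used for", "c", 3, 3),
                 ("P1", "obj", "", "c", 3, 3)]
        ff = score_flexibility_fluency(_table(rows))
        assert ff.loc["P1", "fluency"] == 12

    def test_duplicate_in_used_category_leaves_flexibility_unchanged(self):
        rows = [("P1", "obj", f"r{k}", f"cat{k % 3}", 3, 3) for k in range(6)]
        base = score_flexibility_fluency(_table(rows))
        rows.append(("P1", "obj", "another", "cat0", 3, 3))
        more = score_flexibility_fluency(_table(rows))
        assert base.loc["P1", "flexibility"] == more.loc["P1", "flexibility"]

    def test_exclusion_accounting(self, responses):
        df = responses.copy()
        df.loc[df.index[:7], "raw_text"] = "used for"   # make 7 rows invalid
        ff = score_flexibility_fluency(df)
        assert ff["fluency"].sum() + 7 == len(df)

    def test_zero_valid_participant_warns(self):
        rows = [("P1", "obj", "used for", "c", 3, 3),
                ("P2", "obj", "vase", "c", 3, 3)]
        with pytest.warns(UserWarning, match="P1"):
            ff = score_flexibility_fluency(_table(rows))
        assert list(ff.index) == ["P2"]


class TestRBOriginality:
    def test_idea_mean_of_two_judges(self):
        rows = [("P1", "obj", "vase", "c", 3, 5)]
        assert score_rb_originality(_table(rows)).loc["P1"] == 4.0

    @pytest.mark.parametrize("ratings,expected", [
        ([(1, 1)] * 4, 1.0),
        ([(2, 2), (4, 4), (3, 3)], 3.0),
    ])
    def test_participant_mean(self, ratings, expected):
        rows = [("P1", "obj", f"r{i}", "c", a, b)
                for i, (a, b) in enumerate(ratings)]
        assert score_rb_originality(_table(rows)).loc["P1"] == expected

    def test_rater_exchangeability(self, responses):
        a = score_rb_originality(responses)
        swapped = responses.rename(columns={"rater1_score": "rater2_score",
                                            "rater2_score": "rater1_score"})
        pd.testing.assert_series_equal(a, score_rb_originality(swapped))

    def test_consensus_override(self):
        rows = [("P1", "obj", "vase", "c", 1, 5)]
        df = _table(rows)
        df["consensus_score"] = [2.0]
        assert score_rb_originality(df).loc["P1"] == 2.0

    def test_missing_rating_excluded_with_warning(self):
        df = _table([("P1", "obj", "vase", "c", 3, 3),
                     ("P1", "obj", "boat", "c", np.nan, 3)])
        with pytest.warns(UserWarning, match="missing"):
            out = score_rb_originality(df)
        assert out.loc["P1"] == 3.0

    def test_scores_in_rating_scale(self, responses):
        out = score_rb_originality(responses)
        assert out.between(1.0, 5.0).all()


class TestICC:
    def test_identical_raters_give_one(self):
        rng = np.random.default_rng(0)
        col = rng.normal(3, 1, 40)
        res = compute_icc(np.column_stack([col, col]))
        assert res.icc == pytest.approx(1.0, abs=1e-9)
        assert "2,k" in res.variant

    def test_shuffled_rater_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.normal(3, 1, 1000)
        b = rng.permutation(a)
        assert abs(compute_icc(np.column_stack([a, b])).icc) < 0.1

    def test_calibrated_simulation_round_trip(self, responses):
        res = compute_icc(responses[["rater1_score", "rater2_score"]].to_numpy())
        assert res.icc == pytest.approx(0.88, abs=0.05)

    def test_zero_variance_reported_undefined(self):
        res = compute_icc(np.full((10, 2), 3.0))
        assert np.isnan(res.icc)
        assert "undefined" in res.note

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            compute_icc(np.ones((2, 2)))


def test_score_participants_joins_all_indices(responses, participants):
    sebr = participants.set_index("participant_id")["sebr"]
    scores = score_participants(responses, sebr=sebr)
    assert list(scores.columns) == ["sebr", "fluency", "flexibility",
                                    "fb_originality", "rb_originality"]
    assert len(scores) == participants["participant_id"].nunique()
    assert scores.notna().all().all()
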