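"""Unit and property tests for the HVFL argument-advantage score."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moralargs.exceptions import InsufficientDataError, ValidationError
from moralargs.scoring import (
    DUMMY_COLUMNS,
    HVFL_KINDS,
    ideology_split_reliability,
    item_advantage,
    participant_advantage,
    score_items,
    score_judgments,
    threshold_filter,
)

from conftest import judgment_row


class TestParticipantAdvantage:
    def test_worked_example_quarter(self):
        """Endorsing fairness+harm for yes and liberty for no gives
        1/2 - 1/4 = 0.25 exactly."""
        j = judgment_row(yes_fairness=1, yes_harm=1, no_liberty=1)
        assert participant_advantage(j) == 0.25

    @pytest.mark.parametrize(
        "ones, expected",
        [
            ({}, 0.0),
            ({f"yes_{k}": 1 for k in HVFL_KINDS}, 1.0),
            ({f"no_{k}": 1 for k in HVFL_KINDS}, -1.0),
            (
                {f"yes_{k}": 1 for k in HVFL_KINDS}
                | {f"no_{k}": 1 for k in HVFL_KINDS},
                0.0,
            ),
        ],
    )
    def test_range_endpoints(self, ones, expected):
        assert participant_advantage(judgment_row(**ones)) == expected

    def test_colon_dialect_accepted(self):
        j = {f"{s}:{k}": 0 for s in ("yes", "no") for k in
             ("harm", "violence", "fairness", "liberty")}
        j["yes:harm"] = 1
        assert participant_advantage(j) == 0.25

    def test_missing_dummy_names_field(self):
        j = judgment_row()
        del j["no_liberty"]
        with pytest.raises(ValidationError, match="side=no kind=liberty"):
            participant_advantage(j)

    def test_non_binary_rejected(self):
        j = judgment_row()
        j["yes_harm"] = 0.5
        with pytest.raises(ValidationError, match="non-binary"):
            participant_advantage(j)

    def test_non_hvfl_kinds_never_enter_score(self):
        base = judgment_row(yes_harm=1)
        loaded = judgment_row(
            yes_harm=1, yes_purity=1, yes_loyalty=1, no_authority=1
        )
        assert participant_advantage(base) == participant_advantage(loaded)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=14, max_size=14))
    def test_bounded_and_antisymmetric(self, bits):
        j = dict(zip(DUMMY_COLUMNS, bits))
        score = participant_advantage(j)
        assert -1.0 <= score <= 1.0
        swapped = {
            c: j[c.replace("yes_", "no_") if c.startswith("yes_") else
                 c.replace("no_", "yes_")]
            for c in DUMMY_COLUMNS
        }
        assert participant_advantage(swapped) == -score


class TestItemAdvantage:
    def test_two_point_mean_and_se(self):
        """Scores {0.25, -0.25}: mean 0, SE = SD/sqrt(2) = 0.25."""
        df = pd.DataFrame(
            [
                judgment_row(yes_fairness=1, yes_harm=1, no_liberty=1),
                judgment_row(no_fairness=1, no_harm=1, yes_liberty=1),
            ]
        )
        est = item_advantage(df, item_id="x")
        assert est.mean == 0.0
        assert est.se == pytest.approx(0.25, abs=1e-12)
        assert est.n_judges == 2

    def test_single_judge_se_missing(self):
        df = pd.DataFrame([judgment_row(yes_harm=1)])
        est = item_advantage(df, item_id="x")
        assert est.mean == 0.25
        assert math.isnan(est.se)

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientDataError):
            item_advantage(pd.DataFrame(columns=list(DUMMY_COLUMNS)))

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            rng.integers(0, 2, size=(60, 14)), columns=list(DUMMY_COLUMNS)
        )
        est = item_advantage(df, item_id="x")
        brute = np.mean(
            [participant_advantage(r) for r in df.to_dict("records")]
        )
        assert est.mean == pytest.approx(brute, abs=1e-12)

    def test_other_ideology_in_mean_but_no_submean(self):
        df = pd.DataFrame(
            [
                judgment_row(yes_harm=1) | {"ideology": "liberal"},
                judgment_row(yes_harm=1, yes_fairness=1) | {"ideology": "other"},
            ]
        )
        est = item_advantage(df, item_id="x")
        assert est.mean == pytest.approx((0.25 + 0.5) / 2)
        assert est.mean_liberal_based == 0.25
        assert math.isnan(est.mean_conservative_based)


class TestReliability:
    def _frame(self, lib, con):
        return pd.DataFrame(
            {
                "item_id": range(len(lib)),
                "advantage_liberal": lib,
                "advantage_conservative": con,
            }
        )

    def test_identical_submeans_r_one(self):
        lib = [0.1, 0.2, -0.1, 0.05]
        res = ideology_split_reliability(self._frame(lib, lib))
        assert res.r == pytest.approx(1.0)

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            ideology_split_reliability(self._frame([0.1, np.nan], [0.2, 0.3]))

    def test_independent_noise_stays_small(self):
        """With no shared signal, |r| across 100 items rarely exceeds 0.3."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            res = ideology_split_reliability(
                self._frame(rng.normal(size=100), rng.normal(size=100))
            )
            hits += abs(res.r) < 0.3
        assert hits / n_rep >= 0.95

    def test_attenuation_formula(self):
        """Truth SD 0.16 + independent N(0, 0.05) noise on both sides
        attenuates r to sigma^2/(sigma^2 + tau^2)."""
        rng = np.random.default_rng(8)
        truth = rng.normal(0, 0.16, size=4000)
        res = ideology_split_reliability(
            self._frame(
                truth + rng.normal(0, 0.05, 4000),
                truth + rng.normal(0, 0.05, 4000),
            )
        )
        expected = 0.16**2 / (0.16**2 + 0.05**2)
        assert res.r == pytest.approx(expected, abs=0.02)


class TestThresholdFilter:
    def _estimates(self, means):
        return pd.DataFrame(
            {"item_id": range(len(means)), "advantage": means}
        )

    def test_keeps_both_signs(self):
        kept, dropped = threshold_filter(self._estimates([0.28, 0.05, -0.24]))
        assert sorted(kept["advantage"]) == [-0.24, 0.28]
        assert list(dropped["advantage"]) == [0.05]
        assert set(kept["advantaged_sign"]) == {1, -1}

    def test_boundary_inclusive(self):
        kept, _ = threshold_filter(self._estimates([0.1]))
        assert len(kept) == 1

    def test_all_below_warns_empty(self):
        with pytest.warns(UserWarning, match="kept set is empty"):
            kept, dropped = threshold_filter(self._estimates([0.0, 0.0]))
        assert len(kept) == 0 and len(dropped) == 2


def test_score_items_table_roundtrip():
    rng = np.random.default_rng(9)
    df = pd.DataFrame(
        rng.integers(0, 2, size=(40, 14)), columns=list(DUMMY_COLUMNS)
    )
    df["item_id"] = np.repeat(["a", "b"], 20)
    df["ideology"] = np.tile(["liberal", "conservative"], 20)
    out = score_items(df)
    assert list(out["item_id"]) == ["a", "b"]
    assert (out["n_judges"] == 20).all()
    per_row = score_judgments(df)
    assert out.loc[0, "advantage"] == pytest.approx(
        per_row[df["item_id"] == "a"].mean(), abs=1e-12
    )
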