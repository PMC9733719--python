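import itertools

import numpy as np
import pandas as pd
import pytest

from penflow import config, events, synthetic
from penflow.events import (
    complete_pairs,
    event_contrasts,
    fit_event_model,
    low_share_event_tests,
    match_pairs,
    window_summaries,
)

from conftest import noise_free


@pytest.fixture(scope="module")
def event_run():
    """112-pen study with the realized event pattern and reference offsets."""
    roster = synthetic.study_roster(seed=101)
    ev = synthetic.assign_events_from_counts(roster, seed=102)
    cfg = config.make_event_config()
    hourly, _ = synthetic.simulate_pen_hourly(roster, cfg, seed=103, events=ev)
    pairs = match_pairs(ev, roster)
    summaries = window_summaries(hourly, pairs)
    return roster, ev, cfg, hourly, pairs, summaries


def _mini_roster():
    rows = []
    for i, pos in enumerate([1, 2, 5], start=1):
        rows.append(
            {"pen_id": f"p{i}", "batch": 1, "tail": "docked", "straw": "with",
             "stock": "low", "n_pigs": 11, "position": pos}
        )
    return pd.DataFrame(rows)


class TestMatchPairs:
    def test_single_eligible_control(self):
        roster = _mini_roster().head(2)
        ev = pd.DataFrame({"pen_id": ["p1"], "event_day": [30]})
        pairs = match_pairs(ev, roster)
        assert len(pairs) == 1
        assert pairs["control_pen"].iloc[0] == "p2"

    def test_control_with_event_three_days_later_ineligible(self):
        roster = _mini_roster().head(2)
        ev = pd.DataFrame({"pen_id": ["p1", "p2"], "event_day": [30, 33]})
        pairs = match_pairs(ev, roster)
        # p2's own event is < 7 days after, so p1 has no control
        assert "p1" not in set(pairs["case_pen"])

    def test_control_with_event_week_later_eligible(self):
        roster = _mini_roster().head(2)
        ev = pd.DataFrame({"pen_id": ["p1", "p2"], "event_day": [30, 37]})
        pairs = match_pairs(ev, roster)
        case1 = pairs[pairs["case_pen"] == "p1"]
        assert len(case1) == 1
        assert case1["control_pen"].iloc[0] == "p2"

    def test_proximity_tie_break(self):
        roster = _mini_roster()
        roster.loc[roster["pen_id"] == "p3", "position"] = 3
        ev = pd.DataFrame({"pen_id": ["p2"], "event_day": [30]})
        pairs = match_pairs(ev, roster)  # p1 (pos 1) and p3 (pos 3) equidistant
        assert pairs["control_pen"].iloc[0] == "p1"

    def test_realized_pattern_gives_23_pairs(self, event_run):
        _, ev, _, _, pairs, _ = event_run
        assert len(pairs) == sum(config.STUDY_EVENT_PAIR_COUNTS) == 23

    def test_pairs_satisfy_predicates_exhaustively(self, event_run):
        # brute-force re-check of every eligibility predicate for every pair
        roster, ev, _, _, pairs, _ = event_run
        meta = roster.set_index("pen_id")
        event_day = dict(zip(ev["pen_id"], ev["event_day"]))
        for p in pairs.itertuples(index=False):
            case, ctrl = meta.loc[p.case_pen], meta.loc[p.control_pen]
            assert p.case_pen != p.control_pen
            for col in ("batch", "tail", "straw", "stock"):
                assert case[col] == ctrl[col]
            assert event_day.get(p.control_pen, np.inf) >= p.day0 + 7
            # no strictly closer control among all brute-force candidates
            best = min(
                abs(meta.loc[c, "position"] - case["position"])
                for c in roster["pen_id"]
                if c != p.case_pen
                and (meta.loc[c, ["batch", "tail", "straw", "stock"]]
                     == case[["batch", "tail", "straw", "stock"]]).all()
                and event_day.get(c, np.inf) >= p.day0 + 7
                and c not in event_day
            )
            assert abs(ctrl["position"] - case["position"]) == best


class TestWindowSummaries:
    def test_constant_hourly_statistics(self):
        rows = []
        for day in range(27, 31):
            for hour in range(24):
                rows.append({"pen_id": "c1", "day": day, "hour": hour,
                             "water": 0.2, "activations": 1.0, "n_pigs": 11})
                rows.append({"pen_id": "c2", "day": day, "hour": hour,
                             "water": 0.1, "activations": 0.5, "n_pigs": 11})
        hourly = pd.DataFrame(rows)
        pairs = pd.DataFrame(
            [{"event_id": "e01", "case_pen": "c1", "control_pen": "c2", "day0": 30,
              "batch": 1, "tail": "docked", "straw": "with", "stock": "low"}]
        )
        out = window_summaries(hourly, pairs)
        assert len(out) == 2 * 4 * 3
        peak1 = out[(out["pen_type"] == "case") & (out["period"] == "peak1")]
        assert peak1["water_total"].to_numpy() == pytest.approx(1.2)
        assert peak1["water_min"].to_numpy() == pytest.approx(0.2)
        assert peak1["water_mean"].to_numpy() == pytest.approx(0.2)
        assert peak1["water_max"].to_numpy() == pytest.approx(0.2)
        low = out[(out["pen_type"] == "case") & (out["period"] == "low")]
        assert low["water_total"].to_numpy() == pytest.approx(0.2 * 12)
        assert out["complete"].all()

    def test_min_mean_max_ordering(self, event_run):
        *_, summaries = event_run
        ok = summaries.dropna(subset=["water_min"])
        assert (ok["water_min"] <= ok["water_mean"] + 1e-12).all()
        assert (ok["water_mean"] <= ok["water_max"] + 1e-12).all()

    def test_hour_order_invariance(self, event_run):
        _, ev, _, hourly, pairs, summaries = event_run
        shuffled = hourly.sample(frac=1.0, random_state=3)
        again = window_summaries(shuffled, pairs)
        key = ["event_id", "pen_id", "day_off", "period"]
        a = summaries.sort_values(key).reset_index(drop=True)
        b = again.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_window_flagged(self):
        hourly = pd.DataFrame(
            [{"pen_id": "c1", "day": 30, "hour": h, "water": 0.2,
              "activations": 1.0, "n_pigs": 11} for h in range(24)]
        )
        pairs = pd.DataFrame(
            [{"event_id": "e01", "case_pen": "c1", "control_pen": "c2", "day0": 30,
              "batch": 1, "tail": "docked", "straw": "with", "stock": "low"}]
        )
        out = window_summaries(hourly, pairs)
        assert not out["complete"].all()
        assert complete_pairs(out).empty


class TestEventModel:
    def test_offsets_recovered(self, event_run):
        *_, summaries = event_run
        fit = fit_event_model(summaries, "mean", "water", eliminate=False)
        c = event_contrasts(fit).set_index("period")
        # single realization: generous tolerance, the acceptance suite averages seeds
        assert c.loc["peak2", "diff_case_minus_control"] == pytest.approx(0.058, abs=0.1)
        assert c.loc["low", "diff_case_minus_control"] == pytest.approx(0.0, abs=0.1)

    def test_total_statistic_untransformed(self, event_run):
        *_, summaries = event_run
        fit = fit_event_model(summaries, "total", "water", eliminate=False)
        assert fit.transform == "identity"

    def test_unknown_statistic_rejected(self, event_run):
        *_, summaries = event_run
        with pytest.raises(ValueError, match="statistic"):
            fit_event_model(summaries, "median", "water")

    def test_few_pairs_warns(self):
        roster = synthetic.study_roster(seed=111)
        ev = synthetic.assign_events_from_counts(
            roster, counts={("docked", "with", "low"): 3}, seed=112
        )
        cfg = config.make_event_config()
        hourly, _ = synthetic.simulate_pen_hourly(roster, cfg, seed=113, events=ev)
        pairs = match_pairs(ev, roster)
        summaries = window_summaries(hourly, pairs)
        with pytest.warns(UserWarning, match="floor"):
            fit_event_model(summaries, "mean", "water", eliminate=False)

    def test_day_constant_effects_drop_pen_type_day_term(self, event_run):
        *_, summaries = event_run
        fit = fit_event_model(summaries, "mean", "water", eliminate=True)
        assert "C(pen_type):C(day_off)" not in fit.terms

    def test_null_difference_contrast_near_zero(self):
        roster = synthetic.study_roster(seed=121)
        ev = synthetic.assign_events_from_counts(roster, seed=122)
        cfg = config.make_event_config()
        cfg.event_offsets = None  # cases behave exactly like controls
        hourly, _ = synthetic.simulate_pen_hourly(roster, cfg, seed=123, events=ev)
        pairs = match_pairs(ev, roster)
        summaries = window_summaries(hourly, pairs)
        fit = fit_event_model(summaries, "mean", "water", eliminate=False)
        c = event_contrasts(fit).set_index("period")
        assert abs(c.loc["peak2", "diff_case_minus_control"]) <= 3 * c.loc["peak2", "se_diff"]


class TestLowShareEventTests:
    def test_flat_diurnal_share_half(self):
        rows = []
        for pen in ("c1", "c2", "c3", "c4"):
            for day in range(27, 31):
                for hour in range(24):
                    rows.append({"pen_id": pen, "day": day, "hour": hour,
                                 "water": 0.2, "activations": 1.0, "n_pigs": 11})
        hourly = pd.DataFrame(rows)
        pairs = pd.DataFrame(
            [
                {"event_id": "e01", "case_pen": "c1", "control_pen": "c2", "day0": 30,
                 "batch": 1, "tail": "docked", "straw": "with", "stock": "low"},
                {"event_id": "e02", "case_pen": "c3", "control_pen": "c4", "day0": 30,
                 "batch": 1, "tail": "docked", "straw": "with", "stock": "low"},
            ]
        )
        res = low_share_event_tests(hourly, pairs, "water")
        assert res.pen_shares["share_low"].to_numpy() == pytest.approx(0.5)

    def test_peak_confined_effects_leave_share_null(self, event_run):
        _, ev, _, hourly, pairs, _ = event_run
        res = low_share_event_tests(hourly, pairs, "water")
        assert res.pen_type_pvalue > 0.05
        assert res.day_pvalue > 0.05

    def test_degenerate_groups_raise(self):
        hourly = pd.DataFrame(
            [{"pen_id": "c1", "day": 30, "hour": h, "water": 0.2,
              "activations": 1.0, "n_pigs": 11} for h in range(24)]
        )
        pairs = pd.DataFrame(
            [{"event_id": "e01", "case_pen": "c1", "control_pen": "c2", "day0": 30,
              "batch": 1, "tail": "docked", "straw": "with", "stock": "low"}]
        )
        with pytest.raises(ValueError):
            low_share_event_tests(hourly, pairs, "water")
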