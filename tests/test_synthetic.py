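import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penflow import config, synthetic
from penflow.config import TREATMENT_COMBINATIONS
from penflow.periods import PERIOD_OF_HOUR

from conftest import noise_free

# frozen oracle: 0.343 + 0.003214*31 + three-wave sum at hour 13, squared
# (computed independently by direct trigonometric evaluation)
DAY31_H13_WATER = 0.4430430060


class TestRoster:
    def test_factorial_enumeration(self):
        roster = synthetic.generate_pen_roster(1, 1, seed=0)
        assert len(roster) == 8
        combos = set(zip(roster["tail"], roster["straw"], roster["stock"]))
        assert combos == set(TREATMENT_COMBINATIONS)

    def test_balance_and_scale(self):
        roster = synthetic.generate_pen_roster(3, 2, seed=0)
        assert len(roster) == 2 * 8 * 3
        counts = roster.groupby(["batch", "tail", "straw", "stock"]).size()
        assert (counts == 3).all()

    def test_study_scale_112(self):
        roster = synthetic.study_roster(seed=0)
        assert len(roster) == 112
        assert roster.groupby("batch").size().tolist() == [32, 32, 32, 16]

    def test_pig_counts_follow_stock(self):
        roster = synthetic.generate_pen_roster(2, 1, seed=3)
        assert (roster.loc[roster["stock"] == "high", "n_pigs"] == 18).all()
        assert (roster.loc[roster["stock"] == "low", "n_pigs"] == 11).all()

    def test_positions_unique_within_batch(self):
        roster = synthetic.generate_pen_roster(4, 3, seed=5)
        for _, grp in roster.groupby("batch"):
            assert sorted(grp["position"]) == list(range(1, len(grp) + 1))

    def test_determinism(self):
        a = synthetic.generate_pen_roster(2, 2, seed=42)
        b = synthetic.generate_pen_roster(2, 2, seed=42)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("kwargs", [{"n_per_combination": 0}, {"batches": 0}])
    def test_nonpositive_rejected(self, kwargs):
        args = {"n_per_combination": 1, "batches": 1, **kwargs}
        with pytest.raises(ValueError):
            synthetic.generate_pen_roster(**args)


class TestSimulatePenHourly:
    def test_flat_deterministic_value(self, roster8):
        cfg = noise_free(config.make_diurnal_config())
        cfg.water = dataclasses.replace(
            cfg.water, mean0=0.343, trend=0.0, amplitudes=(0.0, 0.0, 0.0)
        )
        hourly, _ = synthetic.simulate_pen_hourly(roster8, cfg, seed=0)
        assert hourly["water"].to_numpy() == pytest.approx(0.343**2)

    def test_reference_mean_function_value(self, roster8):
        cfg = noise_free(config.make_diurnal_config())
        hourly, _ = synthetic.simulate_pen_hourly(roster8, cfg, seed=0)
        cell = hourly[(hourly["day"] == 31) & (hourly["hour"] == 13)]
        assert cell["water"].to_numpy() == pytest.approx(DAY31_H13_WATER, abs=1e-9)

    def test_sample_mean_matches_fixed_effect(self):
        # law of large numbers on the sqrt scale at one (day, hour) cell
        roster = synthetic.generate_pen_roster(30, 1, seed=6)  # 240 pens
        cfg = config.make_diurnal_config()
        cfg.n_days = 16
        _, truth = synthetic.simulate_pen_hourly(roster, cfg, seed=7)
        cell = truth[(truth["day"] == 15) & (truth["hour"] == 9)]
        expected = cfg.water.sqrt_mean(15.0, 9.0)
        sd = np.sqrt(
            cfg.water.pen_sd**2 + cfg.water.day_sd**2 + cfg.water.resid_sd**2
            + (cfg.water.amp_pen_cv**2 + cfg.water.amp_day_cv**2)
            * (cfg.water.sqrt_mean(15.0, 9.0) - cfg.water.mean0 - 15 * cfg.water.trend) ** 2
        )
        assert cell["water_value_sqrt"].mean() == pytest.approx(
            float(expected), abs=4 * sd / np.sqrt(len(cell))
        )

    def test_all_values_non_negative(self, diurnal_run56):
        _, _, hourly, _ = diurnal_run56
        assert (hourly["water"] >= 0).all()
        assert (hourly["activations"] >= 0).all()

    def test_seed_reproducibility(self, roster8):
        cfg = config.make_diurnal_config()
        a, ta = synthetic.simulate_pen_hourly(roster8, cfg, seed=99)
        b, tb = synthetic.simulate_pen_hourly(roster8, cfg, seed=99)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_event_censoring(self, roster8):
        cfg = config.make_diurnal_config()
        events = pd.DataFrame({"pen_id": [roster8["pen_id"].iloc[0]], "event_day": [10]})
        hourly, _ = synthetic.simulate_pen_hourly(roster8, cfg, seed=1, events=events)
        censored = hourly[hourly["pen_id"] == roster8["pen_id"].iloc[0]]
        assert censored["day"].max() == 10
        other = hourly[hourly["pen_id"] != roster8["pen_id"].iloc[0]]
        assert other["day"].max() == cfg.n_days

    def test_invalid_config_names_field(self, roster8):
        cfg = config.make_diurnal_config()
        cfg.water = dataclasses.replace(cfg.water, resid_sd=-1.0)
        with pytest.raises(ValueError, match="resid_sd"):
            synthetic.simulate_pen_hourly(roster8, cfg, seed=0)

    def test_diurnal_extremes_fall_in_expected_periods(self, roster8):
        # numeric scan of the deterministic mean function
        cfg = noise_free(config.make_diurnal_config())
        hourly, _ = synthetic.simulate_pen_hourly(roster8, cfg, seed=0)
        day = hourly[(hourly["pen_id"] == roster8["pen_id"].iloc[0]) & (hourly["day"] == 31)]
        by_hour = day.set_index("hour")["water"]
        h_min, h_max = by_hour.idxmin(), by_hour.idxmax()
        assert PERIOD_OF_HOUR[h_min] == "low"
        assert PERIOD_OF_HOUR[h_max] == "peak2"


class TestSplitSensors:
    def test_full_preference_zeroes_of(self, roster8):
        cfg = noise_free(config.make_diurnal_config())
        cfg.preference = config.PreferenceParams(
            f_share_mean=1.0 - 1e-12, f_share_conc=1e9, switch_prob=0.0, hour_jitter_conc=1e9
        )
        hourly, _ = synthetic.simulate_pen_hourly(roster8, cfg, seed=0)
        sensors = synthetic.split_sensors(hourly, cfg, seed=1)
        of = sensors[sensors["location"] == "OF"]
        assert of["water"].abs().max() < 1e-6

    def test_conservation_exact(self, diurnal_run56):
        roster, cfg, hourly, _ = diurnal_run56
        sensors = synthetic.split_sensors(hourly, cfg, seed=5)
        total = sensors.groupby(["pen_id", "day", "hour"])[["water", "activations"]].sum()
        pen = hourly.set_index(["pen_id", "day", "hour"])[["water", "activations"]]
        pen = pen.loc[total.index]
        assert np.allclose(total.to_numpy(), pen.to_numpy(), rtol=0, atol=1e-12)

    def test_default_location_gap(self, diurnal_run56):
        roster, cfg, hourly, _ = diurnal_run56
        sensors = synthetic.split_sensors(hourly, cfg, seed=5)
        means = sensors.groupby("location")["water"].mean()
        assert means["F"] - means["OF"] == pytest.approx(0.075, abs=0.03)
        assert means["F"] > means["OF"]


class TestAnomalies:
    def test_zero_rate_no_change(self, roster8):
        cfg = config.make_diurnal_config()
        cfg.anomaly.rate = 0.0
        hourly, _ = synthetic.simulate_pen_hourly(roster8, cfg, seed=2)
        sensors = synthetic.split_sensors(hourly, cfg, seed=3)
        corrupted, labels = synthetic.inject_anomalies(sensors, cfg, seed=4)
        pd.testing.assert_frame_equal(corrupted, sensors.reset_index(drop=True))
        assert labels.empty

    def test_labeled_fraction_matches_rate(self, diurnal_run56):
        roster, cfg, hourly, _ = diurnal_run56
        sensors = synthetic.split_sensors(hourly, cfg, seed=5)
        cfg2 = config.make_diurnal_config()
        cfg2.anomaly.rate = 0.005
        _, labels = synthetic.inject_anomalies(sensors, cfg2, seed=6)
        n = len(sensors)
        frac = len(labels) / n
        binom_sd = np.sqrt(0.005 * 0.995 / n)
        assert frac == pytest.approx(0.005, abs=4 * binom_sd)

    def test_invalid_rate_rejected(self, roster8):
        good = config.make_diurnal_config()
        hourly, _ = synthetic.simulate_pen_hourly(roster8, good, seed=0)
        sensors = synthetic.split_sensors(hourly, good, seed=0)
        bad = config.make_diurnal_config()
        bad.anomaly.rate = 1.5
        with pytest.raises(ValueError, match="rate"):
            synthetic.inject_anomalies(sensors, bad, seed=0)

    def test_stuck_magnitude_detectable(self):
        # sqrt deviation of a stuck-open hour dwarfs the generating residual SD
        cfg = config.make_diurnal_config()
        typical_sqrt = cfg.water.mean0 + cfg.water.trend * 31
        deviation = np.sqrt(cfg.anomaly.stuck_water) - typical_sqrt
        assert deviation >= 8 * cfg.water.resid_sd


class TestTailEvents:
    def test_zero_hazard(self, roster8):
        cfg = config.make_diurnal_config()
        cfg.event_hazard = 0.0
        events = synthetic.schedule_tail_events(roster8, cfg, seed=0)
        assert events.empty

    def test_hazard_scale(self):
        # P(event within 63 d) = 1-(1-h)^63; h tuned so ~54/110 pens convert
        roster = synthetic.study_roster(seed=2)
        cfg = config.make_diurnal_config()
        cfg.event_hazard = 0.0107  # 1-(1-h)^63 ~ 0.49
        events = synthetic.schedule_tail_events(roster, cfg, seed=3)
        p = 1 - (1 - cfg.event_hazard) ** cfg.n_days
        expected = len(roster) * p
        sd = np.sqrt(len(roster) * p * (1 - p))
        assert abs(len(events) - expected) < 4 * sd

    def test_at_most_one_event_per_pen(self):
        roster = synthetic.study_roster(seed=4)
        cfg = config.make_diurnal_config()
        cfg.event_hazard = 0.05
        events = synthetic.schedule_tail_events(roster, cfg, seed=5)
        assert events["pen_id"].is_unique

    def test_counts_assignment(self):
        roster = synthetic.study_roster(seed=6)
        events = synthetic.assign_events_from_counts(roster, seed=7)
        assert len(events) == sum(config.STUDY_EVENT_PAIR_COUNTS)
        merged = events.merge(roster, on="pen_id")
        counts = merged.groupby(["tail", "straw", "stock"]).size().to_dict()
        expected = {
            c: n for c, n in zip(TREATMENT_COMBINATIONS, config.STUDY_EVENT_PAIR_COUNTS) if n
        }
        assert counts == expected

    def test_event_pen_elevated_in_peak2(self, roster8):
        cfg = noise_free(config.make_event_config())
        pen = roster8["pen_id"].iloc[0]
        events = pd.DataFrame({"pen_id": [pen], "event_day": [40]})
        with_ev, _ = synthetic.simulate_pen_hourly(roster8, cfg, seed=0, events=events)
        without, _ = synthetic.simulate_pen_hourly(roster8, cfg, seed=0)
        mask = lambda df: df[
            (df["pen_id"] == pen) & df["day"].between(37, 40)
            & (PERIOD_OF_HOUR[df["hour"].to_numpy()] == "peak2")
        ]
        delta = mask(with_ev)["water"].mean() - mask(without)["water"].mean()
        assert delta == pytest.approx(0.058, abs=1e-6)


class TestPulseStream:
    def test_zero_activation_hour_emits_nothing(self):
        table = pd.DataFrame(
            {
                "pen_id": ["p1"], "location": ["F"], "day": [1], "hour": [4],
                "water": [0.0], "activations": [0.0], "n_pigs": [11],
            }
        )
        stream = synthetic.emit_pulse_stream(table, 1000.0, seed=0)
        assert stream.empty

    def test_pulse_and_start_conservation(self):
        table = pd.DataFrame(
            {
                "pen_id": ["p1"], "location": ["F"], "day": [2], "hour": [7],
                "water": [2.0 / 11], "activations": [4.0 / 11], "n_pigs": [11],
            }
        )
        stream = synthetic.emit_pulse_stream(table, 1000.0, seed=1)
        assert len(stream) == 4
        assert stream["pulses"].sum() == 2000
        assert (stream["start"].dt.hour == 7).all()

    def test_too_many_activations_rejected(self):
        table = pd.DataFrame(
            {
                "pen_id": ["p1"], "location": ["F"], "day": [1], "hour": [0],
                "water": [1.0], "activations": [4000.0], "n_pigs": [1],
            }
        )
        with pytest.raises(ValueError, match="cannot fit"):
            synthetic.emit_pulse_stream(table, 1000.0, seed=0)

    def test_nonpositive_ppl_rejected(self):
        with pytest.raises(ValueError, match="pulses_per_liter"):
            synthetic.emit_pulse_stream(pd.DataFrame(), 0.0, seed=0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_quantize_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            {
                "pen_id": ["p1"] * 5, "location": ["F"] * 5, "day": [1] * 5,
                "hour": list(range(5)),
                "water": rng.uniform(0, 0.5, 5), "activations": rng.uniform(0, 1, 5),
                "n_pigs": [11] * 5,
            }
        )
        once = synthetic.quantize_sensor_hourly(table, 1000.0)
        twice = synthetic.quantize_sensor_hourly(once, 1000.0)
        pd.testing.assert_frame_equal(once, twice)
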