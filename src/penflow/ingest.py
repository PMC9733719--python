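"""From calibration trials and pulse-level flow events to hourly use tables.

A flow event is one start/stop drinking bout recorded by one sensor with a
pulse total.  Calibration converts pulses to liters (mean pulses over
repeated 1-liter extraction trials); aggregation yields per-sensor hourly
water (L/pig) and activation counts (starts/pig) on a complete hour lattice
with explicit zeros, and pen-level tables sum the two sensors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOCATIONS = ("F", "OF")


@dataclass(frozen=True)
class SensorCalibration:
    """Pulses-per-liter factor for one sensor, from >= 1 one-liter trials."""

    sensor_id: str
    pulses_per_liter: float
    trial_counts: tuple

    def __post_init__(self):
        expected = float(np.mean(self.trial_counts))
        if abs(self.pulses_per_liter - expected) > 1e-9 * max(expected, 1.0):
            raise ValueError("pulses_per_liter must equal the mean of trial_counts")


def calibrate_sensor(trial_counts, sensor_id: str = "") -> SensorCalibration:
    """Calibration factor = arithmetic mean of the 1-liter trial pulse counts."""
    counts = tuple(float(c) for c in trial_counts)
    if not counts:
        raise ValueError("at least one calibration trial is required")
    if any(c <= 0 for c in counts):
        raise ValueError(f"trial counts must be positive, got {counts}")
    if len(counts) < 3:
        warnings.warn(
            f"only {len(counts)} calibration trial(s); three repeats are the norm",
            stacklevel=2,
        )
    return SensorCalibration(sensor_id, float(np.mean(counts)), counts)


def recalibration_drift(old: SensorCalibration, new: SensorCalibration) -> float:
    """Percent inaccuracy between two calibrations of the same sensor."""
    if old.sensor_id != new.sensor_id:
        raise ValueError(
            f"calibrations are for different sensors: {old.sensor_id!r} vs {new.sensor_id!r}"
        )
    return 100.0 * abs(new.pulses_per_liter - old.pulses_per_liter) / old.pulses_per_liter


def sensor_map_from_roster(roster: pd.DataFrame) -> pd.DataFrame:
    """Two sensors per pen, ids ``<pen_id>:F`` and ``<pen_id>:OF``."""
    rows = [
        {"sensor_id": f"{pen_id}:{loc}", "pen_id": pen_id, "location": loc}
        for pen_id in roster["pen_id"]
        for loc in LOCATIONS
    ]
    return pd.DataFrame(rows)


def uniform_calibrations(roster: pd.DataFrame, pulses_per_liter: float) -> dict:
    """Identical calibration for every sensor (synthetic-data convenience)."""
    trial = (pulses_per_liter,) * 3
    return {
        sid: SensorCalibration(sid, pulses_per_liter, trial)
        for sid in sensor_map_from_roster(roster)["sensor_id"]
    }


def aggregate_hourly(
    events: pd.DataFrame,
    calibrations: dict,
    roster: pd.DataFrame,
    n_days: int,
    start_date: str = "2015-06-01",
    last_day_by_pen: dict | None = None,
) -> pd.DataFrame:
    """Aggregate flow events to per-sensor hourly water use and activations.

    Each event contributes its full pulse total and one activation to the
    hour containing its *start* time.  Hours with no events appear as
    explicit zero rows over the full lattice (all pens, both locations,
    days 1..n_days, hours 0..23), truncated per pen by ``last_day_by_pen``
    (for pens that left the study early).  Values are per current pig.
    """
    sensor_map = sensor_map_from_roster(roster)
    known = set(sensor_map["sensor_id"])
    origin = pd.Timestamp(start_date)
    if len(events):
        if (events["pulses"] < 0).any():
            bad = events.loc[events["pulses"] < 0]
            raise ValueError(f"negative pulse counts for {len(bad)} events")
        unknown = sorted(set(events["sensor_id"]) - known)
        if unknown:
            raise ValueError(f"events from unknown sensors: {unknown[:5]}")
        missing_cal = sorted(set(events["sensor_id"]) - set(calibrations))
        if missing_cal:
            raise ValueError(f"no calibration for sensors: {missing_cal[:5]}")
        start = pd.to_datetime(events["start"])
        day = (start.dt.normalize() - origin).dt.days.to_numpy() + 1
        if (day < 1).any() or (day > n_days).any():
            raise ValueError("events fall outside study days 1..n_days")
        work = pd.DataFrame(
            {
                "sensor_id": events["sensor_id"].to_numpy(),
                "day": day,
                "hour": start.dt.hour.to_numpy(),
                "pulses": events["pulses"].to_numpy(dtype=float),
            }
        )
        agg = (
            work.groupby(["sensor_id", "day", "hour"])
            .agg(pulses=("pulses", "sum"), starts=("pulses", "size"))
            .reset_index()
        )
    else:
        agg = pd.DataFrame(columns=["sensor_id", "day", "hour", "pulses", "starts"])

    # full lattice with explicit zeros
    frames = []
    for pen in roster.itertuples(index=False):
        last = int(last_day_by_pen.get(pen.pen_id, n_days)) if last_day_by_pen else n_days
        days = np.arange(1, last + 1)
        for loc in LOCATIONS:
            idx = pd.MultiIndex.from_product(
                [[f"{pen.pen_id}:{loc}"], days, np.arange(24)],
                names=["sensor_id", "day", "hour"],
            )
            frames.append(
                pd.DataFrame(
                    {"pen_id": pen.pen_id, "location": loc, "n_pigs": pen.n_pigs}, index=idx
                )
            )
    lattice = pd.concat(frames)
    agg = agg.set_index(["sensor_id", "day", "hour"]).reindex(lattice.index, fill_value=0.0)
    ppl = lattice.index.get_level_values("sensor_id").map(
        {sid: cal.pulses_per_liter for sid, cal in calibrations.items()}
    )
    if pd.isna(ppl).any():
        missing = sorted(
            set(lattice.index.get_level_values("sensor_id")) - set(calibrations)
        )
        raise ValueError(f"no calibration for sensors: {missing[:5]}")
    n_pigs = lattice["n_pigs"].to_numpy(dtype=float)
    out = lattice.reset_index()
    out["water"] = agg["pulses"].to_numpy() / np.asarray(ppl, dtype=float) / n_pigs
    out["activations"] = agg["starts"].to_numpy(dtype=float) / n_pigs
    out = out[["pen_id", "location", "day", "hour", "water", "activations", "n_pigs"]]
    logger.info(
        "aggregated %d events into %d sensor-hours (%d sensors)",
        len(events), len(out), out.groupby(["pen_id", "location"]).ngroups,
    )
    return out.reset_index(drop=True)


def pen_level(
    sensor_hourly: pd.DataFrame, exclusions=()
) -> pd.DataFrame:
    """Sum the two sensor locations to one pen-level row per pen-hour.

    Pens listed in ``exclusions`` (e.g. broken sensors) are dropped, as are
    pens missing one of the two locations (flagged in the log and in
    ``result.attrs['excluded']``).  Per-pig normalization carries through
    because both sensors are already per-pig on the same pig count.
    """
    df = sensor_hourly[~sensor_hourly["pen_id"].isin(set(exclusions))]
    excluded = {pen: "listed in exclusions" for pen in exclusions}
    locs = df.groupby("pen_id")["location"].agg(lambda s: frozenset(s))
    incomplete = locs.index[locs != frozenset(LOCATIONS)]
    for pen in incomplete:
        excluded[pen] = f"missing sensor location(s): {sorted(set(LOCATIONS) - locs[pen])}"
        logger.warning("pen %s excluded: %s", pen, excluded[pen])
    df = df[~df["pen_id"].isin(set(incomplete))]
    out = (
        df.groupby(["pen_id", "day", "hour"], sort=True)
        .agg(
            water=("water", "sum"),
            activations=("activations", "sum"),
            n_pigs=("n_pigs", "first"),
            n_locations=("location", "nunique"),
        )
        .reset_index()
    )
    bad = out["n_locations"] != len(LOCATIONS)
    if bad.any():
        # partial hours (one sensor missing a row) are kept as the available sum
        logger.warning("%d pen-hours had only one sensor row", int(bad.sum()))
    out = out.drop(columns="n_locations")
    out.insert(1, "level", "pen")
    out.attrs["excluded"] = excluded
    return out
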