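"""Synthetic drinker-use data with known ground truth.

Generates pen rosters, pen-level hourly water use and activation counts on
the square-root scale (3-wave diurnal pattern or per-period step means, pen
and day random intercepts, within-day AR(1) residuals; values clipped at
zero and squared), sensor-level splits with location preference, injected
sensor faults, tail-damage events, and second-resolution pulse streams.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import (
    GeneratorConfig,
    PIGS_PER_STOCK,
    PERIODS,
    STUDY_EVENT_PAIR_COUNTS,
    STUDY_PENS_PER_BATCH,
    TREATMENT_COMBINATIONS,
)
from .periods import PERIOD_OF_HOUR, week_of_day

RESPONSES = ("water", "activations")

ROSTER_COLUMNS = ["pen_id", "batch", "tail", "straw", "stock", "n_pigs", "position"]


# ---------------------------------------------------------------------------
# rosters
# ---------------------------------------------------------------------------


def generate_pen_roster(
    n_per_combination: int,
    batches: int,
    seed=None,
    *,
    extra_batch_n: int | None = None,
) -> pd.DataFrame:
    """Balanced factorial roster: ``batches * 8 * n_per_combination`` pens.

    Each batch holds ``n_per_combination`` pens for each of the eight
    (tail, straw, stock) combinations, with room positions randomly permuted
    within batch.  ``extra_batch_n`` appends one additional batch with its own
    (smaller) per-combination count, mirroring deployments where one batch ran
    at half scale.
    """
    if n_per_combination < 1:
        raise ValueError(f"n_per_combination must be >= 1, got {n_per_combination}")
    if batches < 1:
        raise ValueError(f"batches must be >= 1, got {batches}")
    if extra_batch_n is not None and extra_batch_n < 1:
        raise ValueError(f"extra_batch_n must be >= 1, got {extra_batch_n}")
    rng = np.random.default_rng(seed)
    per_batch = [n_per_combination] * batches
    if extra_batch_n is not None:
        per_batch.append(extra_batch_n)
    rows = []
    for batch_idx, n_combo in enumerate(per_batch, start=1):
        combos = [c for c in TREATMENT_COMBINATIONS for _ in range(n_combo)]
        positions = rng.permutation(len(combos)) + 1
        for k, ((tail, straw, stock), pos) in enumerate(zip(combos, positions), start=1):
            rows.append(
                {
                    "pen_id": f"b{batch_idx}p{k:02d}",
                    "batch": batch_idx,
                    "tail": tail,
                    "straw": straw,
                    "stock": stock,
                    "n_pigs": PIGS_PER_STOCK[stock],
                    "position": int(pos),
                }
            )
    return pd.DataFrame(rows, columns=ROSTER_COLUMNS)


def study_roster(seed=None) -> pd.DataFrame:
    """112-pen roster at the reference deployment's scale: three full batches
    of 32 pens plus one half batch of 16."""
    return generate_pen_roster(4, 3, seed, extra_batch_n=2)


# ---------------------------------------------------------------------------
# sqrt-scale offset helpers
# ---------------------------------------------------------------------------


def sqrt_shift_for_difference(baseline_sqrt: float, delta_obs: float) -> float:
    """Sqrt-scale shift s with (m + s)^2 - m^2 = delta_obs at baseline m."""
    m = max(baseline_sqrt, 0.0)
    target = m * m + delta_obs
    if target < 0:
        raise ValueError(
            f"offset {delta_obs} drives the squared mean negative at baseline {m:.4f}"
        )
    return math.sqrt(target) - m


def _reference_day(config: GeneratorConfig) -> float:
    return 7.0 * (config.reference_week - 1.0) + 4.0


def _period_hour_sets() -> dict[str, np.ndarray]:
    hours = np.arange(24)
    return {p: hours[PERIOD_OF_HOUR[hours] == p] for p in PERIODS}


def _stock_shifts(config: GeneratorConfig, response: str) -> dict[str, float]:
    """Per-period sqrt-scale shifts for low-stocking pens."""
    if not config.stock_offsets or response not in config.stock_offsets:
        return {}
    period_params = config.period_params(response)
    hour_sets = _period_hour_sets()
    shifts = {}
    for period, delta in config.stock_offsets[response].items():
        if period_params is not None:
            m = period_params.sqrt_mean(period, config.reference_week)
        else:
            params = config.response(response)
            m = float(np.mean(params.sqrt_mean(_reference_day(config), hour_sets[period])))
        shifts[period] = sqrt_shift_for_difference(m, delta)
    return shifts


def _event_shifts_from_grid(
    config: GeneratorConfig,
    response: str,
    mean_grid: np.ndarray,
    period_idx: np.ndarray,
    event_day: int,
) -> dict[str, float]:
    """Per-period sqrt shifts for an event pen, solved against the pen's own
    realized mean grid over its day -3..0 window, so the back-transformed
    case-control gap equals the configured offset where it is measured."""
    if not config.event_offsets or response not in config.event_offsets:
        return {}
    lo = max(1, event_day - 3) - 1
    hi = min(event_day, mean_grid.shape[0])
    shifts = {}
    for period, delta in config.event_offsets[response].items():
        window = mean_grid[lo:hi, period_idx == period]
        m = float(np.mean(window))
        shifts[period] = sqrt_shift_for_difference(m, delta)
    return shifts


# ---------------------------------------------------------------------------
# pen-level simulation
# ---------------------------------------------------------------------------


def _mean_grid(config: GeneratorConfig, response: str, n_days: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sqrt-scale mean as (level, wave) grids, shape (n_days, 24).

    The wave part is zero in period mode; in harmonic mode it is the wave sum,
    which pen/day amplitude heterogeneity scales multiplicatively.
    """
    days = np.arange(1, n_days + 1, dtype=float)
    hours = np.arange(24, dtype=float)
    period_params = config.period_params(response)
    if period_params is not None:
        weeks = week_of_day(days)
        grid = np.empty((n_days, 24))
        for h in range(24):
            p = PERIOD_OF_HOUR[h]
            grid[:, h] = period_params.intercepts[p] + period_params.slopes[p] * (weeks - 1.0)
        return grid, np.zeros_like(grid)
    params = config.response(response)
    level = np.broadcast_to(
        (params.mean0 + params.trend * days)[:, None], (n_days, 24)
    ).copy()
    wave = params.sqrt_mean(days[:, None], hours[None, :]) - level
    return level, wave


def _ar1_noise(rng: np.random.Generator, n_days: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) residuals, restarted each day; shape (n_days, 24)."""
    eps = rng.standard_normal((n_days, 24))
    out = np.empty_like(eps)
    out[:, 0] = sd * eps[:, 0]
    scale = sd * math.sqrt(1.0 - rho * rho)
    for h in range(1, 24):
        out[:, h] = rho * out[:, h - 1] + scale * eps[:, h]
    return out


def simulate_pen_hourly(
    roster: pd.DataFrame,
    config: GeneratorConfig,
    seed=None,
    events: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate pen-level hourly use for both responses.

    Returns ``(hourly, truth)``: the observed table (back-transformed, i.e.
    squared values) and a ground-truth table holding the sqrt-scale means and
    pre-squaring values of every cell.  Pens listed in ``events`` are censored
    after their event day and receive the configured per-period offsets for
    all their simulated days.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n_days = config.n_days
    period_idx = PERIOD_OF_HOUR[np.arange(24)]
    event_day_by_pen = {}
    if events is not None and len(events):
        event_day_by_pen = dict(zip(events["pen_id"], events["event_day"]))

    base = {r: _mean_grid(config, r, n_days) for r in RESPONSES}
    stock_shift = {r: _stock_shifts(config, r) for r in RESPONSES}

    obs_rows = []
    truth_rows = []
    days = np.arange(1, n_days + 1)
    for pen in roster.itertuples(index=False):
        last_day = int(event_day_by_pen.get(pen.pen_id, n_days))
        last_day = min(max(last_day, 1), n_days)
        keep = slice(0, last_day)
        pen_obs = {}
        pen_truth = {}
        for response in RESPONSES:
            params = config.response(response)
            level, wave = base[response]
            mean = level.copy()
            if params.phase_pen_sd > 0 and config.period_params(response) is None:
                # coherent pen-level time shift of the whole diurnal pattern
                delta = rng.normal(0.0, params.phase_pen_sd)
                shifted_hours = np.arange(24, dtype=float) - delta
                wave = (
                    params.sqrt_mean(
                        np.arange(1, n_days + 1, dtype=float)[:, None],
                        shifted_hours[None, :],
                    )
                    - level
                )
            if params.amp_pen_cv > 0 or params.amp_day_cv > 0:
                pen_scale = (
                    max(0.0, 1.0 + rng.normal(0.0, params.amp_pen_cv))
                    if params.amp_pen_cv > 0
                    else 1.0
                )
                day_scale = (
                    np.clip(1.0 + rng.normal(0.0, params.amp_day_cv, n_days), 0.0, None)
                    if params.amp_day_cv > 0
                    else np.ones(n_days)
                )
                mean += pen_scale * day_scale[:, None] * wave
            else:
                mean += wave
            if pen.stock == "low":
                for period, shift in stock_shift[response].items():
                    mean[:, period_idx == period] += shift
            if pen.pen_id in event_day_by_pen:
                for period, shift in _event_shifts_from_grid(
                    config, response, mean, period_idx, event_day_by_pen[pen.pen_id]
                ).items():
                    mean[:, period_idx == period] += shift
            pen_eff = rng.normal(0.0, params.pen_sd) if params.pen_sd > 0 else 0.0
            day_eff = (
                rng.normal(0.0, params.day_sd, n_days)
                if params.day_sd > 0
                else np.zeros(n_days)
            )
            resid = (
                _ar1_noise(rng, n_days, params.resid_sd, params.rho)
                if params.resid_sd > 0
                else np.zeros((n_days, 24))
            )
            value_sqrt = np.clip(mean + pen_eff + day_eff[:, None] + resid, 0.0, None)
            pen_obs[response] = (value_sqrt**2)[keep]
            pen_truth[response] = (mean[keep], value_sqrt[keep])
        d = np.repeat(days[keep], 24)
        h = np.tile(np.arange(24), last_day)
        obs_rows.append(
            pd.DataFrame(
                {
                    "pen_id": pen.pen_id,
                    "level": "pen",
                    "day": d,
                    "hour": h,
                    "water": pen_obs["water"].ravel(),
                    "activations": pen_obs["activations"].ravel(),
                    "n_pigs": pen.n_pigs,
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "pen_id": pen.pen_id,
                    "day": d,
                    "hour": h,
                    "water_mean_sqrt": pen_truth["water"][0].ravel(),
                    "water_value_sqrt": pen_truth["water"][1].ravel(),
                    "activations_mean_sqrt": pen_truth["activations"][0].ravel(),
                    "activations_value_sqrt": pen_truth["activations"][1].ravel(),
                }
            )
        )
    hourly = pd.concat(obs_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return hourly, truth


# ---------------------------------------------------------------------------
# sensor split
# ---------------------------------------------------------------------------


def split_sensors(
    pen_hourly: pd.DataFrame, config: GeneratorConfig, seed=None
) -> pd.DataFrame:
    """Partition pen-level hourly use between the F and OF cups.

    Each pen draws a persistent preference share for the F cup; the share may
    flip (switch of preferred cup) on any day with probability
    ``preference.switch_prob`` and carries Beta jitter hour to hour.  Both
    responses follow the same hourly share, and F + OF reproduces the pen
    totals exactly.
    """
    pref = config.preference
    pref.validate()
    rng = np.random.default_rng(seed)
    out = []
    for pen_id, grp in pen_hourly.groupby("pen_id", sort=True):
        grp = grp.sort_values(["day", "hour"])
        if pref.f_share_mean >= 1.0:
            share_pen = 1.0
        else:
            share_pen = rng.beta(
                pref.f_share_mean * pref.f_share_conc,
                (1.0 - pref.f_share_mean) * pref.f_share_conc,
            )
        days = np.asarray(sorted(grp["day"].unique()))
        flips = rng.random(len(days)) < pref.switch_prob
        flipped = np.cumsum(flips) % 2 == 1
        share_day = np.where(flipped, 1.0 - share_pen, share_pen)
        day_share = dict(zip(days, share_day))
        s = grp["day"].map(day_share).to_numpy()
        w = np.empty(len(grp))
        degenerate = (s <= 0.0) | (s >= 1.0)
        w[degenerate] = s[degenerate]
        if (~degenerate).any():
            sj = s[~degenerate]
            w[~degenerate] = rng.beta(
                sj * pref.hour_jitter_conc, (1.0 - sj) * pref.hour_jitter_conc
            )
        water_f = grp["water"].to_numpy() * w
        act_f = grp["activations"].to_numpy() * w
        # OF by subtraction so F + OF reproduces pen totals bit-exactly
        splits = {
            "F": (water_f, act_f),
            "OF": (grp["water"].to_numpy() - water_f, grp["activations"].to_numpy() - act_f),
        }
        for loc, (water, act) in splits.items():
            out.append(
                pd.DataFrame(
                    {
                        "pen_id": pen_id,
                        "location": loc,
                        "day": grp["day"].to_numpy(),
                        "hour": grp["hour"].to_numpy(),
                        "water": water,
                        "activations": act,
                        "n_pigs": grp["n_pigs"].to_numpy(),
                    }
                )
            )
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# anomalies
# ---------------------------------------------------------------------------


def inject_anomalies(
    sensor_hourly: pd.DataFrame, config: GeneratorConfig, seed=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt a random fraction of sensor-hours with sensor faults.

    Fault kinds: ``stuck_open`` (nipple stuck flowing: very high water, a
    single long activation), ``leak`` (constant moderate flow), ``dropout``
    (sensor silent: zeros).  Returns the corrupted copy and a label table
    recording every touched cell with its original values.
    """
    anom = config.anomaly
    anom.validate()
    rng = np.random.default_rng(seed)
    df = sensor_hourly.reset_index(drop=True).copy()
    n = len(df)
    hit = np.flatnonzero(rng.random(n) < anom.rate)
    if len(hit) == 0:
        labels = pd.DataFrame(
            columns=["pen_id", "location", "day", "hour", "kind", "water_orig", "activations_orig"]
        )
        return df, labels
    kinds = list(anom.kind_probs)
    probs = np.array([anom.kind_probs[k] for k in kinds])
    drawn = rng.choice(kinds, size=len(hit), p=probs)
    labels = df.loc[hit, ["pen_id", "location", "day", "hour"]].copy()
    labels["kind"] = drawn
    labels["water_orig"] = df.loc[hit, "water"].to_numpy()
    labels["activations_orig"] = df.loc[hit, "activations"].to_numpy()
    n_pigs = df.loc[hit, "n_pigs"].to_numpy(dtype=float)
    water = df["water"].to_numpy().copy()
    act = df["activations"].to_numpy().copy()
    for kind in kinds:
        idx = hit[drawn == kind]
        pigs = df.loc[idx, "n_pigs"].to_numpy(dtype=float)
        if kind == "stuck_open":
            water[idx] = anom.stuck_water
            if anom.chatter_activations is not None:
                act[idx] = anom.chatter_activations
            else:
                act[idx] = 1.0 / pigs
        elif kind == "leak":
            water[idx] = anom.leak_water
        elif kind == "dropout":
            water[idx] = 0.0
            act[idx] = 0.0
        else:  # pragma: no cover - guarded by validate()
            raise ValueError(f"unknown anomaly kind {kind!r}")
    df["water"] = water
    df["activations"] = act
    return df, labels.reset_index(drop=True)


# ---------------------------------------------------------------------------
# tail-damage events
# ---------------------------------------------------------------------------


def schedule_tail_events(
    roster: pd.DataFrame, config: GeneratorConfig, seed=None
) -> pd.DataFrame:
    """Draw at most one tail-damage event per pen from a constant daily hazard.

    A pen with an event leaves the study after its event day (censoring is
    applied by :func:`simulate_pen_hourly`).
    """
    hazard = config.event_hazard
    if not 0.0 <= hazard <= 1.0:
        raise ValueError(f"event hazard must be in [0, 1], got {hazard}")
    rng = np.random.default_rng(seed)
    rows = []
    for pen in roster.itertuples(index=False):
        if hazard <= 0.0:
            continue
        day = int(rng.geometric(hazard))
        if day <= config.n_days:
            rows.append({"pen_id": pen.pen_id, "event_day": day})
    return pd.DataFrame(rows, columns=["pen_id", "event_day"])


def assign_events_from_counts(
    roster: pd.DataFrame,
    counts=STUDY_EVENT_PAIR_COUNTS,
    seed=None,
    day_range: tuple[int, int] = (21, 56),
) -> pd.DataFrame:
    """Designate event pens matching per-treatment-combination counts.

    ``counts`` is a sequence aligned with ``TREATMENT_COMBINATIONS`` (or a
    mapping from combination tuples to counts); event days are drawn uniformly
    in ``day_range``.  Useful for reproducing a realized event pattern.
    """
    rng = np.random.default_rng(seed)
    if not isinstance(counts, dict):
        counts = dict(zip(TREATMENT_COMBINATIONS, counts))
    lo, hi = day_range
    rows = []
    for combo, count in counts.items():
        if count == 0:
            continue
        tail, straw, stock = combo
        pool = roster[
            (roster["tail"] == tail) & (roster["straw"] == straw) & (roster["stock"] == stock)
        ]
        if len(pool) < count:
            raise ValueError(
                f"roster has only {len(pool)} pens for combination {combo}, need {count}"
            )
        # greedy draw that leaves at least one event-free pen in every
        # (batch, combination) cell so a matched control always exists
        cell_free = pool.groupby("batch")["pen_id"].count().to_dict()
        order = rng.permutation(pool["pen_id"].to_numpy())
        batch_of = dict(zip(pool["pen_id"], pool["batch"]))
        chosen = []
        for pen_id in order:
            if len(chosen) == count:
                break
            if cell_free[batch_of[pen_id]] > 1:
                chosen.append(pen_id)
                cell_free[batch_of[pen_id]] -= 1
        if len(chosen) < count:  # relax the constraint if the roster is tight
            leftovers = [p for p in order if p not in chosen]
            chosen.extend(leftovers[: count - len(chosen)])
        for pen_id in chosen:
            rows.append({"pen_id": pen_id, "event_day": int(rng.integers(lo, hi + 1))})
    return pd.DataFrame(rows, columns=["pen_id", "event_day"])


# ---------------------------------------------------------------------------
# pulse streams
# ---------------------------------------------------------------------------


def quantize_sensor_hourly(sensor_hourly: pd.DataFrame, pulses_per_liter: float) -> pd.DataFrame:
    """Snap per-pig values onto the grid representable by integer pulses and
    integer activation counts, so a pulse stream can round-trip bit-exactly."""
    if pulses_per_liter <= 0:
        raise ValueError("pulses_per_liter must be > 0")
    df = sensor_hourly.copy()
    n = df["n_pigs"].to_numpy(dtype=float)
    pulses = np.rint(df["water"].to_numpy() * n * pulses_per_liter)
    acts = np.rint(df["activations"].to_numpy() * n)
    acts = np.where((acts == 0) & (pulses > 0), 1.0, acts)
    acts = np.minimum(acts, 3600.0)
    df["water"] = pulses / pulses_per_liter / n
    df["activations"] = acts / n
    return df


def emit_pulse_stream(
    sensor_hourly: pd.DataFrame,
    pulses_per_liter: float,
    seed=None,
    start_date: str = "2015-06-01",
) -> pd.DataFrame:
    """Decompose hourly sensor totals into start/stop flow events with pulses.

    Each sensor-hour becomes ``round(activations * n_pigs)`` one-second bouts
    at distinct start seconds whose pulse counts sum to
    ``round(water * n_pigs * pulses_per_liter)``.  Feeding a table through
    :func:`quantize_sensor_hourly` first makes the decomposition exact, and
    re-aggregating the stream through :mod:`penflow.ingest` then reproduces
    the table bit for bit.
    """
    if pulses_per_liter <= 0:
        raise ValueError(f"pulses_per_liter must be > 0, got {pulses_per_liter}")
    rng = np.random.default_rng(seed)
    origin = pd.Timestamp(start_date)
    rows = []
    for rec in sensor_hourly.itertuples(index=False):
        n_pigs = float(rec.n_pigs)
        n_act = int(round(rec.activations * n_pigs))
        pulses_total = int(round(rec.water * n_pigs * pulses_per_liter))
        if n_act > 3600:
            raise ValueError(
                f"{n_act} activations cannot fit distinct start seconds in one hour"
            )
        if n_act == 0:
            if pulses_total > 0:
                raise ValueError(
                    "hour has pulses but zero activations; quantize the table first"
                )
            continue
        starts = np.sort(rng.choice(3600, size=n_act, replace=False))
        bout_pulses = rng.multinomial(pulses_total, np.full(n_act, 1.0 / n_act))
        base = origin + pd.Timedelta(days=int(rec.day) - 1, hours=int(rec.hour))
        for s, p in zip(starts, bout_pulses):
            ts = base + pd.Timedelta(seconds=int(s))
            rows.append(
                {
                    "sensor_id": f"{rec.pen_id}:{rec.location}",
                    "location": rec.location,
                    "start": ts,
                    "stop": ts,
                    "pulses": int(p),
                }
            )
    return pd.DataFrame(rows, columns=["sensor_id", "location", "start", "stop", "pulses"])
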