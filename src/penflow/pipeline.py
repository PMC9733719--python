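"""End-to-end orchestration: simulate -> ingest -> clean -> model -> analyses.

Every intermediate table is written as CSV with a one-line ``#`` schema
header recording the seed, and a Markdown report summarizes the fitted
parameters, period contrasts, location table and event effects.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cleaning, diurnal, events, ingest, locations, periods, synthetic
from .config import PipelineConfig

logger = logging.getLogger(__name__)


def write_table(df: pd.DataFrame, path: Path, seed: int) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# penflow table seed={seed} columns={','.join(map(str, df.columns))}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage and return the results bundle.

    Any stage failure is re-raised annotated with the stage name.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    rng = np.random.default_rng(seed)
    results: dict = {"seed": seed, "out_dir": str(out_dir)}
    stage = "setup"
    try:
        stage = "simulate"
        roster = synthetic.generate_pen_roster(
            config.n_per_combination, config.batches, rng.integers(2**31)
        )
        events_df = synthetic.schedule_tail_events(roster, config.generator, rng.integers(2**31))
        pen_hourly, _truth = synthetic.simulate_pen_hourly(
            roster, config.generator, rng.integers(2**31), events=events_df
        )
        sensor_hourly = synthetic.split_sensors(pen_hourly, config.generator, rng.integers(2**31))
        sensor_hourly, anomaly_labels = synthetic.inject_anomalies(
            sensor_hourly, config.generator, rng.integers(2**31)
        )
        logger.info(
            "simulated %d pens, %d sensor-hours, %d events, %d anomalies",
            len(roster), len(sensor_hourly), len(events_df), len(anomaly_labels),
        )
        write_table(roster, out_dir / "roster.csv", seed)
        write_table(events_df, out_dir / "tail_events.csv", seed)
        write_table(anomaly_labels, out_dir / "anomaly_labels.csv", seed)

        stage = "ingest"
        sensor_hourly = synthetic.quantize_sensor_hourly(sensor_hourly, config.pulses_per_liter)
        pulse_stream = synthetic.emit_pulse_stream(
            sensor_hourly, config.pulses_per_liter, rng.integers(2**31)
        )
        calibrations = ingest.uniform_calibrations(roster, config.pulses_per_liter)
        last_day = dict(zip(events_df["pen_id"], events_df["event_day"]))
        sensor_hourly = ingest.aggregate_hourly(
            pulse_stream, calibrations, roster, config.generator.n_days,
            last_day_by_pen=last_day,
        )
        pen_table = ingest.pen_level(sensor_hourly)
        write_table(sensor_hourly, out_dir / "sensor_hourly.csv", seed)
        write_table(pen_table, out_dir / "pen_hourly.csv", seed)

        stage = "clean"
        if config.clean:
            pen_table, report = cleaning.clean_dataset(pen_table, roster, k=config.cleaning_k)
            sensor_hourly = cleaning.apply_flags_to_sensors(sensor_hourly, report)
            results["cleaning"] = {r: report.counts[r] for r in report.counts}
            write_table(report.flags, out_dir / "cleaning_flags.csv", seed)
            logger.info(
                "cleaning: %s",
                {r: round(c["fraction_flagged"], 5) for r, c in report.counts.items()},
            )

        # analyses of normal use run on never-event pens only
        event_pens = set(events_df["pen_id"])
        normal = pen_table[~pen_table["pen_id"].isin(event_pens)]
        normal_sensors = sensor_hourly[~sensor_hourly["pen_id"].isin(event_pens)]

        stage = "fit-diurnal"
        fits = {}
        for response in ("water", "activations"):
            fit = diurnal.fit_harmonic_mixed(normal, response)
            fits[response] = fit
            results[f"diurnal_{response}"] = {
                "mean0": fit.mean0,
                "trend": fit.trend,
                "amplitudes": fit.amplitudes,
                "phases": fit.phases,
                "rho": fit.rho,
            }
        results["daily_total_mid"] = diurnal.daily_total(
            fits["water"], (1 + config.generator.n_days) / 2, variance_correction=True
        )

        if config.run_periods:
            stage = "analyze-periods"
            pfits = {}
            for response in ("water", "activations"):
                pfit = periods.fit_period_model(normal, roster, response)
                pfits[response] = pfit
                entry = {"terms": pfit.terms}
                if pfit.retained("stock"):
                    entry["contrasts"] = periods.period_contrasts(
                        pfit, at_week=config.generator.reference_week
                    ).to_dict("records")
                entry["week1_means"] = periods.period_marginal_means(pfit, 1.0).to_dict("records")
                results[f"periods_{response}"] = entry
            results["low_share"] = {
                r: vars(periods.low_period_share_test(normal, roster, r))["pvalue"]
                for r in ("water", "activations")
            }

        if config.run_locations:
            stage = "analyze-locations"
            summaries = locations.location_means(normal_sensors, roster)
            write_table(summaries, out_dir / "location_summaries.csv", seed)
            results["locations"] = {
                r: locations.location_table(summaries, r).to_dict("records")
                for r in ("water", "activations")
            }

        if config.run_events and len(events_df):
            stage = "analyze-events"
            pairs = events.match_pairs(events_df, roster)
            if len(pairs):
                summaries = events.window_summaries(pen_table, pairs)
                write_table(pairs, out_dir / "matched_pairs.csv", seed)
                write_table(summaries, out_dir / "event_summaries.csv", seed)
                n_complete = events.complete_pairs(summaries)["event_id"].nunique()
                results["events"] = {"n_pairs": int(len(pairs)), "n_complete": int(n_complete)}
                if n_complete >= 10:
                    efit = events.fit_event_model(summaries, "mean", "water")
                    results["events"]["water_mean_contrasts"] = events.event_contrasts(
                        efit
                    ).to_dict("records")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_path = out_dir / "report.md"
    report_path.write_text(render_report(results))
    results["report"] = str(report_path)
    return results


def render_report(results: dict) -> str:
    lines = ["# penflow run report", "", f"seed: {results.get('seed')}", ""]
    for response in ("water", "activations"):
        key = f"diurnal_{response}"
        if key in results:
            d = results[key]
            lines += [
                f"## Diurnal model ({response})",
                "",
                f"- initial mean (sqrt scale): {d['mean0']:.4f}",
                f"- daily trend (sqrt scale): {d['trend']:.6f}",
                f"- amplitudes: {', '.join(f'{a:.4f}' for a in d['amplitudes'])}",
                f"- phases: {', '.join(f'{c:.3f}' for c in d['phases'])}",
                f"- AR(1) rho: {d['rho']:.3f}",
                "",
            ]
    if "daily_total_mid" in results:
        lines += [f"Mid-study daily water use: {results['daily_total_mid']:.2f} L/pig/day", ""]
    if "cleaning" in results:
        lines += ["## Cleaning", ""]
        for r, c in results["cleaning"].items():
            lines.append(
                f"- {r}: {c['n_flagged']} flagged ({100 * c['fraction_flagged']:.2f}%), "
                f"{c['n_retained']} retained"
            )
        lines.append("")
    for response in ("water", "activations"):
        key = f"periods_{response}"
        if key in results:
            lines += [f"## Period model ({response})", ""]
            lines.append(f"- retained terms: {', '.join(results[key]['terms'])}")
            for rec in results[key].get("week1_means", []):
                lines.append(f"- week-1 {rec['period']}: {rec['mean']:.3f}")
            for rec in results[key].get("contrasts", []):
                lines.append(
                    f"- {rec['period']} low-high difference: "
                    f"{rec['diff_low_minus_high']:.4f} (SE {rec['se_diff']:.4f})"
                )
            lines.append("")
    if "locations" in results:
        lines += ["## Drinker location (paired F vs OF)", ""]
        for r, table in results["locations"].items():
            for rec in table:
                lines.append(
                    f"- {r} {rec['subset']}: F {rec['mean_f']:.3f}, OF {rec['mean_of']:.3f}, "
                    f"diff {rec['mean_diff']:.3f}, p={rec['pvalue']:.3g}"
                )
        lines.append("")
    if "events" in results:
        ev = results["events"]
        lines += [
            "## Tail-damage matched pairs",
            "",
            f"- pairs: {ev['n_pairs']} ({ev['n_complete']} with full windows)",
        ]
        for rec in ev.get("water_mean_contrasts", []):
            lines.append(
                f"- {rec['period']} case-control water mean diff: "
                f"{rec['diff_case_minus_control']:.4f}"
            )
        lines.append("")
    return "\n".join(lines)
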