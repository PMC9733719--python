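"""Feeder-side (F) vs opposite-side (OF) drinking-cup comparison.

Sensor-level hourly data are collapsed to one mean per pen and location, and
the two locations are compared with paired Wilcoxon signed-rank tests —
across all pens, per batch, or per stocking level.  Pens that switch cup
preference during the study are kept as-is; no multiplicity correction is
applied across the subset tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def location_means(sensor_hourly: pd.DataFrame, roster: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per pen: mean hourly water and activations for each cup.

    Means are taken over the pen's observed (non-missing) hours per location.
    Pens missing one location entirely are excluded with a log entry.
    """
    df = sensor_hourly
    means = (
        df.groupby(["pen_id", "location"], observed=True)[["water", "activations"]]
        .mean()
        .unstack("location")
    )
    means.columns = [f"{resp}_{loc.lower()}" for resp, loc in means.columns]
    needed = ["water_f", "water_of", "activations_f", "activations_of"]
    missing = [c for c in needed if c not in means.columns]
    if missing:
        raise ValueError(f"sensor data lack location columns: {missing}")
    bad = means[needed].isna().any(axis=1)
    for pen in means.index[bad]:
        logger.warning("pen %s excluded from location summary: missing a location mean", pen)
    out = means.loc[~bad, needed].reset_index()
    if roster is not None:
        out = out.merge(
            roster[["pen_id", "batch", "stock"]], on="pen_id", how="left", validate="1:1"
        )
    return out


@dataclass
class LocationTestResult:
    response: str
    n: int
    mean_f: float
    mean_of: float
    mean_diff: float
    statistic: float
    pvalue: float
    method: str
    degenerate: bool = False


def paired_location_test(
    summaries: pd.DataFrame, response: str = "water", subset=None
) -> LocationTestResult:
    """Two-sided Wilcoxon signed-rank test on per-pen (F - OF) differences.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 non-zero pairs, the normal approximation with continuity
    correction otherwise.  If every difference is zero the test is degenerate
    and reported as such (p = NaN) rather than raising.
    """
    df = summaries if subset is None else summaries.loc[subset]
    if len(df) < 2:
        raise ValueError("need >= 2 paired pens")
    f = df[f"{response}_f"].to_numpy(dtype=float)
    of = df[f"{response}_of"].to_numpy(dtype=float)
    diffs = f - of
    nonzero = diffs[diffs != 0.0]
    if len(nonzero) == 0:
        logger.warning("all %s F-OF differences are zero; signed-rank test degenerate", response)
        return LocationTestResult(
            response, len(df), float(f.mean()), float(of.mean()), 0.0,
            float("nan"), float("nan"), "degenerate", degenerate=True,
        )
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(
        diffs, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return LocationTestResult(
        response=response,
        n=int(len(df)),
        mean_f=float(f.mean()),
        mean_of=float(of.mean()),
        mean_diff=float(diffs.mean()),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method=method,
    )


def location_table(summaries: pd.DataFrame, response: str = "water") -> pd.DataFrame:
    """All-pens, per-batch and per-stocking-level paired tests in one table."""
    rows = []

    def add(label, subset_mask):
        sub = summaries if subset_mask is None else summaries.loc[subset_mask]
        if len(sub) < 2:
            return
        r = paired_location_test(summaries, response, subset_mask)
        rows.append(
            {
                "subset": label,
                "n": r.n,
                "mean_f": r.mean_f,
                "mean_of": r.mean_of,
                "mean_diff": r.mean_diff,
                "pvalue": r.pvalue,
            }
        )

    add("all", None)
    if "batch" in summaries.columns:
        for batch in sorted(summaries["batch"].dropna().unique()):
            add(f"batch {int(batch)}", summaries["batch"] == batch)
    if "stock" in summaries.columns:
        for stock in sorted(summaries["stock"].dropna().unique()):
            add(f"stock {stock}", summaries["stock"] == stock)
    return pd.DataFrame(rows)
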