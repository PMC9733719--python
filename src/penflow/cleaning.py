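"""Outlier-hour removal with a per-batch harmonic OLS model and a k-SD rule.

Each batch is fit separately with an ordinary least-squares model of the
sqrt-transformed response on day, three sine/cosine harmonic pairs, and
day x harmonic interactions (no random effects, no AR(1)).  Observation
hours whose sqrt-scale value deviates from the fitted value by strictly
more than ``k`` batch-wide residual standard deviations are flagged and
blanked.  One pass only: the model is not refit after removal.

The sqrt scale mirrors the analysis models; pass ``transform="identity"``
to clean on the raw scale instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diurnal import build_harmonic_design

logger = logging.getLogger(__name__)

RESPONSES = ("water", "activations")


@dataclass
class CleaningReport:
    """Flag counts per response, per-batch residual SDs, and the flag mask."""

    k: float
    counts: dict = field(default_factory=dict)       # response -> {n_flagged, n_retained, fraction_flagged}
    batch_resid_sd: dict = field(default_factory=dict)  # (response, batch) -> SD
    flags: pd.DataFrame | None = None                # pen_id, batch, day, hour, response

    def fraction_flagged(self, response: str) -> float:
        return self.counts[response]["fraction_flagged"]


def fit_cleaning_model(
    batch_pen_hourly: pd.DataFrame, response: str, transform: str = "sqrt"
) -> tuple[np.ndarray, float]:
    """OLS fit of one batch's (transformed) response on the harmonic design.

    Returns fitted values for every row and the batch-wide residual SD.
    """
    df = batch_pen_hourly
    y = df[response].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError(f"{response} contains negative values")
    if transform == "sqrt":
        y = np.sqrt(y)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    X = build_harmonic_design(df).to_numpy()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} rows cannot identify {p} parameters")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    resid_sd = float(np.sqrt(resid @ resid / (n - p)))
    return fitted, resid_sd


def clean_dataset(
    pen_hourly: pd.DataFrame,
    roster: pd.DataFrame,
    k: float = 4.0,
    responses=RESPONSES,
    transform: str = "sqrt",
) -> tuple[pd.DataFrame, CleaningReport]:
    """Blank observation hours deviating more than ``k`` residual SDs.

    Cleaning runs independently per response (masks may differ) and per
    batch.  Flagged cells are set to NaN in the returned copy; the report
    carries the mask so sensor-level data can be cleaned consistently.
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    df = pen_hourly.copy()
    if "batch" not in df.columns:
        df = df.merge(roster[["pen_id", "batch"]], on="pen_id", how="left", validate="m:1")
    if df["batch"].isna().any():
        unknown = df.loc[df["batch"].isna(), "pen_id"].unique()
        raise ValueError(f"pens not in roster: {list(unknown)[:5]}")
    report = CleaningReport(k=k)
    flag_frames = []
    for response in responses:
        flagged_total = 0
        n_total = int(df[response].notna().sum())
        flag_mask = np.zeros(len(df), dtype=bool)
        for batch, idx in df.groupby("batch").groups.items():
            sub = df.loc[idx]
            ok = sub[response].notna()
            sub = sub.loc[ok]
            fitted, resid_sd = fit_cleaning_model(sub, response, transform)
            y = sub[response].to_numpy(dtype=float)
            if transform == "sqrt":
                y = np.sqrt(y)
            dev = np.abs(y - fitted)
            bad = dev > k * resid_sd  # strictly more than k SDs
            report.batch_resid_sd[(response, batch)] = resid_sd
            flag_mask[df.index.get_indexer(sub.index[bad])] = True
            flagged_total += int(bad.sum())
            logger.info(
                "cleaning %s batch %s: %d/%d flagged (resid SD %.4f)",
                response, batch, int(bad.sum()), len(sub), resid_sd,
            )
        report.counts[response] = {
            "n_flagged": flagged_total,
            "n_retained": n_total - flagged_total,
            "fraction_flagged": flagged_total / n_total if n_total else 0.0,
        }
        flags = df.loc[flag_mask, ["pen_id", "batch", "day", "hour"]].copy()
        flags["response"] = response
        flag_frames.append(flags)
        df.loc[flag_mask, response] = np.nan
    report.flags = (
        pd.concat(flag_frames, ignore_index=True)
        if flag_frames
        else pd.DataFrame(columns=["pen_id", "batch", "day", "hour", "response"])
    )
    if "batch" not in pen_hourly.columns:
        df = df.drop(columns="batch")
    return df, report


def apply_flags_to_sensors(
    sensor_hourly: pd.DataFrame, report: CleaningReport
) -> pd.DataFrame:
    """Blank sensor-level cells for every pen-hour flagged at pen level."""
    df = sensor_hourly.copy()
    if report.flags is None or report.flags.empty:
        return df
    for response, flags in report.flags.groupby("response"):
        key = pd.MultiIndex.from_frame(flags[["pen_id", "day", "hour"]])
        rows = pd.MultiIndex.from_frame(df[["pen_id", "day", "hour"]])
        df.loc[rows.isin(key), response] = np.nan
    return df
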