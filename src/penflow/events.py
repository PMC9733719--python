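"""Matched-pair analysis of drinker use around tail-damage events.

Each event pen is paired with a control pen from the same batch with the
same three treatment levels and no event of its own before the case's event
day plus seven days; among eligible controls the nearest room position wins
(ties to the lower position).  Pairs contribute the last three days before
the event and the event day itself (day offsets -3..0), summarized per time
period as total, minimum, mean and maximum of the hourly values, and
modeled with a pen-type x period x day x stocking mixed model on the
(sqrt-transformed, except totals) summary statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats

from .config import PERIODS
from .periods import PERIOD_OF_HOUR, _term_factors, lrt

logger = logging.getLogger(__name__)

RESPONSES = ("water", "activations")
STATISTICS = ("total", "min", "mean", "max")
DAY_OFFSETS = (-3, -2, -1, 0)
#: hours per period: low spans 12, each peak 6
PERIOD_HOURS = {p: int((PERIOD_OF_HOUR == p).sum()) for p in set(PERIOD_OF_HOUR)}


def match_pairs(events: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    """Pair each event pen with its nearest eligible control pen.

    Eligibility: same batch and (tail, straw, stock) levels, not the case
    pen, and no own event earlier than ``day0 + 7``.  Events without an
    eligible control are dropped with a logged reason, never raised.
    Controls may be reused across events (reuse is logged).
    """
    meta = roster.set_index("pen_id")
    event_day = dict(zip(events["pen_id"], events["event_day"]))
    pairs = []
    used_controls: dict[str, list[str]] = {}
    for ev_idx, ev in enumerate(
        events.sort_values(["event_day", "pen_id"]).itertuples(index=False), start=1
    ):
        if ev.pen_id not in meta.index:
            logger.warning("event pen %s not in roster; dropped", ev.pen_id)
            continue
        case = meta.loc[ev.pen_id]
        day0 = int(ev.event_day)
        candidates = roster[
            (roster["batch"] == case["batch"])
            & (roster["tail"] == case["tail"])
            & (roster["straw"] == case["straw"])
            & (roster["stock"] == case["stock"])
            & (roster["pen_id"] != ev.pen_id)
        ]
        eligible = candidates[
            [
                (pid not in event_day) or (event_day[pid] >= day0 + 7)
                for pid in candidates["pen_id"]
            ]
        ]
        if eligible.empty:
            logger.warning(
                "event pen %s (day %d): no eligible control; dropped", ev.pen_id, day0
            )
            continue
        # prefer pens never scored with an event; pens whose own event comes
        # >= 7 days later satisfy the letter of the rule but are a fallback
        never = eligible[[pid not in event_day for pid in eligible["pen_id"]]]
        if not never.empty:
            eligible = never
        dist = (eligible["position"] - case["position"]).abs()
        chosen = eligible.assign(_d=dist).sort_values(["_d", "position"]).iloc[0]
        control = chosen["pen_id"]
        if control in used_controls:
            logger.info(
                "control pen %s reused for %s (already paired with %s)",
                control, ev.pen_id, used_controls[control],
            )
        used_controls.setdefault(control, []).append(ev.pen_id)
        pairs.append(
            {
                "event_id": f"e{ev_idx:02d}",
                "case_pen": ev.pen_id,
                "control_pen": control,
                "day0": day0,
                "batch": case["batch"],
                "tail": case["tail"],
                "straw": case["straw"],
                "stock": case["stock"],
            }
        )
    return pd.DataFrame(
        pairs,
        columns=[
            "event_id", "case_pen", "control_pen", "day0",
            "batch", "tail", "straw", "stock",
        ],
    )


def window_summaries(pen_hourly: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Per pen x day-offset x period summary statistics over the event window.

    Returns one row per (pair, pen, day offset -3..0, period) with total,
    min, mean and max of the hourly values for both responses, plus a
    ``complete`` flag (False when any expected hour is missing).
    """
    indexed = pen_hourly.set_index(["pen_id", "day"]).sort_index()
    rows = []
    for pair in pairs.itertuples(index=False):
        for pen_type, pen_id in (("case", pair.case_pen), ("control", pair.control_pen)):
            for off in DAY_OFFSETS:
                day = pair.day0 + off
                try:
                    sub = indexed.loc[(pen_id, day)]
                except KeyError:
                    sub = None
                for period in PERIODS:
                    expected = PERIOD_HOURS[period]
                    rec = {
                        "event_id": pair.event_id,
                        "pen_id": pen_id,
                        "pen_type": pen_type,
                        "day_off": off,
                        "period": period,
                        "day0": pair.day0,
                        "stock": pair.stock,
                        "batch": pair.batch,
                    }
                    if sub is None or day < 1:
                        for resp in RESPONSES:
                            for stat in STATISTICS:
                                rec[f"{resp}_{stat}"] = np.nan
                        rec["complete"] = False
                    else:
                        in_period = sub.loc[PERIOD_OF_HOUR[sub["hour"].to_numpy(dtype=int)] == period]
                        complete = True
                        for resp in RESPONSES:
                            vals = in_period[resp].dropna().to_numpy()
                            if len(vals) < expected:
                                complete = False
                            if len(vals) == 0:
                                for stat in STATISTICS:
                                    rec[f"{resp}_{stat}"] = np.nan
                                continue
                            rec[f"{resp}_total"] = float(vals.sum())
                            rec[f"{resp}_min"] = float(vals.min())
                            rec[f"{resp}_mean"] = float(vals.mean())
                            rec[f"{resp}_max"] = float(vals.max())
                        rec["complete"] = complete
                    rows.append(rec)
    out = pd.DataFrame(rows)
    incomplete = out.loc[~out["complete"], "event_id"].unique()
    if len(incomplete):
        logger.warning("pairs with incomplete windows: %s", list(incomplete))
    return out


def complete_pairs(summaries: pd.DataFrame) -> pd.DataFrame:
    """Drop every pair that has any incomplete cell."""
    bad = set(summaries.loc[~summaries["complete"], "event_id"])
    return summaries[~summaries["event_id"].isin(bad)].copy()


def _event_terms() -> list[str]:
    factors = ["C(pen_type)", "C(period)", "C(day_off)", "C(stock)"]
    terms = list(factors) + ["age0"]
    for i in range(len(factors)):
        for j in range(i + 1, len(factors)):
            terms.append(f"{factors[i]}:{factors[j]}")
    return terms


@dataclass
class EventModelFit:
    response: str
    statistic: str
    result: object
    terms: list[str]
    elimination_log: list[dict] = field(default_factory=list)
    data: pd.DataFrame | None = None
    transform: str = "sqrt"

    def retained(self, factor: str) -> bool:
        return any(factor in _term_factors(t) for t in self.terms)


def _fit_event_mixed(data: pd.DataFrame, terms: list[str], reml: bool):
    formula = "y ~ " + " + ".join(terms) if terms else "y ~ 1"
    model = smf.mixedlm(
        formula,
        data,
        groups=data["event_id"],
        re_formula="1",
        vc_formula={"pen": "0 + C(pen_id)"},
    )
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml, method=["lbfgs", "powell"], maxiter=200)
    if not result.converged:
        logger.warning("event model (%s) did not fully converge", formula)
    return result


def fit_event_model(
    summaries: pd.DataFrame,
    statistic: str = "mean",
    response: str = "water",
    alpha: float = 0.05,
    eliminate: bool = True,
) -> EventModelFit:
    """Mixed model of one summary statistic with pen-type/period/day/stock terms.

    Totals stay on the observed scale; min, mean and max are sqrt-transformed.
    Random structure: an intercept per event (pair) and per pen within event.
    Backward elimination (when enabled) mirrors the period model: LRTs under
    ML with marginality respected, REML for the final fit.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    data = complete_pairs(summaries).copy()
    n_pairs = data["event_id"].nunique()
    if n_pairs < 10:
        warnings.warn(
            f"only {n_pairs} complete pairs; below the documented floor of 10",
            stacklevel=2,
        )
    col = f"{response}_{statistic}"
    transform = "identity" if statistic == "total" else "sqrt"
    y = data[col].to_numpy(dtype=float)
    if transform == "sqrt":
        if (y < 0).any():
            raise ValueError(f"{col} contains negative values")
        y = np.sqrt(y)
    data["y"] = y
    data["age0"] = data["day0"].astype(float)
    for covariate in ("pen_type", "period", "stock"):
        if data[covariate].nunique() < 2 and covariate != "stock":
            raise ValueError(f"design is degenerate: {covariate} has a single level")
    terms = _event_terms()
    if data["stock"].nunique() < 2:
        terms = [t for t in terms if "stock" not in _term_factors(t)]
    log_entries: list[dict] = []
    if eliminate:
        current = _fit_event_mixed(data, terms, reml=False)
        while True:
            candidates = [
                t
                for t in terms
                if not any(
                    _term_factors(t) < _term_factors(other) for other in terms if other != t
                )
            ]
            tested = []
            for cand in candidates:
                reduced_terms = [t for t in terms if t != cand]
                reduced = _fit_event_mixed(data, reduced_terms, reml=False)
                chi2, df, p = lrt(current, reduced)
                tested.append((p, chi2, df, cand, reduced, reduced_terms))
            tested.sort(key=lambda x: -x[0])
            p, chi2, df, cand, reduced, reduced_terms = tested[0]
            if p >= alpha:
                log_entries.append(
                    {"term": cand, "chi2": chi2, "df": df, "p": p, "action": "removed"}
                )
                terms = reduced_terms
                current = reduced
                if not terms:
                    break
            else:
                for pp, cc, dd, tt, *_ in tested:
                    log_entries.append(
                        {"term": tt, "chi2": cc, "df": dd, "p": pp, "action": "retained"}
                    )
                break
    final = _fit_event_mixed(data, terms, reml=True)
    return EventModelFit(
        response=response,
        statistic=statistic,
        result=final,
        terms=terms,
        elimination_log=log_entries,
        data=data,
        transform=transform,
    )


def event_contrasts(fit: EventModelFit) -> pd.DataFrame:
    """Back-transformed case-minus-control difference per period.

    Marginal means are evaluated at day offset -3 (effects are assumed
    day-constant unless a pen-type x day term was retained), the high
    stocking level, and the mean age; sqrt-scale means are squared before
    differencing (totals are differenced directly).
    """
    data = fit.data
    if not fit.retained("pen_type"):
        return pd.DataFrame(
            {
                "period": list(PERIODS),
                "diff_case_minus_control": [0.0] * len(PERIODS),
                "se_diff": [np.nan] * len(PERIODS),
                "note": ["pen_type eliminated"] * len(PERIODS),
            }
        )
    design_info = fit.result.model.data.design_info
    fe = fit.result.fe_params
    fe_cov = np.asarray(fit.result.cov_params())[: len(fe), : len(fe)]
    age_ref = float(data["age0"].mean())
    stock_ref = sorted(data["stock"].unique())[0]
    rows = []
    for period in PERIODS:
        X = {}
        for pen_type in ("case", "control"):
            new = pd.DataFrame(
                {
                    "pen_type": [pen_type],
                    "period": [period],
                    "day_off": [-3],
                    "stock": [stock_ref],
                    "age0": [age_ref],
                }
            )
            (mat,) = build_design_matrices([design_info], new)
            X[pen_type] = np.asarray(mat)[0]
        m_case = float(X["case"] @ np.asarray(fe))
        m_ctrl = float(X["control"] @ np.asarray(fe))
        if fit.transform == "sqrt":
            diff = m_case**2 - m_ctrl**2
            grad = 2 * m_case * X["case"] - 2 * m_ctrl * X["control"]
        else:
            diff = m_case - m_ctrl
            grad = X["case"] - X["control"]
        se = float(np.sqrt(grad @ fe_cov @ grad))
        rows.append(
            {
                "period": period,
                "mean_case": m_case**2 if fit.transform == "sqrt" else m_case,
                "mean_control": m_ctrl**2 if fit.transform == "sqrt" else m_ctrl,
                "diff_case_minus_control": diff,
                "se_diff": se,
                "note": "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# low-period share tests
# ---------------------------------------------------------------------------


@dataclass
class EventShareTests:
    response: str
    pen_type_statistic: float
    pen_type_pvalue: float
    day_statistic: float
    day_pvalue: float
    pen_shares: pd.DataFrame
    pen_day_shares: pd.DataFrame


def low_share_event_tests(
    pen_hourly: pd.DataFrame, pairs: pd.DataFrame, response: str = "water"
) -> EventShareTests:
    """Low-period share around events: Mann-Whitney by pen type, Kruskal-Wallis by day.

    Shares are the fraction of a pen's window use falling in the low period —
    one observation per pen for the pen-type test, one per pen-day for the
    day test.  Degenerate groups raise.
    """
    indexed = pen_hourly.copy()
    indexed["period"] = PERIOD_OF_HOUR[indexed["hour"].to_numpy(dtype=int)]
    pen_day_rows = []
    for pair in pairs.itertuples(index=False):
        for pen_type, pen_id in (("case", pair.case_pen), ("control", pair.control_pen)):
            window_days = [pair.day0 + off for off in DAY_OFFSETS]
            sub = indexed[(indexed["pen_id"] == pen_id) & (indexed["day"].isin(window_days))]
            for day in window_days:
                day_sub = sub[sub["day"] == day].dropna(subset=[response])
                total = day_sub[response].sum()
                low = day_sub.loc[day_sub["period"] == "low", response].sum()
                pen_day_rows.append(
                    {
                        "event_id": pair.event_id,
                        "pen_id": pen_id,
                        "pen_type": pen_type,
                        "day_off": day - pair.day0,
                        "share_low": low / total if total > 0 else np.nan,
                    }
                )
    pen_day = pd.DataFrame(pen_day_rows).dropna(subset=["share_low"])
    pen = (
        pen_day.groupby(["event_id", "pen_id", "pen_type"])["share_low"].mean().reset_index()
    )
    groups = [g["share_low"].to_numpy() for _, g in pen.groupby("pen_type")]
    if len(groups) != 2 or min(len(g) for g in groups) < 2:
        raise ValueError("pen-type share test needs two groups with >= 2 pens each")
    mw = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    day_groups = [g["share_low"].to_numpy() for _, g in pen_day.groupby("day_off")]
    if len(day_groups) < 2 or min(len(g) for g in day_groups) < 2:
        raise ValueError("day share test needs >= 2 days with >= 2 observations")
    kw = stats.kruskal(*day_groups)
    return EventShareTests(
        response=response,
        pen_type_statistic=float(mw.statistic),
        pen_type_pvalue=float(mw.pvalue),
        day_statistic=float(kw.statistic),
        day_pvalue=float(kw.pvalue),
        pen_shares=pen,
        pen_day_shares=pen_day,
    )
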