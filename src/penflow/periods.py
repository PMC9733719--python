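"""Time-period segmentation and the period x week x treatment analysis.

Hours are segmented into three periods (low: 18:00-05:59, peak1:
06:00-11:59, peak2: 12:00-17:59).  The model works on sqrt-transformed
hourly values aggregated to (pen, week, period) cells, with a random pen
intercept and week-within-pen variance component, and is reduced by
stepwise backward elimination using likelihood-ratio tests under ML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats

from .config import PERIODS, PERIOD_LOW, PERIOD_PEAK1, PERIOD_PEAK2

logger = logging.getLogger(__name__)

#: hour (0-23) -> period label
PERIOD_OF_HOUR = np.array(
    [PERIOD_LOW] * 6 + [PERIOD_PEAK1] * 6 + [PERIOD_PEAK2] * 6 + [PERIOD_LOW] * 6,
    dtype=object,
)

TREATMENTS = ("tail", "straw", "stock")


def assign_period(hour: int) -> str:
    """Map a clock hour to its time period."""
    if not 0 <= int(hour) <= 23 or int(hour) != hour:
        raise ValueError(f"hour must be an integer in 0..23, got {hour!r}")
    return str(PERIOD_OF_HOUR[int(hour)])


def week_of_day(day):
    """1-based study week of a 1-based study day (days 1-7 -> week 1)."""
    return np.floor((np.asarray(day, dtype=float) - 1.0) / 7.0) + 1.0


def _term_factors(term: str) -> frozenset:
    return frozenset(f.replace("C(", "").replace(")", "") for f in term.split(":"))


def full_term_set() -> list[str]:
    """Fixed-effect terms of the unreduced model."""
    terms = ["C(period)", "week0", "C(period):week0"]
    for t in TREATMENTS:
        terms += [f"C({t})", f"C(period):C({t})", f"week0:C({t})", f"C(period):week0:C({t})"]
    return terms


def period_cells(pen_hourly: pd.DataFrame, roster: pd.DataFrame, response: str) -> pd.DataFrame:
    """Aggregate sqrt-scale hourly values to (pen, week, period) cell means."""
    df = pen_hourly.dropna(subset=[response]).copy()
    if (df[response] < 0).any():
        raise ValueError(f"{response} contains negative values")
    df["sqrt_y"] = np.sqrt(df[response].to_numpy())
    df["period"] = PERIOD_OF_HOUR[df["hour"].to_numpy(dtype=int)]
    df["week"] = week_of_day(df["day"].to_numpy())
    cells = (
        df.groupby(["pen_id", "week", "period"], observed=True)["sqrt_y"]
        .mean()
        .reset_index()
    )
    cells["week0"] = cells["week"] - 1.0
    meta_cols = ["pen_id", "batch", *TREATMENTS]
    cells = cells.merge(roster[meta_cols], on="pen_id", how="left", validate="m:1")
    if cells[list(TREATMENTS)].isna().any().any():
        missing = cells.loc[cells["tail"].isna(), "pen_id"].unique()
        raise ValueError(f"pens missing roster metadata: {list(missing)[:5]}")
    return cells


@dataclass
class PeriodModelFit:
    """Reduced period-model fit plus its elimination trail."""

    response: str
    result: object                      # statsmodels MixedLMResults (REML)
    terms: list[str]
    elimination_log: list[dict] = field(default_factory=list)
    cells: pd.DataFrame | None = None
    alpha: float = 0.05

    @property
    def fe_params(self):
        return self.result.fe_params

    def retained(self, factor: str) -> bool:
        return any(factor in _term_factors(t) for t in self.terms)


def _fit_mixed(cells: pd.DataFrame, terms: list[str], reml: bool):
    formula = "sqrt_y ~ " + " + ".join(terms) if terms else "sqrt_y ~ 1"
    model = smf.mixedlm(
        formula,
        cells,
        groups=cells["pen_id"],
        re_formula="1",
        vc_formula={"week": "0 + C(week)"},
    )
    with np.errstate(all="ignore"):
        result = model.fit(reml=reml, method=["lbfgs", "powell"], maxiter=200)
    if not result.converged:
        logger.warning("period model (%s) did not fully converge", formula)
    return result


def lrt(full_result, reduced_result) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square between two nested ML fits."""
    chi2 = 2.0 * (full_result.llf - reduced_result.llf)
    df = len(full_result.fe_params) - len(reduced_result.fe_params)
    if df < 1:
        raise ValueError("LRT requires the reduced model to drop >= 1 parameter")
    p = stats.chi2.sf(max(chi2, 0.0), df)
    return float(chi2), int(df), float(p)


def fit_period_model(
    pen_hourly: pd.DataFrame,
    roster: pd.DataFrame,
    response: str = "water",
    alpha: float = 0.05,
    eliminate: bool = True,
) -> PeriodModelFit:
    """Fit the period x week x treatment model with backward elimination.

    Elimination removes, among currently maximal terms (marginality respected:
    a term is untouchable while a higher-order interaction containing it is
    retained), the one with the largest LRT p-value, until every maximal term
    is significant at ``alpha``.  LRTs use ML; the final fit is REML.
    """
    cells = period_cells(pen_hourly, roster, response)
    terms = full_term_set()
    log_entries: list[dict] = []
    if eliminate:
        current = _fit_mixed(cells, terms, reml=False)
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
                reduced = _fit_mixed(cells, reduced_terms, reml=False)
                chi2, df, p = lrt(current, reduced)
                tested.append((p, chi2, df, cand, reduced, reduced_terms))
            tested.sort(key=lambda x: -x[0])
            p, chi2, df, cand, reduced, reduced_terms = tested[0]
            if p >= alpha:
                log_entries.append(
                    {"term": cand, "chi2": chi2, "df": df, "p": p, "action": "removed"}
                )
                logger.info("eliminated %s (chi2=%.2f, df=%d, p=%.3f)", cand, chi2, df, p)
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
    final = _fit_mixed(cells, terms, reml=True)
    return PeriodModelFit(
        response=response,
        result=final,
        terms=terms,
        elimination_log=log_entries,
        cells=cells,
        alpha=alpha,
    )


def period_contrasts(fit: PeriodModelFit, at_week: float = 5.0) -> pd.DataFrame:
    """Back-transformed period means per stocking level and their difference.

    Marginal sqrt-scale means are evaluated at ``at_week`` with the other
    treatments at their reference levels, then squared; the contrast is
    low minus high stocking.  Raises if the model retained no stocking term.
    """
    if not fit.retained("stock"):
        raise ValueError(
            "stocking-density terms were eliminated from the model; "
            "no stocking contrast is estimable"
        )
    design_info = fit.result.model.data.design_info
    fe = fit.fe_params
    fe_cov = np.asarray(fit.result.cov_params())[: len(fe), : len(fe)]
    rows = []
    for period in PERIODS:
        grid = {}
        for stock in ("high", "low"):
            new = pd.DataFrame(
                {
                    "period": [period],
                    "week0": [at_week - 1.0],
                    "tail": ["docked"],
                    "straw": ["with"],
                    "stock": [stock],
                }
            )
            (X,) = build_design_matrices([design_info], new)
            x = np.asarray(X)[0]
            m = float(x @ np.asarray(fe))
            var = float(x @ fe_cov @ x)
            grid[stock] = (m, var, x)
        m_hi, v_hi, x_hi = grid["high"]
        m_lo, v_lo, x_lo = grid["low"]
        dx = x_lo - x_hi
        var_d = float(dx @ fe_cov @ dx)
        diff_back = m_lo**2 - m_hi**2
        # delta method on (m_lo^2 - m_hi^2)
        grad = 2 * m_lo * x_lo - 2 * m_hi * x_hi
        se_back = float(np.sqrt(grad @ fe_cov @ grad))
        rows.append(
            {
                "period": period,
                "week": at_week,
                "sqrt_mean_high": m_hi,
                "sqrt_mean_low": m_lo,
                "mean_high": m_hi**2,
                "mean_low": m_lo**2,
                "diff_low_minus_high": diff_back,
                "se_diff": se_back,
                "sqrt_diff": m_lo - m_hi,
                "se_sqrt_diff": float(np.sqrt(var_d)),
            }
        )
    return pd.DataFrame(rows)


def period_marginal_means(fit: PeriodModelFit, at_week: float = 1.0) -> pd.DataFrame:
    """Back-transformed marginal period means at a given week (reference
    levels for any retained treatments)."""
    design_info = fit.result.model.data.design_info
    fe = fit.fe_params
    rows = []
    for period in PERIODS:
        new = pd.DataFrame(
            {
                "period": [period],
                "week0": [at_week - 1.0],
                "tail": ["docked"],
                "straw": ["with"],
                "stock": ["high"],
            }
        )
        (X,) = build_design_matrices([design_info], new)
        m = float(np.asarray(X)[0] @ np.asarray(fe))
        rows.append({"period": period, "week": at_week, "sqrt_mean": m, "mean": m**2})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# low-period shares
# ---------------------------------------------------------------------------


def period_shares(pen_hourly: pd.DataFrame, response: str = "water") -> pd.DataFrame:
    """Per-pen fraction of total use falling in each period (observed hours)."""
    df = pen_hourly.dropna(subset=[response]).copy()
    df["period"] = PERIOD_OF_HOUR[df["hour"].to_numpy(dtype=int)]
    totals = df.groupby(["pen_id", "period"], observed=True)[response].sum().unstack(
        fill_value=0.0
    )
    for p in PERIODS:
        if p not in totals:
            totals[p] = 0.0
    grand = totals.sum(axis=1)
    shares = totals[list(PERIODS)].div(grand, axis=0)
    shares.columns = [f"share_{p}" for p in PERIODS]
    return shares.reset_index()


@dataclass
class ShareTestResult:
    response: str
    group_col: str
    shares: pd.DataFrame
    medians: dict
    statistic: float
    pvalue: float
    method: str


def low_period_share_test(
    pen_hourly: pd.DataFrame,
    roster: pd.DataFrame,
    response: str = "water",
    group_col: str = "stock",
) -> ShareTestResult:
    """Mann-Whitney U test of the low-period use share between two groups.

    Exact null distribution when both groups have <= 25 pens, otherwise the
    normal approximation with tie correction.
    """
    shares = period_shares(pen_hourly, response).merge(
        roster[["pen_id", group_col]], on="pen_id", how="left", validate="1:1"
    )
    levels = sorted(shares[group_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"{group_col} must have exactly 2 levels, found {levels}")
    groups = [
        shares.loc[shares[group_col] == lvl, "share_low"].to_numpy() for lvl in levels
    ]
    if min(len(g) for g in groups) < 2:
        raise ValueError("each group needs >= 2 pens")
    method = "exact" if max(len(g) for g in groups) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method=method)
    medians = {lvl: float(np.median(g)) for lvl, g in zip(levels, groups)}
    return ShareTestResult(
        response=response,
        group_col=group_col,
        shares=shares,
        medians=medians,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method=method,
    )
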