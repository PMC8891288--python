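"""Association statistics for crossing-block success.

The battery relates compatibility indices to genetic distance,
heterozygosity, weather, and pollinating technician:

* Pearson correlation (two-sided t-based p);
* sequential (Type-I) ANOVA of rates on year / location / cross-combination;
* pooled-variance two-sample t with an optional Shapiro-Wilk normality check
  reported alongside (never silently substituting a rank test);
* weekly aggregation of daily weather over a species flowering window
  (rainfall and rainy days summed, the rest averaged; a day is rainy when
  rainfall strictly exceeds 0.5 mm);
* ordinary least-squares regression of weekly success rates on weather
  aggregates (no multiple-testing correction across parameters);
* one-way pollinator ANOVA with Tukey HSD pairwise comparisons at the 5%
  family-wise level;
* germination-rate ANOVA with Fisher LSD pairwise separation at 5%.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CorrelationResult",
    "TTestResult",
    "pearson_correlation",
    "anova",
    "two_sample_t",
    "weekly_aggregate",
    "weather_regression",
    "pollinator_effect",
    "germination_comparison",
    "RAINY_DAY_THRESHOLD_MM",
    "WEATHER_SUM_PARAMS",
]

#: A day counts as rainy when rainfall strictly exceeds this (mm).
RAINY_DAY_THRESHOLD_MM = 0.5

#: Daily weather parameters aggregated to weekly sums; all others use means.
WEATHER_SUM_PARAMS = ("rainfall", "rainy_days")

ALPHA = 0.05


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclasses.dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float
    df: float
    shapiro_x: tuple[float, float] | None = None  # (W, p)
    shapiro_y: tuple[float, float] | None = None


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic),
                             p_value=float(res.pvalue), n=len(x))


def anova(data: pd.DataFrame, response: str,
          factors: Sequence[str]) -> pd.DataFrame:
    """Sequential (Type-I) ANOVA of ``response`` on categorical ``factors``.

    Sums of squares are sequential in the order the factors are listed, so the
    order is part of the analysis definition.  Returns a table with df,
    sum_sq, mean_sq, F and p per source (including Residual).  Aliased
    (perfectly confounded) factors raise with their names.
    """
    if not factors:
        raise ValueError("at least one factor required")
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    formula = f"Q('{response}') ~ " + " + ".join(f"C(Q('{f}'))" for f in factors)
    fit = smf.ols(formula, data=data).fit()
    if fit.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    # detect aliasing: rank-deficient design means a factor is confounded
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError(f"aliased/confounded factors among {list(factors)}")
    table = sm.stats.anova_lm(fit, typ=1)
    table = table.rename(columns={"sum_sq": "sum_sq", "PR(>F)": "p_value"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    idx = {f"C(Q('{f}'))": f for f in factors}
    table.index = [idx.get(i, i) for i in table.index]
    return table[["df", "sum_sq", "mean_sq", "F", "p_value"]]


def two_sample_t(x: Sequence[float], y: Sequence[float], *,
                 check_normality: bool = False,
                 welch: bool = False) -> TTestResult:
    """Two-sided two-sample t test, pooled-variance by default.

    With ``check_normality`` a Shapiro-Wilk W and p are reported for each
    sample; the t test is run regardless (the normality check informs, it
    does not gate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    sw_x = sw_y = None
    if check_normality:
        wx = sps.shapiro(x)
        wy = sps.shapiro(y)
        sw_x = (float(wx.statistic), float(wx.pvalue))
        sw_y = (float(wy.statistic), float(wy.pvalue))
    return TTestResult(t=float(res.statistic), p_value=float(res.pvalue),
                       df=df, shapiro_x=sw_x, shapiro_y=sw_y)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def weekly_aggregate(daily: pd.DataFrame, *, anchor: str | pd.Timestamp,
                     n_weeks: int | None = None) -> pd.DataFrame:
    """Aggregate daily weather to flowering-window weeks.

    ``daily`` must have a ``date`` column plus numeric parameter columns;
    ``rainfall`` (mm) is required.  Weeks are consecutive 7-day blocks
    starting at ``anchor`` (the species-specific window start, e.g. the first
    week of August for D. rotundata at Ibadan).  Rainfall is summed and rainy
    days (> 0.5 mm, strict) counted; every other parameter is averaged.
    Weeks with more than 2 consecutive missing days are flagged
    ``incomplete``.
    """
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    anchor = pd.Timestamp(anchor)
    daily = daily[daily["date"] >= anchor]
    if daily.empty:
        raise ValueError("no daily records on/after the anchor date")
    daily["week"] = ((daily["date"] - anchor).dt.days // 7) + 1
    if n_weeks is not None:
        daily = daily[daily["week"] <= n_weeks]
    params = [c for c in daily.columns
              if c not in {"date", "week"} and pd.api.types.is_numeric_dtype(daily[c])]
    rows = []
    for week, grp in daily.groupby("week"):
        grp = grp.sort_values("date")
        expected = pd.date_range(anchor + pd.Timedelta(days=7 * (week - 1)),
                                 periods=7)
        present = set(grp["date"])
        gap, longest = 0, 0
        for day in expected:
            gap = 0 if day in present else gap + 1
            longest = max(longest, gap)
        row: dict[str, object] = {"week": int(week),
                                  "incomplete": longest > 2}
        for p in params:
            if p in WEATHER_SUM_PARAMS:
                row[p] = float(grp[p].sum())
            else:
                row[p] = float(grp[p].mean())
        row["rainy_days"] = int((grp["rainfall"] > RAINY_DAY_THRESHOLD_MM).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def weather_regression(success: Sequence[float], weekly: pd.DataFrame,
                       parameters: Sequence[str], *,
                       condition_limit: float = 1e8) -> pd.DataFrame:
    """OLS of weekly crossability rates on selected weekly weather aggregates.

    Returns one row per term (intercept + parameters) with coefficient,
    standard error, t and p.  Collinear predictor sets (design condition
    number beyond ``condition_limit``) raise, listing the columns.  No
    multiple-testing correction is applied across parameters.
    """
    y = np.asarray(success, dtype=float)
    X = weekly[list(parameters)].to_numpy(dtype=float)
    if len(y) <= len(parameters) + 1:
        raise ValueError("need more weeks than parameters + 1")
    const_cols = [p for p, col in zip(parameters, X.T) if np.ptp(col) == 0]
    if const_cols:
        raise ValueError(f"constant/collinear predictor(s): {const_cols}")
    Xc = sm.add_constant(X)
    if np.linalg.cond(Xc) > condition_limit:
        raise ValueError(f"collinear predictors among {list(parameters)}")
    fit = sm.OLS(y, Xc).fit()
    return pd.DataFrame({
        "term": ["intercept", *parameters],
        "coef": fit.params,
        "std_err": fit.bse,
        "t": fit.tvalues,
        "p_value": fit.pvalues,
    })


# ---------------------------------------------------------------------------
# pollinator and germination comparisons
# ---------------------------------------------------------------------------

def pollinator_effect(rates: pd.DataFrame, *, alpha: float = ALPHA
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way pollinator ANOVA plus Tukey HSD pairwise comparisons.

    ``rates`` needs columns ``pollinator``, ``combination`` and
    ``crossability_rate``, from a controlled design in which every technician
    worked the same cross-combinations at the same time.  Technicians whose
    combination sets are disjoint from the shared set violate that design and
    raise.  Returns (anova_table, tukey_table); ``reject`` in the Tukey table
    is at the family-wise ``alpha``.
    """
    pollinators = rates["pollinator"].unique()
    if len(pollinators) < 2:
        raise ValueError("need at least two pollinators")
    combo_sets = {p: set(g["combination"])
                  for p, g in rates.groupby("pollinator")}
    shared = set.intersection(*combo_sets.values())
    if not shared:
        raise ValueError("pollinators have no cross-combination in common; "
                         "the controlled-comparison design is violated")
    sub = rates[rates["combination"].isin(shared)]
    table = anova(sub, "crossability_rate", ["pollinator"])
    tukey = pairwise_tukeyhsd(sub["crossability_rate"].to_numpy(dtype=float),
                              sub["pollinator"].to_numpy(), alpha=alpha)
    pairs = list(itertools.combinations(tukey.groupsunique, 2))
    tukey_df = pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "meandiff": tukey.meandiffs,
        "p_adj": tukey.pvalues,
        "lower": tukey.confint[:, 0],
        "upper": tukey.confint[:, 1],
        "reject": tukey.reject,
    })
    return table, tukey_df


def _fisher_lsd(groups: Mapping[str, np.ndarray], mse: float, df_resid: float,
                alpha: float) -> pd.DataFrame:
    """All-pairs Fisher LSD: |mean_i - mean_j| vs t_{a/2,df}*sqrt(MSE*(1/ni+1/nj))."""
    tcrit = sps.t.ppf(1 - alpha / 2, df_resid)
    rows = []
    for (gi, xi), (gj, xj) in itertools.combinations(groups.items(), 2):
        diff = float(np.mean(xi) - np.mean(xj))
        lsd = float(tcrit * np.sqrt(mse * (1 / len(xi) + 1 / len(xj))))
        rows.append({"group1": gi, "group2": gj, "mean_diff": diff,
                     "lsd": lsd, "significant": abs(diff) > lsd})
    return pd.DataFrame(rows)


def germination_comparison(families: pd.DataFrame, *,
                           group: str = "cross_category",
                           alpha: float = ALPHA
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA of family germination rates across categories + Fisher LSD.

    ``families`` needs ``seeds_sown``, ``seeds_germinated`` and the ``group``
    column (cross category, species or year).  Family-level germination rates
    are the analysis unit.  Returns (anova_table, lsd_table); ``significant``
    marks pairs separated at the per-comparison ``alpha``.
    """
    df = families.copy()
    df["germination_rate"] = (100.0 * df["seeds_germinated"]
                              / df["seeds_sown"])
    if df[group].nunique() < 2:
        raise ValueError("need at least two categories")
    table = anova(df, "germination_rate", [group])
    mse = float(table.loc["Residual", "mean_sq"])
    df_resid = float(table.loc["Residual", "df"])
    groups = {str(k): g["germination_rate"].to_numpy(dtype=float)
              for k, g in df.groupby(group)}
    lsd = _fisher_lsd(groups, mse, df_resid, alpha)
    return table, lsd
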