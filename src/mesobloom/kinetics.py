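"""Growth-rate, biomass and viral-load correlation analyses.

Growth rates are ordinary least-squares slopes of log abundance against
day, repeated with the fitting window shifted by ±0.5 days (picking the
twice-daily sample nearest the shifted start), so each estimate carries a
standard deviation over the n = 3 shifted fits.  Biomass conversions use
literature per-cell carbon factors (thraustochytrids 1.65e-10 g C/cell,
bacterioplankton 1e-14 g C/cell).  Metric-versus-viral-load correlations
come in two modes: a simple regression stratified by bag cover, and a
pooled regression with an additive cover-class term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .tables_io import get_series, logger

# g C per cell
BIOMASS_FACTORS = {
    "thraustochytrid": 1.65e-10,
    "bacterium": 1.0e-14,
}

# Fig-3d style named window presets per variable: (start, end) with None
# meaning "until the final day" (thraustochytrids: until their maximum);
# per-bag overrides for the differently timed demises
GROWTH_WINDOW_PRESETS = {
    "thraustochytrids": {"default": (None, "argmax")},
    "bacteria_fl": {"default": (15, None), "bag4": (15, 22), "bag7": (15, 18)},
    "bacteria_2_20": {"default": (10, None), "bag4": (10, 22), "bag7": (10, 22)},
}


def integrate_abundance(table: pd.DataFrame, variable: str) -> pd.Series:
    """Per-bag integrated abundance over the days on which *every* bag has
    a non-null value."""
    sub = table[table["variable"] == variable]
    wide = sub.pivot_table(index="day", columns="bag", values="value")
    common = wide.dropna(axis=0, how="any")
    if common.empty:
        raise ValueError(f"no common sampling days for {variable!r}")
    out = common.sum(axis=0)
    out.name = f"integrated_{variable}"
    return out


@dataclass
class GrowthRateEstimate:
    bag_id: object
    variable: str
    window: tuple
    rate: float          # per day
    rate_sd: float
    n_fits: int
    rates: tuple         # individual shifted-fit slopes


def _ols_log_slope(days: np.ndarray, values: np.ndarray) -> float:
    slope, _ = np.polyfit(days, np.log(values), 1)
    return float(slope)


def fit_growth_rate(table: pd.DataFrame, variable: str, bag,
                    window: tuple, shifts=(-0.5, 0.0, 0.5)) -> GrowthRateEstimate:
    """Log-linear growth rate over a day window, with shifted-start
    replicate fits.

    For each shift, the window start is moved and snapped to the nearest
    twice-daily sample; the slope of ln(abundance) vs day is the OLS
    estimate.  Non-positive values are dropped with a warning (log
    transform requires positivity); fewer than 3 remaining points is an
    error.
    """
    series = get_series(table, variable, bag).dropna()
    pos = series[series > 0]
    if len(pos) < len(series):
        warnings.warn(
            f"{variable}/{bag}: dropped {len(series) - len(pos)} non-positive "
            "values before log transform",
            stacklevel=2,
        )
    days_all = pos.index.to_numpy(dtype=float)
    slopes = []
    for shift in shifts:
        start = window[0] + shift
        end = window[1] + shift
        if len(days_all) == 0:
            raise ValueError("no positive values available")
        # snap the shifted start to the nearest sampled time
        snapped = days_all[np.argmin(np.abs(days_all - start))]
        mask = (days_all >= snapped - 1e-9) & (days_all <= end + 1e-9)
        days = days_all[mask]
        values = pos.to_numpy(dtype=float)[mask]
        if len(days) < 3:
            raise ValueError(
                f"{variable}/{bag}: <3 positive points in window {window} "
                f"(shift {shift:+g})"
            )
        slopes.append(_ols_log_slope(days, values))
    slopes = np.array(slopes)
    return GrowthRateEstimate(
        bag_id=bag,
        variable=variable,
        window=tuple(window),
        rate=float(slopes.mean()),
        rate_sd=float(slopes.std(ddof=0)),
        n_fits=len(slopes),
        rates=tuple(slopes),
    )


def biomass_from_counts(counts: pd.Series, group: str,
                        factor: float | None = None) -> pd.DataFrame:
    """Convert a cells/mL series into g C/mL using the per-group carbon
    factor (overridable).  For *E. huxleyi* use
    :func:`mesobloom.assays.cell_carbon` to derive the factor."""
    if factor is None:
        if group not in BIOMASS_FACTORS:
            raise ValueError(
                f"unknown group {group!r}: pass an explicit carbon factor"
            )
        factor = BIOMASS_FACTORS[group]
    values = counts.astype(float) * factor
    return pd.DataFrame(
        {"day": counts.index, "group": group, "biomass_gC_per_mL": values.values,
         "factor_gC_per_cell": factor}
    )


def fit_biomass_ratio_rate(thrausto: pd.Series, bacteria: pd.Series,
                           window: tuple | None = None) -> float:
    """Exponential rate of change k of the thraustochytrid:bacteria biomass
    ratio: OLS slope of log(ratio) vs day.

    Default window runs from day 10 to the day of maximal ratio.  Zero
    bacterial biomass inside the window is an error (the ratio diverges).
    """
    common = thrausto.index.intersection(bacteria.index)
    th = thrausto.loc[common].astype(float)
    ba = bacteria.loc[common].astype(float)
    if (ba == 0).any() and window is None:
        pass  # zeros may fall outside the resolved window; checked below
    ratio = th / ba.replace(0, np.nan)
    if window is None:
        valid = ratio.dropna()
        tmax = valid[valid.index >= 10].idxmax()
        window = (10.0, float(tmax))
    mask = (common >= window[0]) & (common <= window[1])
    if (ba[mask] == 0).any():
        raise ValueError("zero bacterial biomass inside the fitting window")
    r = ratio[mask].dropna()
    r = r[r > 0]
    if len(r) < 2:
        raise ValueError("need >= 2 positive ratio points in the window")
    return _ols_log_slope(r.index.to_numpy(dtype=float), r.to_numpy())


@dataclass
class CorrelationResult:
    mode: str
    stratum: object
    slope: float
    r2: float
    p: float
    n: int


def correlate_with_viral_load(per_bag_metric: pd.Series,
                              per_bag_viral_total: pd.Series,
                              cover_flags: pd.Series | None = None,
                              mode: str = "stratified") -> list:
    """Linear association between a per-bag metric and total viral load.

    ``mode="stratified"``: an independent simple regression per cover
    class.  ``mode="pooled"``: one regression of metric on viral load with
    an additive cover-class intercept ("corrected for bag cover"); the
    reported slope/p are for the viral-load term and R² is the model R².
    """
    common = per_bag_metric.index.intersection(per_bag_viral_total.index)
    y = per_bag_metric.loc[common].astype(float)
    x = per_bag_viral_total.loc[common].astype(float)
    if x.nunique() < 2:
        raise ValueError("zero variance in viral load across bags")
    if cover_flags is None:
        cover_flags = pd.Series(False, index=common)
    cover = cover_flags.loc[common].astype(bool)

    results = []
    if mode == "stratified":
        for flag in sorted(cover.unique()):
            sel = cover == flag
            if sel.sum() < 3:
                continue
            fit = stats.linregress(x[sel], y[sel])
            results.append(CorrelationResult(
                "stratified", "covered" if flag else "uncovered",
                float(fit.slope), float(fit.rvalue**2), float(fit.pvalue),
                int(sel.sum()),
            ))
    elif mode == "pooled":
        X = pd.DataFrame({"viral": x, "cover": cover.astype(float)})
        X = sm.add_constant(X)
        if cover.nunique() < 2:
            X = X.drop(columns="cover")
        model = sm.OLS(y, X).fit()
        results.append(CorrelationResult(
            "pooled", "all",
            float(model.params["viral"]), float(model.rsquared),
            float(model.pvalues["viral"]), len(y),
        ))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for r in results:
        logger.info("viral-load correlation (%s/%s): slope=%.3g R2=%.3f p=%.3g",
                    r.mode, r.stratum, r.slope, r.r2, r.p)
    return results
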