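"""Recursive production–loss models for extracellular carbon pools.

The central model of the pipeline: a bulk pool C(t) (TEP, PIC, POC or CSP)
accumulates contributions from phytoplankton producers and loses a fixed
fraction ``d`` per day to degradation and sinking,

    C(t) = (1 - d) C(t-1) + sum_i a_i X_i(t),

whose closed form is the discounted sum

    C(t) = sum_{t'=0..t} (1 - d)^(t-t') sum_i a_i X_i(t').

For TEP (and POC/CSP) the producer terms X_i are the abundances of
*E. huxleyi* (E), naked nanophytoplankton (N) and picophytoplankton (P);
for PIC the single producer term is the positive part of the day-to-day
*E. huxleyi* increment, max(E(t) - E(t-1), 0): calcite only accumulates
through newly built coccoliths.

Fitting holds ``d`` fixed, solves the resulting linear model for the
per-cell rates a_i under the constraint a_i >= 0 (non-negative least
squares, no intercept), scans ``d`` over a grid, and keeps the d that
maximizes R²; ties break toward smaller d.

The infected-subpopulation extension splits E into a bystander fraction
producing T per cell (T fixed from the least-infected uncovered bags) and
an infected fraction f(t) producing I×T per cell, and chooses the
multiplier I on a grid by minimizing squared deviation from the observed
pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .tables_io import logger

TEP_PRODUCERS = ("ehux", "nano", "pico")


@dataclass
class ProducerSet:
    """Aligned per-day producer abundance series (cells/mL).

    ``series`` maps producer name → 1-D array on a common day grid.
    """

    days: np.ndarray
    series: dict

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        for name, x in self.series.items():
            if len(x) != len(self.days):
                raise ValueError(f"producer {name!r} not aligned to day grid")
            if (x < 0).any():
                raise ValueError(f"negative abundances in producer {name!r}")

    @property
    def names(self) -> tuple:
        return tuple(self.series)

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.series[k] for k in self.series])


@dataclass
class CarbonModelFit:
    """Result of a constrained production–loss fit."""

    kind: str
    rates: dict          # producer -> a_i (amount per cell per day)
    d: float             # daily loss fraction
    r2: float
    d_grid: np.ndarray
    r2_by_d: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray
    flags: tuple = ()


@dataclass
class InfectionPartition:
    """Two-subpopulation TEP/PIC partition of an infected bag."""

    infected_fraction: np.ndarray
    baseline_rate: float     # T, per-cell production of bystander cells
    multiplier: float        # I, fold-increase of infected cells
    deviation: float         # achieved sum of squared deviations
    i_grid: np.ndarray
    deviation_by_i: np.ndarray


# ---------------------------------------------------------------------------
# Forward models


def _check_params(rates, d) -> None:
    if not (0 <= d < 1):
        raise ValueError("loss fraction d must lie in [0, 1)")
    if np.any(np.asarray(rates, dtype=float) < 0):
        raise ValueError("per-cell rates must be non-negative")


def _discounted_kernel(x: np.ndarray, d: float) -> np.ndarray:
    """K(t) = sum_{t'<=t} (1-d)^(t-t') x(t'), evaluated by the recursion."""
    out = np.empty_like(x, dtype=float)
    acc = 0.0
    for t in range(len(x)):
        acc = (1.0 - d) * acc + x[t]
        out[t] = acc
    return out


def _discounted_kernel_closed(x: np.ndarray, d: float) -> np.ndarray:
    """Same kernel via the explicit geometric sum (cross-check route)."""
    t = np.arange(len(x))
    weights = (1.0 - d) ** (t[:, None] - t[None, :])
    return np.where(t[None, :] <= t[:, None], weights, 0.0) @ x


def forward_tep(producers: ProducerSet, rates: dict, d: float,
                closed_form: bool = False) -> np.ndarray:
    """Forward-simulate the TEP (or POC/CSP) pool.

    ``rates`` maps producer name → per-cell daily production.  The recursion
    and the closed-form sum agree to 1e-10 relative; ``closed_form``
    selects the explicit-sum route.
    """
    _check_params(list(rates.values()), d)
    kernel = _discounted_kernel_closed if closed_form else _discounted_kernel
    total = np.zeros(len(producers.days))
    for name, a in rates.items():
        if name not in producers.series:
            raise ValueError(f"missing producer series {name!r}")
        total += a * kernel(producers.series[name], d)
    return total


def positive_increments(E: np.ndarray) -> np.ndarray:
    """Daily coccolith-production driver: max(E(t) - E(t-1), 0) with
    max(E(0), 0) at the first day."""
    E = np.asarray(E, dtype=float)
    dE = np.diff(E, prepend=0.0)
    return np.maximum(dE, 0.0)


def forward_pic(E: np.ndarray, a_E: float, d: float,
                closed_form: bool = False) -> np.ndarray:
    """Forward-simulate PIC: losses as for TEP, gains only on net
    *E. huxleyi* increase."""
    _check_params([a_E], d)
    kernel = _discounted_kernel_closed if closed_form else _discounted_kernel
    return a_E * kernel(positive_increments(E), d)


# ---------------------------------------------------------------------------
# Constrained fitting with loss-rate scan


def _design_matrix(producers: ProducerSet, d: float, kind: str) -> np.ndarray:
    if kind == "pic":
        (name,) = producers.names
        return _discounted_kernel(positive_increments(producers.series[name]), d)[:, None]
    return np.column_stack(
        [_discounted_kernel(x, d) for x in producers.series.values()]
    )


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_tot = np.sum((observed - observed.mean()) ** 2)
    if ss_tot == 0:
        return np.nan
    return 1.0 - np.sum((observed - predicted) ** 2) / ss_tot


def fit_production_model(observed, producers: ProducerSet, d_grid,
                         kind: str = "tep") -> CarbonModelFit:
    """Fit the production–loss model by NNLS over a loss-rate grid.

    For each candidate d the observed pool is regressed, without intercept,
    on the d-discounted producer kernels under a_i >= 0; the d maximizing
    R² wins, ties toward smaller d.  An all-zero observation returns zero
    rates with an ``r2-undefined`` flag.
    """
    observed = np.asarray(observed, dtype=float)
    d_grid = np.asarray(d_grid, dtype=float)
    if d_grid.size == 0:
        raise ValueError("empty d grid")
    X_any = producers.matrix()
    if not X_any.any():
        raise ValueError("all producer series are zero")
    n_par = 1 if kind == "pic" else X_any.shape[1]
    if len(observed) < n_par + 1:
        raise ValueError("need at least one more observation day than producers")

    names = producers.names if kind != "pic" else (producers.names[0],)
    best = None
    r2_by_d = np.full(len(d_grid), np.nan)
    sse_by_d = np.full(len(d_grid), np.inf)
    for j, d in enumerate(d_grid):
        A = _design_matrix(producers, d, kind)
        coef, _ = nnls(A, observed)
        pred = A @ coef
        sse_by_d[j] = np.sum((observed - pred) ** 2)
        r2_by_d[j] = _r2(observed, pred)
        # maximizing R^2 == minimizing SSE for fixed observations; use SSE
        # so the degenerate all-zero case still selects d deterministically
        if best is None or sse_by_d[j] < best[0] - 1e-15 * max(1.0, best[0]):
            best = (sse_by_d[j], d, coef, pred)
    _, d_opt, coef, pred = best
    flags = ()
    if not observed.any():
        flags = ("r2-undefined",)
    fit = CarbonModelFit(
        kind=kind,
        rates=dict(zip(names, coef)),
        d=float(d_opt),
        r2=float(_r2(observed, pred)) if observed.any() else np.nan,
        d_grid=d_grid,
        r2_by_d=r2_by_d,
        predicted=pred,
        residuals=observed - pred,
        flags=flags,
    )
    logger.info(
        "%s fit: n=%d days, d grid [%g, %g], d*=%g, R2=%.4f",
        kind.upper(), len(observed), d_grid[0], d_grid[-1], fit.d, fit.r2,
    )
    return fit


def fit_pic_model(observed, E, d_grid) -> CarbonModelFit:
    """PIC variant of :func:`fit_production_model` (single producer,
    positive-increment kernel)."""
    E = np.asarray(E, dtype=float)
    producers = ProducerSet(np.arange(len(E), dtype=float), {"ehux": E})
    return fit_production_model(observed, producers, d_grid, kind="pic")


def contribution_shares(fit: CarbonModelFit, producers: ProducerSet,
                        day_range: tuple | None = None) -> dict:
    """Fraction of the modeled pool contributed by each producer over
    ``day_range`` (inclusive); fractions sum to 1."""
    days = producers.days
    mask = (
        np.ones(len(days), dtype=bool)
        if day_range is None
        else (days >= day_range[0]) & (days <= day_range[1])
    )
    totals = {}
    for name, a in fit.rates.items():
        x = (
            positive_increments(producers.series[name])
            if fit.kind == "pic"
            else producers.series[name]
        )
        totals[name] = float(np.sum(a * _discounted_kernel(x, fit.d)[mask]))
    pool = sum(totals.values())
    if pool == 0:
        raise ValueError("zero modeled pool over the requested day range")
    return {k: v / pool for k, v in totals.items()}


def fit_production_model_global(observed_by_bag: dict, producers_by_bag: dict,
                                d_grid, kind: str = "tep") -> dict:
    """Joint fit across bags: per-cell rates are bag-specific, the loss
    fraction d is shared.

    For each candidate d every bag gets its own NNLS solution; the d
    minimizing the summed squared error wins (ties toward smaller d).
    Returns bag → :class:`CarbonModelFit`, all carrying the shared d.
    """
    d_grid = np.asarray(d_grid, dtype=float)
    if d_grid.size == 0:
        raise ValueError("empty d grid")
    bags = list(observed_by_bag)
    sse_by_d = np.zeros(len(d_grid))
    coefs = {bag: [None] * len(d_grid) for bag in bags}
    for j, d in enumerate(d_grid):
        for bag in bags:
            obs = np.asarray(observed_by_bag[bag], dtype=float)
            A = _design_matrix(producers_by_bag[bag], d, kind)
            coef, _ = nnls(A, obs)
            coefs[bag][j] = coef
            sse_by_d[j] += np.sum((obs - A @ coef) ** 2)
    j_opt = int(np.argmin(sse_by_d))
    d_opt = float(d_grid[j_opt])
    fits = {}
    for bag in bags:
        obs = np.asarray(observed_by_bag[bag], dtype=float)
        A = _design_matrix(producers_by_bag[bag], d_opt, kind)
        coef = coefs[bag][j_opt]
        pred = A @ coef
        names = (
            producers_by_bag[bag].names
            if kind != "pic"
            else (producers_by_bag[bag].names[0],)
        )
        fits[bag] = CarbonModelFit(
            kind=kind,
            rates=dict(zip(names, coef)),
            d=d_opt,
            r2=float(_r2(obs, pred)) if obs.any() else np.nan,
            d_grid=d_grid,
            r2_by_d=np.full(len(d_grid), np.nan),
            predicted=pred,
            residuals=obs - pred,
        )
    return fits


# ---------------------------------------------------------------------------
# Infected-subpopulation multiplier


def infected_prediction(producers: ProducerSet, baseline: CarbonModelFit,
                        f: np.ndarray, I: float) -> np.ndarray:
    """Pool prediction with E split into bystanders producing T per cell
    and an infected fraction f(t) producing I×T per cell.  Reduces to the
    baseline model at I = 1."""
    f = np.asarray(f, dtype=float)
    eff = dict(producers.series)
    eff["ehux"] = producers.series["ehux"] * ((1.0 - f) + I * f)
    eff_set = ProducerSet(producers.days, eff)
    if baseline.kind == "pic":
        return forward_pic(eff_set.series["ehux"], baseline.rates["ehux"], baseline.d)
    return forward_tep(eff_set, baseline.rates, baseline.d)


def fit_infection_multiplier(observed, producers: ProducerSet, f,
                             baseline_fit: CarbonModelFit,
                             i_grid=None) -> InfectionPartition:
    """Estimate the infected-cell production multiplier I.

    The baseline fit (from the least-infected uncovered bags) fixes the
    bystander per-cell rate T and loss fraction d; I is scanned over
    ``i_grid`` (default 0–10, step 0.05) minimizing the squared deviation
    of the two-subpopulation prediction from the observed pool of the
    infected bag.  Requires a nonzero infected-fraction series.
    """
    observed = np.asarray(observed, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("infected fractions must lie in [0, 1]")
    if not f.any():
        raise ValueError(
            "infected fraction is identically zero: multiplier I is unidentifiable"
        )
    if i_grid is None:
        i_grid = 0.05 * np.arange(201)
    i_grid = np.asarray(i_grid, dtype=float)
    dev = np.empty(len(i_grid))
    for j, I in enumerate(i_grid):
        pred = infected_prediction(producers, baseline_fit, f, I)
        dev[j] = np.sum((observed - pred) ** 2)
    j_opt = int(np.argmin(dev))
    return InfectionPartition(
        infected_fraction=f,
        baseline_rate=float(baseline_fit.rates["ehux"]),
        multiplier=float(i_grid[j_opt]),
        deviation=float(dev[j_opt]),
        i_grid=i_grid,
        deviation_by_i=dev,
    )


def interpolate_fraction(measured_days, measured_f, target_days) -> np.ndarray:
    """Linearly interpolate a sparse infected-fraction series onto the model
    day grid (constant extrapolation at the ends, clipped to [0, 1])."""
    f = np.interp(np.asarray(target_days, dtype=float),
                  np.asarray(measured_days, dtype=float),
                  np.asarray(measured_f, dtype=float))
    return np.clip(f, 0.0, 1.0)
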