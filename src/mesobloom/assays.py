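"""Assay-level computations.

* Dilution-method rates: apparent growth k = ln(Ct/C0)/t per bottle;
  microzooplankton grazing g = (kd − k1)/(1 − x) from the 20% whole-
  seawater dilution; intrinsic growth µ = g + k1 (k1 from the unamended
  100% treatment); viral lysis from the paired 100-kDa-filtrate dilution,
  retained only when the TFF- and FSW-diluted treatments differ (paired
  t-test, alpha 0.1), in which case µ additionally includes v.
* ddPCR conversions: copies/µL reaction → cells/mL seawater through the
  reaction volume, template dilution and filtered volume, divided by the
  genome-size-derived rDNA copy number per cell.
* The *E. huxleyi* carbon budget: spherical cell volume × 220 fg C/µm³,
  demise cell-loss rate, and the resulting carbon flux.
* Carbohydrate-microarray normalization: highest mean signal set to 100,
  values below 5 arbitrary units zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_COPIES_PER_CELL = 64
CARBON_DENSITY_FG_PER_UM3 = 220.0


# ---------------------------------------------------------------------------
# Dilution method


def apparent_growth(C0: float, Ct: float, t: float,
                    literal_log_difference: bool = False) -> float:
    """Apparent daily growth rate from initial/final concentrations.

    Computed as ln(Ct/C0)/t.  ``literal_log_difference=True`` evaluates
    ln(Ct − C0)/t instead — a dimensionally inconsistent variant kept only
    for auditing against sources that print it; never used by the
    pipeline."""
    if t <= 0:
        raise ValueError("incubation time must be positive")
    if literal_log_difference:
        return float(np.log(Ct - C0) / t)
    if C0 <= 0 or Ct <= 0:
        raise ValueError("concentrations must be positive")
    return float(np.log(Ct / C0) / t)


@dataclass
class DilutionResult:
    k1_nutrient: float      # apparent growth, 100% WSW + nutrients
    k1_no_nutrient: float   # apparent growth, 100% WSW unamended
    kd_fsw: float           # 20% WSW in 0.45-um filtrate
    kd_tff: float | None    # 20% WSW in 100-kDa filtrate
    grazing: float          # g, per day
    viral_lysis: float | None
    mu: float               # intrinsic growth, per day
    nutrient_pooled: bool
    p_nutrient: float
    p_grazing: float
    p_lysis: float | None
    lysis_detected: bool


def _paired_p(a, b) -> float:
    """Paired two-sided t-test p; exact-tie and zero-variance cases handled
    (all-equal pairs -> p=1; constant nonzero difference -> p=0).  Falls
    back to Welch when the replicate counts differ."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    diff = a - b
    if np.allclose(diff.std(ddof=0), 0.0):
        return 1.0 if np.allclose(diff, 0.0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def dilution_rates(treatment_rates: dict, x: float,
                   alpha: float = 0.1) -> DilutionResult:
    """Invert the paired dilution design.

    ``treatment_rates`` maps treatment name → replicate apparent rates:
    ``wsw_nut`` (100% + nutrients), ``wsw`` (100% unamended), ``fsw_dil``
    (20% in particle-free 0.45-µm filtrate) and optionally ``tff_dil``
    (20% in virus-free 100-kDa filtrate).

    Pooling: the ±nutrient 100% treatments are compared by paired t-test;
    if not different at ``alpha`` they are pooled and the pooled mean
    serves both roles of k1.  Grazing g = (kd − k1)/(1 − x) with the
    +nutrient k1; µ = g + k1 with the unamended k1.  Viral lysis
    v = (kd_TFF − kd_FSW)/(1 − x), retained only when those treatments
    differ at ``alpha``; when retained, µ = g + v + k1.
    """
    if not 0 < x < 1:
        raise ValueError("x must lie in (0, 1)")
    for name in ("wsw_nut", "wsw", "fsw_dil"):
        if name not in treatment_rates:
            raise ValueError(f"missing treatment {name!r}")
        if len(np.atleast_1d(treatment_rates[name])) < 2:
            raise ValueError(f"treatment {name!r} needs >= 2 replicates")

    k_nut = np.asarray(treatment_rates["wsw_nut"], dtype=float)
    k_non = np.asarray(treatment_rates["wsw"], dtype=float)
    kd_fsw = np.asarray(treatment_rates["fsw_dil"], dtype=float)

    p_nutrient = _paired_p(k_nut, k_non)
    pooled = p_nutrient >= alpha
    if pooled:
        k1_for_g = k1_for_mu = float(np.concatenate([k_nut, k_non]).mean())
    else:
        k1_for_g = float(k_nut.mean())
        k1_for_mu = float(k_non.mean())

    g = (float(kd_fsw.mean()) - k1_for_g) / (1.0 - x)
    p_grazing = _paired_p(kd_fsw, k_nut)

    v = p_lysis = None
    lysis_detected = False
    kd_tff_mean = None
    if "tff_dil" in treatment_rates:
        kd_tff = np.asarray(treatment_rates["tff_dil"], dtype=float)
        kd_tff_mean = float(kd_tff.mean())
        p_lysis = _paired_p(kd_tff, kd_fsw)
        if p_lysis < alpha:
            v = (kd_tff_mean - float(kd_fsw.mean())) / (1.0 - x)
            lysis_detected = True

    mu = g + k1_for_mu + (v if lysis_detected else 0.0)
    return DilutionResult(
        k1_nutrient=float(k_nut.mean()),
        k1_no_nutrient=float(k_non.mean()),
        kd_fsw=float(kd_fsw.mean()),
        kd_tff=kd_tff_mean,
        grazing=g,
        viral_lysis=v,
        mu=mu,
        nutrient_pooled=pooled,
        p_nutrient=p_nutrient,
        p_grazing=p_grazing,
        p_lysis=p_lysis,
        lysis_detected=lysis_detected,
    )


def dilution_rates_from_counts(counts: pd.DataFrame, x: float,
                               alpha: float = 0.1) -> DilutionResult:
    """Convenience wrapper: compute per-bottle apparent rates from a T0/T24
    count table (columns treatment, replicate, hours, count) and invert."""
    rates = {}
    for treatment, grp in counts.groupby("treatment"):
        reps = []
        for _, rep in grp.groupby("replicate"):
            rep = rep.sort_values("hours")
            t0, t1 = rep.iloc[0], rep.iloc[-1]
            dt_days = (t1["hours"] - t0["hours"]) / 24.0
            reps.append(apparent_growth(t0["count"], t1["count"], dt_days))
        rates[treatment] = np.array(reps)
    return dilution_rates(rates, x=x, alpha=alpha)


# ---------------------------------------------------------------------------
# ddPCR conversions


def copies_per_cell(genome_size_mb: float) -> tuple:
    """rDNA copies per cell from genome size via the published log-log
    regression 0.6607·log10(G) + 0.7508; returns (log10 value rounded to 3
    decimals, rounded copy number).  G = 40 Mb gives (1.809, 64)."""
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    log_value = 0.6607 * np.log10(genome_size_mb) + 0.7508
    return round(float(log_value), 3), int(round(10 ** round(float(log_value), 3)))


@dataclass
class DdpcrMeasurement:
    concentration: float        # copies per uL of reaction
    reaction_volume_ul: float = 20.0
    dilution_factor: float = 1.0
    filtered_volume_ml: float = 100.0
    copies_per_cell: float = DEFAULT_COPIES_PER_CELL

    def __post_init__(self):
        if self.filtered_volume_ml <= 0:
            raise ValueError("filtered seawater volume must be positive")
        if self.copies_per_cell < 1:
            raise ValueError("copies per cell must be >= 1")
        if self.concentration < 0 or self.reaction_volume_ul <= 0 \
                or self.dilution_factor <= 0:
            raise ValueError("ddPCR measurement fields must be positive")


def ddpcr_to_cells(m: DdpcrMeasurement) -> float:
    """Cells per mL of sampled seawater: total reaction copies, corrected
    for template dilution, per mL filtered, divided by copies/cell."""
    copies_per_ml = (
        m.concentration * m.reaction_volume_ul * m.dilution_factor
        / m.filtered_volume_ml
    )
    return copies_per_ml / m.copies_per_cell


# ---------------------------------------------------------------------------
# E. huxleyi carbon budget


def cell_carbon(radius_um: float = 2.5,
                carbon_density: float = CARBON_DENSITY_FG_PER_UM3) -> tuple:
    """Spherical cell volume and carbon content.

    Returns (volume µm³, carbon fg/cell); the carbon value is truncated to
    an integer femtogram, matching the budget arithmetic convention
    (R = 2.5 µm → 65.4498 µm³ → 14,398 fg C/cell)."""
    if radius_um < 0:
        raise ValueError("radius must be non-negative")
    volume = 4.0 / 3.0 * np.pi * radius_um**3
    carbon = int(carbon_density * volume)  # truncation, not rounding
    return float(volume), carbon


def demise_carbon_flux(abundance_t1: float, abundance_t2: float,
                       days_between: float, carbon_per_cell_pg: float) -> dict:
    """Carbon flux released by bloom demise.

    Cell loss rate = (abundance_t1 − abundance_t2)/days (cells/mL/day); a
    negative loss (growing population) is clamped to zero flux with a
    warning.  The pg-scale flux is truncated to an integer (same budget
    arithmetic convention as the cell carbon content) and also reported in
    µg C/L/day (1 pg/mL = 1e-3 µg/L)."""
    if days_between <= 0:
        raise ValueError("days_between must be positive")
    loss = (abundance_t1 - abundance_t2) / days_between
    clamped = False
    if loss < 0:
        warnings.warn("negative demise loss clamped to 0 flux", stacklevel=2)
        loss, clamped = 0.0, True
    flux_pg = float(np.trunc(loss * carbon_per_cell_pg))
    return {
        "cell_loss_per_ml_per_day": loss,
        "flux_pg_c_per_ml_per_day": flux_pg,
        "flux_ug_c_per_l_per_day": flux_pg * 1e-3,
        "clamped": clamped,
    }


# ---------------------------------------------------------------------------
# Carbohydrate microarray


def normalize_microarray(signals: pd.DataFrame, cutoff: float = 5.0,
                         replicate_level: str | None = None) -> pd.DataFrame:
    """Scale mean antibody signals so the data-set maximum is 100, then
    zero values below ``cutoff`` (arbitrary units, applied post-scaling).

    If ``replicate_level`` names an index level, replicate spots are
    averaged over it first.  Idempotent on already-normalized data whose
    maximum is 100.
    """
    df = signals.astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative signal intensities")
    if replicate_level is not None:
        df = df.groupby(level=replicate_level).mean()
    top = df.to_numpy().max()
    if top == 0:
        raise ValueError("all-zero signal matrix")
    scaled = df * (100.0 / top)
    return scaled.where(scaled >= cutoff, 0.0)
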