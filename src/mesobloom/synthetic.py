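"""In-silico mesocosm experiments.

Generates a complete 7-bag, 24-day coccolithophore-bloom experiment with
the statistical structure the downstream analyses assume: two bloom peaks
(a mixed pico/nano bloom followed by an *E. huxleyi* bloom), a per-bag
viral-load gradient spanning three orders of magnitude, bloom-demise depth
increasing with viral load (up to ~90% of peak abundance lost in the most
infected bags), infection fractions peaking at 10% and 25% in the two
smFISH-monitored bags, thraustochytrids appearing only after the
*E. huxleyi* peak with viral-load-dependent growth, clustered taxon
succession in the composition matrices, and TEP/PIC/POC/CSP pools produced
by the package's own forward production–loss models plus multiplicative
lognormal measurement noise.

Bloom shapes are phenomenological (logistic growth × exponential demise
for *E. huxleyi*, Gaussian bumps for other groups): the generator
reproduces the statistical features the analyses contract on, not
mechanistic virus–host dynamics.  All output is reproducible bit-for-bit
from (scenario, seed); per-variable substreams are derived deterministically
from the scenario seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import carbon
from .tables_io import CompositionMatrix, validate_measurements

# default per-bag viral-load multipliers: bags 4 and 7 heavily infected,
# bags 3 and 5 three orders of magnitude lower
DEFAULT_VIRAL_SCALE = (0.01, 0.05, 0.001, 1.0, 0.001, 0.01, 1.08)
DEFAULT_COVERED = (False, False, False, False, True, True, True)
# smFISH maxima: 10% in bag 2, 25% in bag 4; least-infected uncovered bags
# (1 and 3) carry no detectable infection and serve as the model baseline
DEFAULT_INFECTION_MAX = (0.0, 0.10, 0.0, 0.25, 0.005, 0.02, 0.30)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass
class MesocosmScenario:
    """Generating parameters of one synthetic mesocosm experiment.

    Rates are in pool units per (cell/mL) per day: µg XG eq/L for TEP,
    µmol/L for PIC, µg C/L for POC, µg BSA eq/L for CSP (equivalently
    pg/cell/day for TEP/POC/CSP and nmol per 1000 cells/day for PIC).
    """

    n_bags: int = 7
    n_days: int = 24
    covered_flags: tuple = DEFAULT_COVERED
    viral_load_scale: tuple = DEFAULT_VIRAL_SCALE
    bloom1_peak_day: float = 5.0
    bloom2_peak_day: float = 17.0
    infection_fraction_max: tuple = DEFAULT_INFECTION_MAX
    infection_multiplier: float = 4.0
    tep_params: tuple = (4.75e-3, 1.5e-3, 2.0e-4, 0.12)   # (a_E, a_N, a_P, d)
    pic_params: tuple = (1.5e-3, 0.0075)                   # (a_E, d)
    poc_params: tuple = (5.0e-3, 2.0e-3, 3.0e-4, 0.05)
    csp_params: tuple = (1.0e-3, 8.0e-4, 1.0e-4, 0.08)
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 3:
            raise ValueError("n_days must be >= 3")
        if self.n_bags < 1:
            raise ValueError("n_bags must be >= 1")
        for name in ("covered_flags", "viral_load_scale", "infection_fraction_max"):
            vals = getattr(self, name)
            if len(vals) != self.n_bags:
                raise ValueError(f"{name} must have one entry per bag")
        if any(s < 0 for s in self.viral_load_scale):
            raise ValueError("viral_load_scale entries must be non-negative")
        if any(not 0 <= f <= 1 for f in self.infection_fraction_max):
            raise ValueError("infection fractions must lie in [0, 1]")
        for params in (self.tep_params, self.poc_params, self.csp_params):
            if any(a < 0 for a in params[:3]) or not 0 <= params[3] < 1:
                raise ValueError("per-cell rates must be >= 0 and d in [0, 1)")
        if self.pic_params[0] < 0 or not 0 <= self.pic_params[1] < 1:
            raise ValueError("per-cell rates must be >= 0 and d in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def bags(self) -> list:
        return [f"bag{i + 1}" for i in range(self.n_bags)]

    @property
    def demise_start(self) -> float:
        return self.bloom2_peak_day

    def rng(self, *substream) -> np.random.Generator:
        """Deterministic substream keyed by (seed, *labels); labels are
        hashed with CRC32 so streams are stable across processes."""
        key = [self.seed] + [
            zlib.crc32(repr(s).encode()) & 0x7FFFFFFF for s in substream
        ]
        return np.random.default_rng(key)

    def truth(self) -> dict:
        """Full generating-parameter record, for recovery tests."""
        return asdict(self)


# ---------------------------------------------------------------------------
# Deterministic shape functions (continuous in t, per bag)


def _relative_virus(scenario: MesocosmScenario) -> np.ndarray:
    v = np.asarray(scenario.viral_load_scale, dtype=float)
    vmax = v.max() if v.max() > 0 else 1.0
    return v / vmax


def ehux_shape(scenario: MesocosmScenario, bag_idx: int, t) -> np.ndarray:
    """Calcified *E. huxleyi*: logistic rise to a carrying capacity, then
    exponential demise whose depth grows with relative viral load (30%
    of peak lost without virus, up to 90% in the most infected bag)."""
    t = np.asarray(t, dtype=float)
    rel_v = _relative_virus(scenario)[bag_idx]
    peak = scenario.bloom2_peak_day
    K = 5.7e4 * (0.8 if scenario.covered_flags[bag_idx] else 1.0)
    # logistic saturates by the peak day so the realized demise depth
    # matches the viral-load-scaled target
    growth = _logistic(1.2 * (t - (peak - 5.0)))
    depth = 0.3 + 0.6 * rel_v
    span = max(scenario.n_days - 1 - peak, 1.0)
    lam = -np.log(1.0 - depth) / span
    demise = np.exp(-lam * np.maximum(t - peak, 0.0))
    return K * growth * demise


def pico_shape(scenario, bag_idx, t):
    t = np.asarray(t, dtype=float)
    return 1.8e5 * np.exp(-0.5 * ((t - scenario.bloom1_peak_day) / 2.5) ** 2) + 1e3


def nano_shape(scenario, bag_idx, t):
    t = np.asarray(t, dtype=float)
    return 4.0e4 * np.exp(-0.5 * ((t - scenario.bloom1_peak_day - 1.0) / 3.0) ** 2) + 5e2


def bacteria_shape(scenario, bag_idx, t):
    """Free-living bacteria: tenfold rise during the first-bloom demise,
    plus a viral-load-dependent secondary rise during E. huxleyi demise."""
    t = np.asarray(t, dtype=float)
    rel_v = _relative_virus(scenario)[bag_idx]
    base = 5e5 * (1.0 + 9.0 * _logistic(1.2 * (t - 9.0)) * _logistic(-(t - 15.0)))
    demise_rise = 1.0 + (0.8 + 1.7 * rel_v) * _logistic(1.5 * (t - scenario.demise_start - 2.0))
    return base * demise_rise


def bacteria_2_20_shape(scenario, bag_idx, t):
    return 0.05 * bacteria_shape(scenario, bag_idx, t)


def thraustochytrid_shape(scenario, bag_idx, t):
    """Thraustochytrids appear only after the E. huxleyi peak; growth rate
    increases with viral load."""
    t = np.asarray(t, dtype=float)
    rel_v = _relative_virus(scenario)[bag_idx]
    rate = 0.3 + 0.5 * rel_v
    out = 5.0 * np.exp(rate * (t - scenario.demise_start))
    return np.where(t >= scenario.demise_start, out, 0.0)


def ciliate_shape(scenario, bag_idx, t):
    """Ciliates: up to sixfold late increase, strongest in low-virus bags."""
    t = np.asarray(t, dtype=float)
    rel_v = _relative_virus(scenario)[bag_idx]
    return 10.0 * (1.0 + 5.0 * (1.0 - rel_v) * _logistic(1.5 * (t - 20.0)))


def viral_load_shape(scenario, bag_idx, t):
    """Biomass-associated EhV (mcp copies/L): low early, logistic rise
    through demise, scaled by the per-bag viral-load multiplier."""
    t = np.asarray(t, dtype=float)
    scale = scenario.viral_load_scale[bag_idx]
    return scale * (1e7 + 1.5e10 * _logistic(1.5 * (t - scenario.demise_start - 1.0)))


def infection_fraction(scenario: MesocosmScenario, bag_idx: int, t) -> np.ndarray:
    """Fraction of infected *E. huxleyi* cells: scaled logistic rising
    through the demise phase, reaching exactly the per-bag maximum at the
    final day."""
    t = np.asarray(t, dtype=float)
    fmax = scenario.infection_fraction_max[bag_idx]
    if fmax == 0:
        return np.zeros_like(t)
    mid = scenario.demise_start + 2.0
    raw = _logistic((t - mid) / 1.5)
    return fmax * raw / _logistic((scenario.n_days - 1 - mid) / 1.5)


_ABUNDANCE_SHAPES = {
    "pico": (pico_shape, "cells/mL"),
    "nano": (nano_shape, "cells/mL"),
    "ehux": (ehux_shape, "cells/mL"),
    "bacteria_fl": (bacteria_shape, "cells/mL"),
    "bacteria_2_20": (bacteria_2_20_shape, "cells/mL"),
    "thraustochytrids": (thraustochytrid_shape, "cells/mL"),
    "ciliates": (ciliate_shape, "cells/mL"),
    "viral_load": (viral_load_shape, "copies/L"),
}


def _noisy(rng, values, cv):
    """Mean-preserving multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.asarray(values, dtype=float)
    sigma = np.sqrt(np.log1p(cv**2))
    return values * rng.lognormal(-(sigma**2) / 2.0, sigma, size=len(values))


# ---------------------------------------------------------------------------
# Generators


def generate_abundances(scenario: MesocosmScenario) -> pd.DataFrame:
    """Twice-daily abundance table (morning at integer days, evening at
    +0.5) for all flow-cytometry groups plus the qPCR viral load."""
    days = np.arange(scenario.n_days, dtype=float)
    t = np.sort(np.concatenate([days, days + 0.5]))
    records = []
    for b, bag in enumerate(scenario.bags):
        for var, (shape, unit) in _ABUNDANCE_SHAPES.items():
            rng = scenario.rng("abundance", var, b)
            values = _noisy(rng, shape(scenario, b, t), scenario.noise_cv)
            records.extend(
                {"bag": bag, "day": ti, "variable": var, "value": vi, "unit": unit}
                for ti, vi in zip(t, values)
            )
    return validate_measurements(pd.DataFrame.from_records(records))


def generate_infection(scenario: MesocosmScenario) -> pd.DataFrame:
    """Daily infected-fraction table (smFISH analogue)."""
    days = np.arange(scenario.n_days, dtype=float)
    records = []
    for b, bag in enumerate(scenario.bags):
        f = infection_fraction(scenario, b, days)
        records.extend(
            {"bag": bag, "day": d, "variable": "infected_fraction",
             "value": fi, "unit": "fraction"}
            for d, fi in zip(days, f)
        )
    return validate_measurements(pd.DataFrame.from_records(records))


def daily_producers(abundances: pd.DataFrame, scenario_or_bag,
                    bag=None) -> carbon.ProducerSet:
    """Extract the daily (morning-sample) TEP producer set for one bag."""
    from .tables_io import daily, get_series

    if bag is None:
        bag = scenario_or_bag
    series = {}
    for var in ("ehux", "nano", "pico"):
        s = daily(get_series(abundances, var, bag))
        series[var] = s.to_numpy()
    days = daily(get_series(abundances, "ehux", bag)).index.to_numpy()
    return carbon.ProducerSet(days, series)


def generate_bulk_chemistry(abundances: pd.DataFrame,
                            scenario: MesocosmScenario) -> pd.DataFrame:
    """Daily bulk-chemistry table generated by the forward production–loss
    models.

    TEP/POC/CSP use the three-producer kernel; PIC uses the positive-
    increment *E. huxleyi* kernel.  Infected cells produce at
    ``infection_multiplier`` times the per-cell rate, implemented by
    scaling the effective E series with the infected fraction.  Noise is
    multiplicative lognormal with CV ``noise_cv``.
    """
    days = np.arange(scenario.n_days, dtype=float)
    records = []
    I = scenario.infection_multiplier
    for b, bag in enumerate(scenario.bags):
        prod = daily_producers(abundances, bag)
        for var in ("ehux", "nano", "pico"):
            if var not in prod.series:
                raise ValueError(f"missing producer series {var!r} for {bag}")
        f = infection_fraction(scenario, b, prod.days)
        eff = dict(prod.series)
        eff["ehux"] = prod.series["ehux"] * ((1.0 - f) + I * f)
        eff_set = carbon.ProducerSet(prod.days, eff)

        pools = {}
        aE, aN, aP, d = scenario.tep_params
        pools["TEP"] = (
            carbon.forward_tep(eff_set, {"ehux": aE, "nano": aN, "pico": aP}, d),
            "ug XG eq/L",
        )
        aE, d = scenario.pic_params
        pools["PIC"] = (carbon.forward_pic(eff["ehux"], aE, d), "umol/L")
        aE, aN, aP, d = scenario.poc_params
        pools["POC"] = (
            carbon.forward_tep(eff_set, {"ehux": aE, "nano": aN, "pico": aP}, d),
            "ug C/L",
        )
        aE, aN, aP, d = scenario.csp_params
        pools["CSP"] = (
            carbon.forward_tep(eff_set, {"ehux": aE, "nano": aN, "pico": aP}, d),
            "ug BSA eq/L",
        )
        # DOC: slowly accumulating background pool, a plot-only series
        pools["DOC"] = (80.0 + 0.015 * np.cumsum(pools["POC"][0]) / 10.0, "umol/L")

        for var, (values, unit) in pools.items():
            rng = scenario.rng("chemistry", var, b)
            noisy = _noisy(rng, values, scenario.noise_cv)
            records.extend(
                {"bag": bag, "day": di, "variable": var, "value": vi, "unit": unit}
                for di, vi in zip(prod.days, noisy)
            )
    return validate_measurements(pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# Composition matrices


def generate_composition(scenario: MesocosmScenario, marker: str = "18S",
                         n_clusters: int = 6, taxa_per_cluster: int = 5,
                         differential_bag: str | None = "auto",
                         differential_fold: float = 3.0) -> CompositionMatrix:
    """Taxa × (bag, day) relative-abundance matrix with planted succession
    clusters.

    Each cluster is a Gaussian bump at a staggered center day; taxa within
    a cluster share the bump with small seeded jitter.  One high-virus bag
    receives a planted taxon over-represented by ``differential_fold``
    during the demise days (plus a matching under-represented partner), so
    the differential-abundance screen has a known positive.  Columns are
    renormalized to sum to 1.
    """
    if n_clusters * taxa_per_cluster < 2:
        raise ValueError("need at least 2 taxa")
    days = np.arange(scenario.n_days, dtype=float)
    centers = np.linspace(2.0, scenario.n_days - 2.0, n_clusters)
    width = 1.8
    rng = scenario.rng("composition", marker)
    rel_v = _relative_virus(scenario)
    if differential_bag == "auto":
        differential_bag = scenario.bags[int(np.argmax(rel_v))]

    names, rows_by_bag, traits = [], {bag: [] for bag in scenario.bags}, []
    modes = ["autotroph", "autotroph", "mixotroph", "heterotroph",
             "heterotroph", "heterotroph"]
    submodes = ["other", "other", "other", "osmotroph", "saprotroph", "other"]
    for c in range(n_clusters):
        mode = modes[c % len(modes)]
        sub = submodes[c % len(submodes)]
        for j in range(taxa_per_cluster):
            name = f"{marker}_c{c + 1}_t{j + 1}"
            names.append(name)
            traits.append((name, mode, sub if mode == "heterotroph" else ""))
            amp = 1.0 + 0.3 * rng.standard_normal()
            shift = 0.4 * rng.standard_normal()
            profile = np.abs(amp) * np.exp(
                -0.5 * ((days - centers[c] - shift) / width) ** 2
            ) + 1e-4
            for bag in scenario.bags:
                noise = (
                    1.0
                    if scenario.noise_cv == 0
                    else np.exp(scenario.noise_cv
                                * scenario.rng("composition", marker, bag, name)
                                .standard_normal(len(days)))
                )
                rows_by_bag[bag].append(profile * noise)

    # planted differential pair in the focal (high-virus) bag; abundant
    # enough to clear the 10%-max differential-screen prefilter.  Skipped
    # entirely when differential_bag is None (pure cluster structure).
    demise = days >= scenario.demise_start + 1
    base = np.full(len(days), 0.4)
    pairs = () if differential_bag is None else (
        ("enriched", differential_fold), ("depleted", 1.0 / differential_fold))
    for suffix, factor in pairs:
        name = f"{marker}_diff_{suffix}"
        names.append(name)
        traits.append((name, "heterotroph", "other"))
        for bag in scenario.bags:
            profile = base.copy()
            if bag == differential_bag:
                profile = np.where(demise, base * factor, base)
            noise = (
                1.0
                if scenario.noise_cv == 0
                else np.exp(scenario.noise_cv
                            * scenario.rng("composition", marker, bag, name)
                            .standard_normal(len(days)))
            )
            rows_by_bag[bag].append(profile * noise)

    cols = pd.MultiIndex.from_product([scenario.bags, days], names=["bag", "day"])
    data = pd.DataFrame(
        np.hstack([np.vstack(rows_by_bag[bag]) for bag in scenario.bags]),
        index=names,
        columns=cols,
    )
    trait_df = pd.DataFrame(
        traits, columns=["taxon", "trophic_mode", "sub_mode"]
    ).set_index("taxon")
    taxonomy = pd.Series({n: f"{marker};cluster" for n in names})
    return CompositionMatrix(data, taxonomy, trait_df, marker).normalize()


# ---------------------------------------------------------------------------
# Dilution experiment


DILUTION_TREATMENTS = ("wsw_nut", "wsw", "fsw_dil", "tff_dil")


def dilution_apparent_rates(mu: float, g: float, v: float, x: float,
                            mu_nutrient: float | None = None) -> dict:
    """Noise-free apparent growth rates per treatment.

    ``wsw_nut``: 100% whole seawater with nutrients (growth mu_n, full
    grazing and lysis); ``wsw``: without nutrients; ``fsw_dil``: 20%
    whole seawater in 0.45-µm filtrate (grazing diluted to x·g, viruses
    pass the filter so lysis stays at v); ``tff_dil``: 20% in 100-kDa
    tangential-flow filtrate (both grazing and lysis diluted).
    """
    if not 0 < x <= 1:
        raise ValueError("x must lie in (0, 1]")
    mu_n = mu if mu_nutrient is None else mu_nutrient
    return {
        "wsw_nut": mu_n - g - v,
        "wsw": mu - g - v,
        "fsw_dil": mu_n - x * g - v,
        "tff_dil": mu_n - x * g - x * v,
    }


def generate_dilution_experiment(mu: float, g: float, v: float, x: float = 0.2,
                                 t: float = 1.0, C0: float = 1e4,
                                 seed: int = 0, noise_cv: float = 0.0,
                                 n_replicates: int = 3) -> pd.DataFrame:
    """Triplicate T0/T24 count table for the paired dilution design such
    that noise-free inversion returns (mu, g, v) exactly."""
    if t <= 0:
        raise ValueError("incubation time must be positive")
    rates = dilution_apparent_rates(mu, g, v, x)
    rng = np.random.default_rng([seed, 777])
    records = []
    for treatment, k in rates.items():
        for rep in range(1, n_replicates + 1):
            c0 = C0
            ct = C0 * np.exp(k * t)
            if noise_cv > 0:
                sigma = np.sqrt(np.log1p(noise_cv**2))
                c0 *= rng.lognormal(-(sigma**2) / 2, sigma)
                ct *= rng.lognormal(-(sigma**2) / 2, sigma)
            records.append((treatment, rep, 0.0, c0))
            records.append((treatment, rep, t * 24.0, ct))
    return pd.DataFrame(records, columns=["treatment", "replicate", "hours", "count"])


# ---------------------------------------------------------------------------
# Whole experiments


@dataclass
class SyntheticExperiment:
    """One complete generated experiment plus its truth record."""

    abundances: pd.DataFrame
    bulk_chemistry: pd.DataFrame
    infection: pd.DataFrame
    composition_16s: CompositionMatrix
    composition_18s: CompositionMatrix
    truth: dict = field(default_factory=dict)


def generate_experiment(scenario: MesocosmScenario) -> SyntheticExperiment:
    """Generate all tables of one experiment from a scenario."""
    abundances = generate_abundances(scenario)
    return SyntheticExperiment(
        abundances=abundances,
        bulk_chemistry=generate_bulk_chemistry(abundances, scenario),
        infection=generate_infection(scenario),
        composition_16s=generate_composition(scenario, marker="16S"),
        composition_18s=generate_composition(scenario, marker="18S"),
        truth=scenario.truth(),
    )
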