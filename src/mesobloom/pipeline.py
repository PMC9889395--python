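"""End-to-end orchestration on a directory of tables.

``run_pipeline`` consumes the canonical tables (as written by the
``simulate`` subcommand, or real data in the same schema), runs the stages
in dependency order — I/O validation, succession statistics, kinetics,
carbon models, infection partition, viral-load correlations — and writes
one tidy CSV per result family plus a machine-readable JSON summary.
Per-bag fit failures are recorded and do not abort the remaining bags.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import carbon, kinetics, succession
from .tables_io import (
    AnalysisConfig,
    CompositionMatrix,
    daily,
    get_series,
    logger,
    read_composition,
    read_measurements,
)

TABLE_FILES = {
    "abundances": "abundances.csv",
    "bulk_chemistry": "bulk_chemistry.csv",
    "infection": "infection.csv",
    "composition_16s": "composition_16s.csv",
    "composition_18s": "composition_18s.csv",
}

CHEMISTRY_MODELS = {"TEP": "tep", "POC": "poc", "CSP": "csp"}


def load_tables(data_dir) -> dict:
    data_dir = Path(data_dir)
    tables = {}
    for key, fname in TABLE_FILES.items():
        path = data_dir / fname
        if not path.exists():
            raise FileNotFoundError(
                f"pipeline stage 'io': required table {fname} missing in {data_dir}"
            )
        if key.startswith("composition"):
            marker = "16S" if "16s" in key else "18S"
            tables[key] = read_composition(path, marker=marker)
        else:
            tables[key] = read_measurements(path)
    return tables


def _bags(table: pd.DataFrame) -> list:
    return sorted(table["bag"].unique())


def _daily_producers(abundances, bag) -> carbon.ProducerSet:
    series = {
        var: daily(get_series(abundances, var, bag)).to_numpy()
        for var in ("ehux", "nano", "pico")
    }
    days = daily(get_series(abundances, "ehux", bag)).index.to_numpy()
    return carbon.ProducerSet(days, series)


def run_pipeline(data_dir, config: AnalysisConfig | None = None,
                 out_dir=None) -> dict:
    """Run every analysis stage; return (and optionally write) the report."""
    config = config or AnalysisConfig()
    tables = load_tables(data_dir)
    abund = tables["abundances"]
    chem = tables["bulk_chemistry"]
    bags = _bags(abund)
    report: dict = {"per_bag_status": {}, "config": {
        "d_grid": [config.d_min, config.d_max, config.d_step],
        "bc_floor": config.bc_floor,
        "seed": config.seed,
    }}

    # --- succession ------------------------------------------------------
    comp18 = tables["composition_18s"]
    clusters = succession.cluster_succession(
        succession.filter_asvs(comp18, *FILTER_CLUSTER[:2], use_max=True),
        seed=config.seed,
    )
    turnover = []
    for bag in bags:
        try:
            fit = succession.fit_turnover(comp18, bag, start_day=0,
                                          floor=config.bc_floor)
            turnover.append({"bag": bag, "k_per_day": fit.rate,
                             "floor": fit.floor, "residual": fit.residual})
        except ValueError as exc:
            report["per_bag_status"][f"turnover/{bag}"] = str(exc)
    div = succession.divergence(
        comp18, start_days=config.divergence_start_days,
        end_day=float(chem["day"].max()),
    )

    # --- kinetics --------------------------------------------------------
    integrated_virus = kinetics.integrate_abundance(abund, "viral_load")
    integrated_ehux = kinetics.integrate_abundance(abund, "ehux")
    growth_rows = []
    for var, presets in kinetics.GROWTH_WINDOW_PRESETS.items():
        for bag in bags:
            window = presets.get(bag, presets["default"])
            try:
                resolved = _resolve_window(abund, var, bag, window)
                est = kinetics.fit_growth_rate(abund, var, bag, resolved)
                growth_rows.append({
                    "bag": bag, "variable": var, "start": resolved[0],
                    "end": resolved[1], "rate": est.rate, "sd": est.rate_sd,
                    "n_fits": est.n_fits,
                })
            except ValueError as exc:
                report["per_bag_status"][f"growth/{var}/{bag}"] = str(exc)

    # --- carbon models ---------------------------------------------------
    producers = {bag: _daily_producers(abund, bag) for bag in bags}
    carbon_rows = []
    fits_by_model: dict = {}
    for variable, kind in CHEMISTRY_MODELS.items():
        observed = {
            bag: daily(get_series(chem, variable, bag)).to_numpy() for bag in bags
        }
        fits = carbon.fit_production_model_global(
            observed, producers, config.d_grid, kind=kind
        )
        fits_by_model[kind] = fits
        for bag, fit in fits.items():
            carbon_rows.append(_fit_row(bag, fit))
    pic_obs = {bag: daily(get_series(chem, "PIC", bag)).to_numpy() for bag in bags}
    pic_prod = {
        bag: carbon.ProducerSet(producers[bag].days,
                                {"ehux": producers[bag].series["ehux"]})
        for bag in bags
    }
    pic_fits = carbon.fit_production_model_global(
        pic_obs, pic_prod, config.d_grid, kind="pic"
    )
    fits_by_model["pic"] = pic_fits
    for bag, fit in pic_fits.items():
        carbon_rows.append(_fit_row(bag, fit))

    # --- infection partition --------------------------------------------
    infection = tables["infection"]
    inf_max = {
        bag: get_series(infection, "infected_fraction", bag).max() for bag in bags
    }
    uncovered_baseline = [b for b in bags if inf_max[b] == min(inf_max.values())][:2]
    focal = max(inf_max, key=inf_max.get)
    partition = None
    if inf_max[focal] > 0:
        base_obs = {b: daily(get_series(chem, "TEP", b)).to_numpy()
                    for b in uncovered_baseline}
        base_fit = carbon.fit_production_model_global(
            base_obs, {b: producers[b] for b in uncovered_baseline},
            config.d_grid, kind="tep",
        )[uncovered_baseline[0]]
        f_series = get_series(infection, "infected_fraction", focal)
        f = carbon.interpolate_fraction(
            f_series.index.to_numpy(), f_series.to_numpy(), producers[focal].days
        )
        partition = carbon.fit_infection_multiplier(
            daily(get_series(chem, "TEP", focal)).to_numpy(),
            producers[focal], f, base_fit, config.i_grid,
        )

    # --- correlations ----------------------------------------------------
    covered = pd.Series(False, index=bags)
    truth_path = Path(data_dir) / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        flags = truth.get("covered_flags")
        if flags is not None and len(flags) == len(bags):
            covered = pd.Series(list(flags), index=bags).astype(bool)
    tep_rate = pd.Series(
        {bag: fits_by_model["tep"][bag].rates["ehux"] for bag in bags}
    )
    corr = kinetics.correlate_with_viral_load(
        tep_rate, integrated_virus, covered, mode="pooled"
    )[0]
    corr_ehux = kinetics.correlate_with_viral_load(
        integrated_ehux, integrated_virus, covered, mode="pooled"
    )[0]

    report.update({
        "clusters": {"n": clusters.n_clusters,
                     "silhouette_by_k": clusters.silhouette_by_k},
        "turnover": turnover,
        "divergence": div.reset_index().to_dict(orient="records"),
        "growth_rates": growth_rows,
        "carbon_fits": carbon_rows,
        "infection_multiplier": None if partition is None else {
            "I": partition.multiplier,
            "baseline_rate": partition.baseline_rate,
            "deviation": partition.deviation,
            "focal_bag": focal,
            "baseline_bags": uncovered_baseline,
        },
        "correlations": [
            {"metric": "tep_rate_per_cell", "slope": corr.slope,
             "r2": corr.r2, "p": corr.p},
            {"metric": "integrated_ehux", "slope": corr_ehux.slope,
             "r2": corr_ehux.r2, "p": corr_ehux.p},
        ],
    })
    report["provenance"] = {
        "config_hash": hashlib.sha256(
            json.dumps(report["config"], sort_keys=True).encode()
        ).hexdigest()[:16],
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(carbon_rows).to_csv(out_dir / "carbon_fits.csv", index=False)
        pd.DataFrame(growth_rows).to_csv(out_dir / "growth_rates.csv", index=False)
        pd.DataFrame(turnover).to_csv(out_dir / "turnover.csv", index=False)
        div.to_csv(out_dir / "divergence.csv")
        clusters.labels.to_csv(out_dir / "cluster_assignments.csv")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
        logger.info("pipeline outputs written to %s", out_dir)
    return report


FILTER_CLUSTER = succession.FILTER_PRESETS["cluster"]


def _resolve_window(abund, var, bag, window) -> tuple:
    start, end = window
    series = daily(get_series(abund, var, bag)).dropna()
    positive = series[series > 0]
    if start is None:
        start = float(positive.index.min())
    if end == "argmax":
        end = float(positive.idxmax())
    elif end is None:
        end = float(series.index.max())
    return float(start), float(end)


def _fit_row(bag, fit: carbon.CarbonModelFit) -> dict:
    row = {"bag": bag, "model": fit.kind, "d": fit.d, "r2": fit.r2}
    for name, a in fit.rates.items():
        row[f"a_{name}"] = a
    return row


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
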