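"""Tabular I/O and shared containers.

Every stage exchanges data through two containers:

* ``MeasurementTable`` — a tidy long-format :class:`pandas.DataFrame` with
  columns ``(bag, day, variable, value, unit)``.  ``day`` is real-valued so
  that evening flow-cytometry samples can sit at half-day offsets; analyses
  that operate on daily values aggregate by calendar day using the morning
  sample.
* ``CompositionMatrix`` — a taxa × sample relative-abundance matrix with
  optional taxonomy and trophic-trait annotations, standing in for 16S/18S
  ASV tables.

Plus :class:`AnalysisConfig`, the flat configuration record shared by the
CLI subcommands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mesobloom")

MEASUREMENT_COLUMNS = ["bag", "day", "variable", "value", "unit"]


# ---------------------------------------------------------------------------
# MeasurementTable


def make_measurements(records, unit: str = "") -> pd.DataFrame:
    """Build a tidy measurement table from ``(bag, day, variable, value)``
    records (unit optional per record)."""
    df = pd.DataFrame(records, columns=MEASUREMENT_COLUMNS[: len(records[0])])
    if "unit" not in df.columns:
        df["unit"] = unit
    return validate_measurements(df)


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a measurement table.

    Replicate rows (same bag, day, variable) are averaged; conflicting
    units for a variable raise ``ValueError``.
    """
    missing = [c for c in MEASUREMENT_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    if "unit" not in df.columns:
        df = df.assign(unit="")
    df = df[MEASUREMENT_COLUMNS].copy()
    df["day"] = pd.to_numeric(df["day"])
    df["value"] = pd.to_numeric(df["value"])
    if (df["day"] < 0).any():
        raise ValueError("negative day coordinate")
    units = df.groupby("variable")["unit"].nunique()
    bad = units[units > 1]
    if len(bad):
        raise ValueError(f"conflicting units for variables: {list(bad.index)}")
    # average replicates
    df = (
        df.groupby(["bag", "day", "variable"], as_index=False)
        .agg(value=("value", "mean"), unit=("unit", "first"))
    )
    return df[MEASUREMENT_COLUMNS]


def read_measurements(path, schema: dict | None = None) -> pd.DataFrame:
    """Read a delimited measurement table (delimiter sniffed from header).

    ``schema`` may rename columns, e.g. ``{"enclosure": "bag"}``.  Parse
    failures raise ``ValueError`` with the offending line number.
    """
    df = _read_delimited(path)
    if schema:
        df = df.rename(columns=schema)
    if len(df) == 0:
        out = pd.DataFrame(columns=MEASUREMENT_COLUMNS)
        return out
    for col in ("day", "value"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                # +2: header line plus 1-based numbering
                raise ValueError(
                    f"{path}: non-numeric {col!r} at line {bad[0] + 2}"
                )
            df[col] = coerced
    table = validate_measurements(df)
    logger.info("read %d measurement records from %s", len(table), path)
    return table


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def _read_delimited(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def get_series(table: pd.DataFrame, variable: str, bag) -> pd.Series:
    """Extract one ``(bag, variable)`` series, indexed by day, sorted."""
    sub = table[(table["variable"] == variable) & (table["bag"] == bag)]
    s = sub.set_index("day")["value"].sort_index()
    s.name = variable
    return s


def daily(series: pd.Series) -> pd.Series:
    """Collapse twice-daily samples to daily values using the morning
    (integer-day) sample; days with only an evening sample keep it."""
    days = np.floor(series.index.to_numpy())
    out = series.groupby(days).first()
    out.index.name = "day"
    return out


# ---------------------------------------------------------------------------
# CompositionMatrix


@dataclass
class CompositionMatrix:
    """Taxa × sample relative abundances.

    ``data``: DataFrame, rows = taxa, columns = MultiIndex ``(bag, day)``.
    ``taxonomy``: optional per-taxon taxonomy strings; taxa flagged as
    chloroplast-derived can be dropped on normalization.
    ``traits``: optional per-taxon DataFrame with columns ``trophic_mode``
    (autotroph | mixotroph | heterotroph) and ``sub_mode`` (osmotroph |
    saprotroph | other) for heterotrophs.
    """

    data: pd.DataFrame
    taxonomy: pd.Series | None = None
    traits: pd.DataFrame | None = None
    marker: str = "18S"

    def __post_init__(self):
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative abundance entries")

    @property
    def taxa(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def normalize(self, drop_chloroplast: bool = False) -> "CompositionMatrix":
        """Convert counts to per-sample proportions (idempotent).

        With ``drop_chloroplast=True``, rows whose taxonomy string contains
        ``"Chloroplast"`` are removed before renormalizing, mirroring the
        removal of reads mapping to chloroplast 16S.
        """
        data = self.data
        taxonomy = self.taxonomy
        traits = self.traits
        if drop_chloroplast and taxonomy is not None:
            keep = ~taxonomy.str.contains("Chloroplast", case=False, na=False)
            data = data.loc[keep.reindex(data.index, fill_value=True)]
            taxonomy = taxonomy.loc[data.index]
            if traits is not None:
                traits = traits.loc[traits.index.intersection(data.index)]
        sums = data.sum(axis=0)
        zero = sums[sums == 0]
        if len(zero):
            raise ValueError(f"zero-sum sample(s): {list(zero.index)}")
        return CompositionMatrix(data / sums, taxonomy, traits, self.marker)

    def subset_taxa(self, taxa) -> "CompositionMatrix":
        taxonomy = self.taxonomy.loc[taxa] if self.taxonomy is not None else None
        traits = (
            self.traits.loc[self.traits.index.intersection(taxa)]
            if self.traits is not None
            else None
        )
        return CompositionMatrix(self.data.loc[taxa], taxonomy, traits, self.marker)

    def drop_taxa(self, taxa) -> "CompositionMatrix":
        keep = self.data.index.difference(pd.Index(taxa))
        return self.subset_taxa(keep)

    def sample_vector(self, bag, day) -> np.ndarray:
        return self.data[(bag, day)].to_numpy(dtype=float)


def read_composition(path, marker: str = "18S",
                     drop_chloroplast: bool = False) -> CompositionMatrix:
    """Read a taxa × samples matrix (first column taxon id, remaining columns
    ``bag:day`` sample labels; counts or proportions) and normalize.

    An optional trailing ``taxonomy`` column carries annotation strings.
    """
    df = _read_delimited(path).set_index("taxon")
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df.pop("taxonomy").astype(str)
    cols = pd.MultiIndex.from_tuples(
        [(c.split(":")[0], float(c.split(":")[1])) for c in df.columns],
        names=["bag", "day"],
    )
    df.columns = cols
    df = df.astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative entries")
    mat = CompositionMatrix(df, taxonomy=taxonomy, marker=marker)
    return mat.normalize(drop_chloroplast=drop_chloroplast)


def write_composition(matrix: CompositionMatrix, path) -> None:
    df = matrix.data.copy()
    df.columns = [f"{b}:{d:g}" for b, d in df.columns]
    if matrix.taxonomy is not None:
        df["taxonomy"] = matrix.taxonomy
    df.index.name = "taxon"
    df.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# Smoothing


def moving_average(series, width: int):
    """Centered running mean with shrinking windows at the boundaries.

    ``width`` is the nominal window size in points; at each position the
    mean is taken over the available points of the centered window, so the
    output has the same length as the input.  For even widths the window
    extends one further point to the left (trailing-biased), matching the
    width-2 smoothing convention (mean of the point and its predecessor).
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    x = np.asarray(series, dtype=float)
    n = len(x)
    left = width // 2
    right = width - left - 1
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i + right + 1)
        out[i] = x[lo:hi].mean()
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out


# ---------------------------------------------------------------------------
# AnalysisConfig


@dataclass
class AnalysisConfig:
    """Flat configuration shared across stages.

    The defaults encode the analysis conventions: a loss-rate grid from 0 to
    0.5 in steps of 0.0025, a Bray–Curtis similarity floor of 0.05, dilution
    t-tests at alpha = 0.1, Bonferroni correction for the differential-
    abundance screen, and the three bloom phases (mixed bloom days 0–9,
    *E. huxleyi* growth 10–17, demise 18–23).
    """

    d_min: float = 0.0
    d_max: float = 0.5
    d_step: float = 0.0025
    bc_floor: float = 0.05
    dilution_alpha: float = 0.1
    mtc_method: str = "bonferroni"
    diff_alpha: float = 0.05
    i_min: float = 0.0
    i_max: float = 10.0
    i_step: float = 0.05
    phase_mixed: tuple = (0, 9)
    phase_growth: tuple = (10, 17)
    phase_demise: tuple = (18, 23)
    divergence_start_days: tuple = (11, 12, 13)
    seed: int = 0

    def __post_init__(self):
        if self.d_step <= 0:
            raise ValueError("grid step must be > 0")
        if not (0 <= self.bc_floor < 1):
            raise ValueError("BC floor must lie in [0, 1)")

    @property
    def d_grid(self) -> np.ndarray:
        n = int(round((self.d_max - self.d_min) / self.d_step))
        return self.d_min + self.d_step * np.arange(n + 1)

    @property
    def i_grid(self) -> np.ndarray:
        n = int(round((self.i_max - self.i_min) / self.i_step))
        return self.i_min + self.i_step * np.arange(n + 1)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        return cfg

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})
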