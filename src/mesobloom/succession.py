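"""Community-dynamics statistics: ordering, clustering, turnover,
divergence, differential abundance, trait aggregation.

Operates on :class:`~mesobloom.tables_io.CompositionMatrix` objects (taxa ×
(bag, day) relative abundances standing in for 16S/18S ASV tables).

The turnover model: for a bag, the Bray–Curtis similarity between the
community at a start day t' and each later day t declines roughly
exponentially but levels out at a floor BC∞ (taxa present in every sample
keep a minimal similarity between time points), so fits use

    BC(t) = (1 - BC∞) · exp(-k (t - t')) + BC∞,   k >= 0,

with BC∞ fixed (default 0.05).  The divergence statistic asks whether a
focal bag's community moved away from the other bags between the onset of
the *E. huxleyi* bloom (start days 11–13) and a later day, normalizing
end-day between-bag distances by start-day distances so that 1 means "no
more different than it already was".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .tables_io import CompositionMatrix, logger, moving_average

# named filter presets: (min abundance, min samples, use max-over-samples)
FILTER_PRESETS = {
    "heatmap_16s": (0.02, 4, False),
    "heatmap_18s": (0.02, 8, False),
    "cluster": (0.02, 5, True),
    "diff": (0.10, 1, True),
}


def bray_curtis_similarity(x, y) -> float:
    """Bray–Curtis similarity 1 - sum|x-y| / sum(x+y) for non-negative
    vectors; 1 for identical vectors, 0 for disjoint supports."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("entries must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return 1.0 - np.abs(x - y).sum() / denom


@dataclass
class TurnoverFit:
    bag_id: object
    start_day: float
    rate: float              # k, per day
    floor: float             # BC_inf
    residual: float          # RMS residual of the fit
    days: np.ndarray
    similarities: np.ndarray
    flags: tuple = ()

    @property
    def e_folding_days(self) -> float:
        return np.inf if self.rate == 0 else 1.0 / self.rate

    @property
    def half_life_days(self) -> float:
        return np.inf if self.rate == 0 else np.log(2.0) / self.rate


def turnover_curve(dt, k, floor):
    """BC(t' + dt) under the exponential-decay-to-floor model."""
    return (1.0 - floor) * np.exp(-k * np.asarray(dt, dtype=float)) + floor


def fit_turnover(matrix: CompositionMatrix, bag, start_day: float,
                 floor: float = 0.05) -> TurnoverFit:
    """Least-squares turnover rate of one bag from a fixed start day.

    Builds the similarity curve BC(t) against the start-day composition for
    every later sampled day and fits the floored exponential with k
    constrained non-negative.  If the community never decays (all
    similarities within 1e-6 of 1) the fit is flagged degenerate with k=0.
    """
    sub = matrix.data[bag]
    days = np.array(sorted(d for d in sub.columns if d >= start_day), dtype=float)
    if len(days) < 4:
        raise ValueError("need >= 3 time points after the start day")
    ref = sub[days[0]].to_numpy(dtype=float)
    sims = np.array(
        [bray_curtis_similarity(ref, sub[d].to_numpy(dtype=float)) for d in days]
    )
    dt = days - days[0]
    if np.all(sims >= 1.0 - 1e-6):
        return TurnoverFit(bag, days[0], 0.0, floor, 0.0, days, sims,
                           flags=("degenerate-no-decay",))

    # linearized warm start on points above the floor
    above = sims > floor + 1e-9
    if above[1:].any():
        z = -np.log((sims[above] - floor) / (1.0 - floor))
        denom = np.sum(dt[above] ** 2)
        k0 = max(np.sum(z * dt[above]) / denom, 0.0) if denom > 0 else 0.1
    else:
        k0 = 1.0
    res = optimize.least_squares(
        lambda k: turnover_curve(dt, k[0], floor) - sims,
        x0=[max(k0, 1e-6)],
        bounds=([0.0], [np.inf]),
    )
    k = float(res.x[0])
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return TurnoverFit(bag, days[0], k, floor, rms, days, sims)


def center_of_mass(profile) -> float:
    """Abundance-weighted mean day of a per-day profile (used to order
    heatmap rows after per-row max-normalization)."""
    if isinstance(profile, pd.Series):
        t = profile.index.to_numpy(dtype=float)
        f = profile.to_numpy(dtype=float)
    else:
        f = np.asarray(profile, dtype=float)
        t = np.arange(len(f), dtype=float)
    total = f.sum()
    if total <= 0:
        raise ValueError("all-zero profile")
    return float((t * f).sum() / total)


def filter_asvs(matrix: CompositionMatrix, min_abund: float, min_samples: int,
                use_max: bool = False) -> CompositionMatrix:
    """Retain taxa by prevalence/abundance (boundaries inclusive).

    ``use_max=False``: keep taxa at relative abundance >= ``min_abund`` in
    >= ``min_samples`` samples (heatmap rule).  ``use_max=True``: keep taxa
    whose maximum abundance is >= ``min_abund`` and that are present
    (nonzero) in >= ``min_samples`` samples (clustering / differential
    screen rule)."""
    data = matrix.data
    if use_max:
        keep = (data.max(axis=1) >= min_abund) & ((data > 0).sum(axis=1) >= min_samples)
    else:
        keep = (data >= min_abund).sum(axis=1) >= min_samples
    return matrix.subset_taxa(data.index[keep])


@dataclass
class ClusterResult:
    labels: pd.Series              # taxon -> cluster id
    n_clusters: int
    silhouette_by_k: dict          # candidate k -> score
    mean_profiles: pd.DataFrame    # cluster x day
    sd_profiles: pd.DataFrame
    flags: tuple = ()


def _mean_smoothed_profiles(matrix: CompositionMatrix, smooth_width: int = 2
                            ) -> pd.DataFrame:
    """Per-taxon day profile: relative abundance averaged across bags,
    then smoothed with a width-2 moving average."""
    by_day = matrix.data.T.groupby(level="day").mean().T  # taxa x day
    by_day = by_day[sorted(by_day.columns)]
    smoothed = by_day.apply(
        lambda row: pd.Series(moving_average(row.to_numpy(), smooth_width),
                              index=by_day.columns),
        axis=1,
    )
    return smoothed


def cluster_succession(matrix: CompositionMatrix, k_range=range(2, 13),
                       seed: int = 0, n_restarts: int = 10,
                       smooth_width: int = 2) -> ClusterResult:
    """Cosine k-means over smoothed mean taxon profiles with silhouette
    model selection.

    Profiles are L2-normalized so Euclidean k-means orders identically to
    cosine distance; the silhouette (cosine metric) is computed for each
    candidate cluster count and the count with the maximal positive score
    wins.  Identical profiles across all taxa yield a single flagged
    cluster.
    """
    if matrix.data.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    profiles = _mean_smoothed_profiles(matrix, smooth_width)
    X = profiles.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    Xn = X / norms

    if np.allclose(Xn, Xn[0], atol=1e-12):
        labels = pd.Series(0, index=profiles.index)
        return ClusterResult(labels, 1, {},
                             profiles.mean().to_frame().T,
                             profiles.std().to_frame().T * 0,
                             flags=("degenerate-identical-profiles",))

    scores, labelings = {}, {}
    for k in k_range:
        if k >= len(profiles):
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(Xn)
        if len(np.unique(lab)) < 2:
            continue
        scores[k] = float(silhouette_score(Xn, lab, metric="cosine"))
        labelings[k] = lab
    if not scores:
        raise ValueError("no valid candidate cluster counts in k_range")
    positive = {k: s for k, s in scores.items() if s > 0}
    chosen_pool = positive if positive else scores
    k_best = max(sorted(chosen_pool), key=lambda k: chosen_pool[k])
    lab = labelings[k_best]
    labels = pd.Series(lab, index=profiles.index, name="cluster")
    mean_profiles = profiles.groupby(labels).mean()
    sd_profiles = profiles.groupby(labels).std().fillna(0.0)
    flags = () if positive else ("no-positive-silhouette",)
    logger.info("cluster selection: k=%d (silhouette %.3f) among %s",
                k_best, chosen_pool[k_best], sorted(scores))
    return ClusterResult(labels, int(k_best), scores, mean_profiles,
                         sd_profiles, flags)


def divergence(matrix: CompositionMatrix, start_days=(11, 12, 13),
               end_day: float = 23, exclude_taxa=None) -> pd.DataFrame:
    """Per-bag community divergence between bloom onset and a later day.

    For each focal bag: mean Bray–Curtis *distance* to every other bag at
    ``end_day``, divided by the same quantity at each start day; returns
    the mean and standard deviation over start days.  ``exclude_taxa``
    removes rows (e.g. the *E. huxleyi* ASV for 18S) before renormalizing.
    """
    if exclude_taxa is not None:
        matrix = matrix.drop_taxa(exclude_taxa).normalize()
    bags = sorted(matrix.data.columns.get_level_values("bag").unique())
    if len(bags) < 2:
        raise ValueError("need >= 2 bags")
    days_available = set(matrix.data.columns.get_level_values("day"))
    if end_day not in days_available:
        raise ValueError(f"end day {end_day} not sampled")

    def mean_dist(focal, day):
        x = matrix.sample_vector(focal, day)
        others = [
            1.0 - bray_curtis_similarity(x, matrix.sample_vector(b, day))
            for b in bags
            if b != focal
        ]
        return float(np.mean(others))

    rows = []
    for focal in bags:
        ratios = []
        for s in start_days:
            if s not in days_available:
                raise ValueError(f"start day {s} not sampled")
            base = mean_dist(focal, s)
            if base == 0:
                ratios.append(1.0 if mean_dist(focal, end_day) == 0 else np.inf)
            else:
                ratios.append(mean_dist(focal, end_day) / base)
        rows.append((focal, float(np.mean(ratios)), float(np.std(ratios))))
    return pd.DataFrame(rows, columns=["bag", "divergence", "sd"]).set_index("bag")


def differential_abundance(matrix: CompositionMatrix, focal_bag,
                           demise_days, alpha: float = 0.05,
                           method: str = "bonferroni") -> pd.DataFrame:
    """Mann–Whitney screen for taxa over/under-represented in a focal bag.

    For each (pre-filtered) taxon, a two-sided Mann–Whitney U test compares
    its relative abundances in the focal bag against the pooled values of
    all other bags over the demise time points; p-values are corrected
    (Bonferroni by default) and taxa with adjusted p < alpha are returned
    with the sign of the median difference.
    """
    data = matrix.data
    demise_days = [float(d) for d in demise_days]
    day_level = data.columns.get_level_values("day")
    bag_level = data.columns.get_level_values("bag")
    in_demise = np.isin(day_level, demise_days)
    focal_cols = (bag_level == focal_bag) & in_demise
    other_cols = (bag_level != focal_bag) & in_demise
    if focal_cols.sum() < 2 or other_cols.sum() < 2:
        raise ValueError("need >= 2 observations per group over demise days")

    results = []
    for taxon, row in data.iterrows():
        a = row.to_numpy(dtype=float)[focal_cols]
        b = row.to_numpy(dtype=float)[other_cols]
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic")
        direction = np.sign(np.median(a) - np.median(b))
        results.append((taxon, direction, p))
    df = pd.DataFrame(results, columns=["taxon", "direction", "p"])
    df["p_adj"] = multipletests(df["p"], method=method)[1]
    hits = df[df["p_adj"] < alpha].set_index("taxon")
    return hits.sort_values("p_adj")


def aggregate_traits(matrix: CompositionMatrix, phases: dict) -> pd.DataFrame:
    """Per-phase trophic-trait shares.

    ``phases`` maps phase name -> (first_day, last_day) inclusive.  Taxa
    without a trophic annotation are excluded; within each sample the
    annotated relative abundances are summed per trait and renormalized,
    then averaged over the phase's days and bags.  Heterotroph sub-modes
    (osmotroph / saprotroph / other) are reported alongside.
    """
    if matrix.traits is None or matrix.traits.empty:
        raise ValueError("no trait annotations available")
    annotated = matrix.traits.index.intersection(matrix.data.index)
    if len(annotated) == 0:
        raise ValueError("no annotated taxa present in the matrix")
    data = matrix.data.loc[annotated]
    traits = matrix.traits.loc[annotated]
    day_level = data.columns.get_level_values("day")

    rows = []
    for phase, (lo, hi) in phases.items():
        cols = (day_level >= lo) & (day_level <= hi)
        if not cols.any():
            continue
        sub = data.loc[:, cols]
        totals = sub.sum(axis=0)
        shares = sub / totals  # renormalize over annotated taxa per sample
        mode_share = shares.groupby(traits["trophic_mode"]).sum().mean(axis=1)
        for mode, val in mode_share.items():
            rows.append((phase, mode, "", float(val)))
        het = traits["trophic_mode"] == "heterotroph"
        if het.any():
            het_shares = shares.loc[het[het].index]
            het_total = het_shares.sum(axis=0)
            het_total[het_total == 0] = np.nan
            sub_share = (
                het_shares.groupby(traits.loc[het[het].index, "sub_mode"]).sum()
                / het_total
            ).mean(axis=1)
            for sub_mode, val in sub_share.items():
                rows.append((phase, "heterotroph", sub_mode or "other", float(val)))
    return pd.DataFrame(rows, columns=["phase", "trophic_mode", "sub_mode", "share"])
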