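import numpy as np
import pandas as pd
import pytest
from scipy.spatial import distance as spdist

from mesobloom import succession, synthetic
from mesobloom.succession import (
    aggregate_traits,
    bray_curtis_similarity,
    center_of_mass,
    cluster_succession,
    differential_abundance,
    divergence,
    filter_asvs,
    fit_turnover,
    turnover_curve,
)
from mesobloom.tables_io import CompositionMatrix

from conftest import two_taxon_matrix


def simple_matrix(array, bags=("bag1",), taxa=None, traits=None):
    array = np.asarray(array, dtype=float)
    n_taxa, n_cols = array.shape
    days = np.arange(n_cols / len(bags))
    cols = pd.MultiIndex.from_product([bags, days], names=["bag", "day"])
    taxa = taxa or [f"t{i}" for i in range(n_taxa)]
    data = pd.DataFrame(array, index=taxa, columns=cols)
    trait_df = None
    if traits is not None:
        trait_df = pd.DataFrame(traits, index=taxa,
                                columns=["trophic_mode", "sub_mode"])
    return CompositionMatrix(data, traits=trait_df)


class TestBrayCurtis:
    def test_identity(self):
        x = np.array([0.2, 0.3, 0.5])
        assert bray_curtis_similarity(x, x) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert bray_curtis_similarity([1, 0, 0], [0, 0.5, 0.5]) == pytest.approx(0.0)

    def test_hand_example(self):
        assert bray_curtis_similarity(
            [0.5, 0.5, 0], [0.25, 0.25, 0.5]
        ) == pytest.approx(0.5)

    def test_matches_scipy_dissimilarity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x, y = rng.uniform(0, 1, (2, 12))
            assert bray_curtis_similarity(x, y) == pytest.approx(
                1.0 - spdist.braycurtis(x, y), abs=1e-12
            )

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.uniform(0, 1, (2, 9))
        assert bray_curtis_similarity(x, y) == bray_curtis_similarity(y, x)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_similarity([0, 0], [0, 0])


class TestTurnover:
    def test_constant_composition_flags_zero_rate(self):
        mat = simple_matrix(np.tile([[0.3], [0.7]], 10))
        fit = fit_turnover(mat, "bag1", 0)
        assert fit.rate == 0.0
        assert "degenerate-no-decay" in fit.flags

    @pytest.mark.parametrize("k_true", [0.05, 0.2, 0.8])
    def test_exact_inversion(self, k_true):
        """A similarity curve synthesized from the floored exponential is
        inverted to the generating rate within 1e-6."""
        days = np.arange(0.0, 15.0)
        sims = turnover_curve(days, k_true, 0.05)
        mat = two_taxon_matrix(sims, days)
        fit = fit_turnover(mat, "bag1", 0, floor=0.05)
        assert fit.rate == pytest.approx(k_true, abs=1e-6)
        assert fit.residual < 1e-9

    def test_monotone_in_replacement_rate(self):
        """Communities with faster random taxon replacement turn over
        faster (larger fitted k)."""
        def replaced_community(rate, seed):
            rng = np.random.default_rng(seed)
            n_taxa, n_days = 40, 15
            comp = np.zeros((n_taxa + n_days, n_days))
            comp[:n_taxa, 0] = rng.dirichlet(np.ones(n_taxa))
            for t in range(1, n_days):
                comp[:, t] = comp[:, t - 1] * (1 - rate)
                comp[n_taxa + t, t] = rate  # fresh taxon takes over `rate`
            cols = pd.MultiIndex.from_product(
                [["bag1"], np.arange(n_days, dtype=float)], names=["bag", "day"])
            return CompositionMatrix(pd.DataFrame(comp, columns=cols))

        k_fast = fit_turnover(replaced_community(0.2, 0), "bag1", 0).rate
        k_slow = fit_turnover(replaced_community(0.1, 0), "bag1", 0).rate
        assert k_fast > k_slow > 0

    def test_requires_enough_timepoints(self):
        mat = simple_matrix(np.tile([[0.3], [0.7]], 3))
        with pytest.raises(ValueError):
            fit_turnover(mat, "bag1", 0)

    def test_derived_timescales(self):
        days = np.arange(0.0, 15.0)
        fit = fit_turnover(two_taxon_matrix(turnover_curve(days, 0.2, 0.05), days),
                           "bag1", 0)
        assert fit.e_folding_days == pytest.approx(5.0, rel=1e-5)
        assert fit.half_life_days == pytest.approx(np.log(2) / 0.2, rel=1e-5)


class TestCenterOfMass:
    def test_single_support_day(self):
        assert center_of_mass(pd.Series([0, 0, 3.0, 0], index=[0, 1, 2, 3])) == 2

    def test_hand_example(self):
        assert center_of_mass(
            pd.Series([1.0, 0, 0, 1.0], index=[0, 1, 2, 3])
        ) == pytest.approx(1.5)

    def test_symmetric_bump(self):
        prof = np.exp(-0.5 * (np.arange(5) - 2.0) ** 2)
        assert center_of_mass(prof) == pytest.approx(2.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            center_of_mass(np.zeros(4))


class TestFilterAsvs:
    def test_rare_taxon_removed(self):
        mat = simple_matrix(np.vstack([np.full(10, 0.01), np.full(10, 0.99)]))
        out = filter_asvs(mat, 0.02, 4)
        assert "t0" not in out.taxa

    def test_boundary_inclusive(self):
        row = np.zeros(10)
        row[:4] = 0.03
        mat = simple_matrix(np.vstack([row, 1 - row]))
        out = filter_asvs(mat, 0.02, 4)
        assert "t0" in out.taxa

    def test_planted_pass_fail_counts(self):
        """Brute-force check of the retained count on a random matrix."""
        rng = np.random.default_rng(8)
        raw = rng.uniform(0, 0.1, (30, 12))
        mat = simple_matrix(raw / raw.sum(axis=0))
        expected = sum(
            ((raw / raw.sum(axis=0))[i] >= 0.04).sum() >= 3 for i in range(30)
        )
        assert len(filter_asvs(mat, 0.04, 3).taxa) == expected


class TestClustering:
    def test_identical_profiles_degenerate(self):
        mat = simple_matrix(np.tile(np.linspace(0.1, 1, 10), (5, 1)))
        res = cluster_succession(mat)
        assert res.n_clusters == 1
        assert "degenerate-identical-profiles" in res.flags

    def test_recovers_planted_clusters(self, clean_scenario):
        mat = synthetic.generate_composition(clean_scenario,
                                             differential_bag=None)
        filtered = filter_asvs(mat, 0.02, 5, use_max=True)
        res = cluster_succession(filtered, seed=0)
        assert res.n_clusters == 6
        # selected count maximizes the silhouette among all candidates
        assert res.silhouette_by_k[6] == max(res.silhouette_by_k.values())

    def test_invariant_to_taxon_order(self, clean_scenario):
        mat = synthetic.generate_composition(clean_scenario,
                                             differential_bag=None)
        res = cluster_succession(mat, seed=0)
        perm = mat.data.sample(frac=1, random_state=4).index
        res_p = cluster_succession(mat.subset_taxa(perm), seed=0)
        # same partition up to label renaming
        ref = res.labels.loc[perm]
        mapping = {}
        for a, b in zip(res_p.labels, ref):
            mapping.setdefault(a, b)
            assert mapping[a] == b

    def test_k_range_exceeding_taxa(self):
        mat = simple_matrix(np.vstack([np.linspace(0, 1, 8),
                                       np.linspace(1, 0, 8)]))
        with pytest.raises(ValueError):
            cluster_succession(mat, k_range=[5, 6])


class TestDivergence:
    def _bags_matrix(self, perturb_bag=None, seed=0):
        rng = np.random.default_rng(seed)
        bags = [f"bag{i}" for i in range(1, 5)]
        days = np.arange(24.0)
        base = rng.dirichlet(np.ones(12))
        frames = {}
        for bag in bags:
            profile = np.tile(base[:, None], (1, len(days)))
            profile = profile * (1 + 0.05 * rng.standard_normal(profile.shape))
            if bag == perturb_bag:
                profile[:, 14:] = rng.dirichlet(np.ones(12))[:, None]
            frames[bag] = profile
        cols = pd.MultiIndex.from_product([bags, days], names=["bag", "day"])
        data = pd.DataFrame(np.hstack([frames[b] for b in bags]),
                            index=[f"t{i}" for i in range(12)], columns=cols)
        return CompositionMatrix(data).normalize()

    def test_identical_bags_give_unity(self):
        days = np.arange(24.0)
        bags = ["bag1", "bag2", "bag3"]
        cols = pd.MultiIndex.from_product([bags, days], names=["bag", "day"])
        data = pd.DataFrame(
            np.tile(np.array([[0.4], [0.6]]), (1, len(cols))),
            index=["A", "B"], columns=cols,
        )
        out = divergence(CompositionMatrix(data), (11, 12, 13), 23)
        np.testing.assert_allclose(out["divergence"], 1.0)

    def test_perturbed_focal_bag_diverges(self):
        mat = self._bags_matrix(perturb_bag="bag4")
        out = divergence(mat, (11, 12, 13), 23)
        assert out.loc["bag4", "divergence"] > 1.5
        others = out.drop("bag4")["divergence"]
        assert (others < out.loc["bag4", "divergence"]).all()

    def test_invariant_to_bag_relabeling(self):
        mat = self._bags_matrix(perturb_bag="bag2", seed=5)
        out = divergence(mat, (11, 12, 13), 23)
        relabeled = mat.data.copy()
        relabeled.columns = pd.MultiIndex.from_tuples(
            [(b.replace("bag", "enclosure"), d) for b, d in relabeled.columns],
            names=["bag", "day"],
        )
        out2 = divergence(CompositionMatrix(relabeled), (11, 12, 13), 23)
        np.testing.assert_allclose(out2["divergence"].to_numpy(),
                                   out["divergence"].to_numpy(), rtol=1e-12)

    def test_missing_end_day_rejected(self):
        mat = self._bags_matrix()
        with pytest.raises(ValueError):
            divergence(mat, (11, 12, 13), 99)


class TestDifferentialAbundance:
    def test_identical_distributions_yield_nothing(self):
        rng = np.random.default_rng(9)
        bags = [f"bag{i}" for i in range(1, 5)]
        days = np.arange(24.0)
        cols = pd.MultiIndex.from_product([bags, days], names=["bag", "day"])
        base = rng.uniform(0.1, 1, (6, len(days)))
        data = pd.DataFrame(np.hstack([base] * len(bags)),
                            index=[f"t{i}" for i in range(6)], columns=cols)
        hits = differential_abundance(CompositionMatrix(data).normalize(),
                                      "bag2", range(18, 24))
        assert hits.empty

    def test_planted_enrichment_detected(self, noisy_scenario):
        mat = synthetic.generate_composition(noisy_scenario)
        screened = filter_asvs(mat, 0.10, 1, use_max=True)
        hits = differential_abundance(screened, "bag7", range(18, 24))
        assert "18S_diff_enriched" in hits.index
        assert hits.loc["18S_diff_enriched", "direction"] == 1

    def test_rank_test_invariant_to_monotone_transform(self, noisy_scenario):
        mat = synthetic.generate_composition(noisy_scenario)
        screened = filter_asvs(mat, 0.10, 1, use_max=True)
        transformed = CompositionMatrix(np.sqrt(screened.data),
                                        traits=screened.traits)
        a = differential_abundance(screened, "bag7", range(18, 24), alpha=1.1)
        b = differential_abundance(transformed, "bag7", range(18, 24), alpha=1.1)
        np.testing.assert_allclose(a["p"], b.loc[a.index, "p"], rtol=1e-9)


class TestAggregateTraits:
    PHASES = {"mixed": (0, 9), "growth": (10, 17), "demise": (18, 23)}

    def test_all_autotrophs_share_one(self):
        mat = simple_matrix(
            np.full((3, 24), 1 / 3),
            traits=[("autotroph", "")] * 3,
        )
        out = aggregate_traits(mat, self.PHASES)
        auto = out[(out.trophic_mode == "autotroph") & (out.sub_mode == "")]
        np.testing.assert_allclose(auto["share"], 1.0)

    def test_two_taxon_split(self):
        mat = simple_matrix(
            np.vstack([np.full(24, 0.4), np.full(24, 0.6)]),
            traits=[("autotroph", ""), ("heterotroph", "osmotroph")],
        )
        out = aggregate_traits(mat, {"all": (0, 23)}).set_index(
            ["trophic_mode", "sub_mode"])
        assert out.loc[("autotroph", ""), "share"] == pytest.approx(0.4)
        assert out.loc[("heterotroph", ""), "share"] == pytest.approx(0.6)
        assert out.loc[("heterotroph", "osmotroph"), "share"] == pytest.approx(1.0)

    def test_mode_shares_sum_to_one(self, noisy_scenario):
        mat = synthetic.generate_composition(noisy_scenario)
        out = aggregate_traits(mat, self.PHASES)
        top = out[out.sub_mode == ""]
        for _, grp in top.groupby("phase"):
            assert grp["share"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_annotations_rejected(self):
        mat = simple_matrix(np.full((2, 5), 0.5))
        with pytest.raises(ValueError):
            aggregate_traits(mat, self.PHASES)
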