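import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agehet.change_models import fit_dataset
from agehet.meta_consistency import (
    consistency_analysis,
    consistency_counts,
    consistency_null_test,
    count_distribution,
    independent_triple_correlation_test,
    pca_dispersion_summary,
    period_difference_test,
    permute_individual_ages,
    permuted_heterogeneity,
    permuted_expression_change,
)
from agehet.synthetic_data import SimulationConfig, simulate_collection
from conftest import make_dataset
from agehet.core_data import StudyCollection


class TestPermutationSet:
    def test_swap_propagates_to_all_region_datasets(self, two_region_collection):
        pset = permute_individual_ages(two_region_collection, n_perm=50, seed=0)
        ds1 = two_region_collection.datasets["study1_region01"]
        ds2 = two_region_collection.datasets["study1_region02"]
        a1 = pset.ages_for_dataset(ds1)
        a2 = pset.ages_for_dataset(ds2)
        # same individuals in the same order -> identical permuted ages
        assert list(ds1.meta["individual_id"]) == list(ds2.meta["individual_id"])
        np.testing.assert_array_equal(a1, a2)

    def test_age_multiset_preserved_every_permutation(self, two_region_collection):
        pset = permute_individual_ages(two_region_collection, n_perm=25, seed=1)
        for study in two_region_collection.studies:
            observed = np.sort(pset.observed_ages[study])
            for k in range(pset.n_perm):
                np.testing.assert_array_equal(np.sort(pset.perm_ages[study][k]), observed)

    def test_deterministic_given_seed(self, two_region_collection):
        p1 = permute_individual_ages(two_region_collection, n_perm=10, seed=9)
        p2 = permute_individual_ages(two_region_collection, n_perm=10, seed=9)
        for study in p1.perm_ages:
            np.testing.assert_array_equal(p1.perm_ages[study], p2.perm_ages[study])

    def test_single_individual_study_rejected(self):
        ds = make_dataset(ages_years=(30, 30, 30, 30), n_genes=3)
        meta = ds.meta.copy()
        meta["individual_id"] = "only_one"
        meta["sex"] = "female"
        from agehet.core_data import ExpressionDataset

        solo = ExpressionDataset(ds.name, ds.expr, meta)
        with pytest.raises(ValueError, match="fewer than 2"):
            permute_individual_ages(StudyCollection({solo.name: solo}), n_perm=5, seed=0)


class TestPermutedHeterogeneity:
    def test_identity_permutation_reproduces_observed_rho(self, two_region_collection):
        tables, residuals = {}, {}
        for name, ds in two_region_collection.datasets.items():
            tables[name], residuals[name] = fit_dataset(ds)
        pset = permute_individual_ages(two_region_collection, n_perm=3, seed=0)
        # overwrite permutation 0 with the identity
        for study in pset.perm_ages:
            pset.perm_ages[study][0] = pset.observed_ages[study]
        rho_star = permuted_heterogeneity(two_region_collection, residuals, pset)
        for name in two_region_collection.names:
            np.testing.assert_allclose(
                rho_star[name][:, 0], tables[name]["rho"].to_numpy(), atol=1e-10
            )

    def test_heteroskedastic_gene_beats_null(self):
        cfg = SimulationConfig(
            n_studies=1, regions_per_study=(1,), n_individuals=(60,), n_genes=30,
            frac_het_increase=1.0 / 30, var_slope_range=(2.0, 2.0), seed=8,
        )
        coll = simulate_collection(cfg)
        name = coll.names[0]
        table, resid = fit_dataset(coll.datasets[name])
        pset = permute_individual_ages(coll, n_perm=200, seed=1)
        rho_star = permuted_heterogeneity(coll, {name: resid}, pset)[name]
        planted = coll.planted_increase[0]
        i = list(table.index).index(planted)
        assert table.loc[planted, "rho"] > np.quantile(rho_star[i], 0.95)

    def test_mismatched_gene_sets_rejected(self, two_region_collection):
        _, resid = fit_dataset(two_region_collection.datasets["study1_region01"])
        residuals = {}
        for j, name in enumerate(two_region_collection.names):
            _, r = fit_dataset(two_region_collection.datasets[name])
            residuals[name] = r.iloc[: len(r) - j]  # progressively truncate
        pset = permute_individual_ages(two_region_collection, n_perm=2, seed=0)
        with pytest.raises(ValueError, match="mismatched"):
            permuted_heterogeneity(two_region_collection, residuals, pset)

    def test_permuted_beta_refit_matches_direct_fit(self, two_region_collection):
        from agehet.core_data import transform_age
        from agehet.change_models import fit_expression_change

        pset = permute_individual_ages(two_region_collection, n_perm=4, seed=2)
        out = permuted_expression_change(two_region_collection, pset)
        name = "study2_region01"
        ds = two_region_collection.datasets[name]
        perm_ages = pset.ages_for_dataset(ds)
        for k in range(4):
            t = transform_age(perm_ages[k])
            fit = fit_expression_change(ds.expr.iloc[0].to_numpy(), t)
            assert out[name]["beta"][0, k] == pytest.approx(fit.beta1, abs=1e-10)
            assert out[name]["p"][0, k] == pytest.approx(fit.p_beta, abs=1e-10)


class TestConsistencyCounts:
    def test_counts_positive_entries(self):
        m = pd.DataFrame({"a": [0.1, -0.5], "b": [-0.2, 0.0], "c": [0.3, 0.2]}, index=["g1", "g2"])
        out = consistency_counts(m)
        assert out["g1"] == 2 and out["g2"] == 1  # rho = 0 is not-up

    def test_all_positive(self):
        m = pd.DataFrame(np.full((2, 19), 0.5))
        assert (consistency_counts(m) == 19).all()

    def test_negation_identity(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(40, 7)))
        m.iloc[0, 0] = 0.0
        up = consistency_counts(m)
        down = consistency_counts(-m)
        zeros = (m == 0).sum(axis=1)
        np.testing.assert_array_equal(down.to_numpy(), 7 - up.to_numpy() - zeros.to_numpy())

    def test_count_distribution_sums_to_genes(self):
        n_up = pd.Series([0, 3, 3, 1, 2])
        dist = count_distribution(n_up, 3)
        assert dist.sum() == 5
        np.testing.assert_array_equal(dist, [1, 1, 1, 2])


class TestConsistencyNullTest:
    def test_floor_when_observed_above_all_permutations(self):
        perm = np.zeros((200, 4), dtype=int)
        obs = np.array([0, 0, 0, 50])
        p = consistency_null_test(obs, perm)
        assert p[3] == pytest.approx(1 / 201)

    def test_median_observation_near_half(self):
        rng = np.random.default_rng(0)
        perm = rng.integers(0, 100, size=(999, 2))
        obs = np.median(perm, axis=0)
        p = consistency_null_test(obs, perm)
        assert np.all((p > 0.35) & (p < 0.7))

    def test_requires_100_permutations(self):
        with pytest.raises(ValueError):
            consistency_null_test(np.array([1]), np.zeros((50, 1)))

    def test_independent_null_binomial_scale(self):
        # truly independent datasets: P(all K positive) = 2^-K per gene
        rng = np.random.default_rng(42)
        n_genes, K = 5000, 8
        rho = pd.DataFrame(rng.normal(size=(n_genes, K)))
        n_up = consistency_counts(rho)
        observed = (n_up == K).sum()
        expected = n_genes * 0.5**K
        assert abs(observed - expected) < 4 * np.sqrt(expected)


class TestIndependentTriples:
    def test_enumerates_product_of_studies(self):
        rng = np.random.default_rng(0)
        sizes = {"s1": 16, "s2": 2, "s3": 1}
        names, study_of = [], {}
        for s, k in sizes.items():
            for i in range(k):
                n = f"{s}_d{i}"
                names.append(n)
                study_of[n] = s
        stat = pd.DataFrame(rng.normal(size=(30, len(names))), columns=names)
        perm = {n: rng.normal(size=(30, 11)) for n in names}
        obs, p, null = independent_triple_correlation_test(stat, study_of, perm)
        assert null.size == 11
        assert 0 < p <= 1
        # the statistic is a median over 16*2*1 = 32 triples
        n_triples = np.prod(list(sizes.values()))
        assert n_triples == 32

    def test_identical_signal_reaches_p_floor(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=100)
        stat = pd.DataFrame({f"d{i}": base for i in range(3)})
        study_of = {f"d{i}": f"s{i}" for i in range(3)}
        perm = {f"d{i}": rng.normal(size=(100, 99)) for i in range(3)}
        obs, p, _ = independent_triple_correlation_test(stat, study_of, perm)
        assert obs == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_single_study_rejected(self):
        stat = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="2 studies"):
            independent_triple_correlation_test(
                stat, {"a": "s1", "b": "s1"}, {"a": np.zeros((10, 5)), "b": np.zeros((10, 5))}
            )


class TestPeriodDifference:
    @staticmethod
    def _toy(seed, shift=0.0):
        rng = np.random.default_rng(seed)
        names = ["d1", "d2", "d3"]
        dev = pd.DataFrame({n: rng.normal(size=60) for n in names})
        aging = pd.DataFrame({n: rng.normal(loc=shift, size=60) for n in names})
        dev_perm = {n: rng.normal(size=(60, 199)) for n in names}
        aging_perm = {n: rng.normal(size=(60, 199)) for n in names}
        return dev, aging, dev_perm, aging_perm

    def test_shifted_aging_is_detected(self):
        dev, aging, dp, ap = self._toy(0, shift=1.0)
        obs, p, _ = period_difference_test(dev, aging, dp, ap, "median_rho_diff")
        assert obs > 0.5 and p == pytest.approx(1 / 200)

    def test_unknown_statistic_rejected(self):
        dev, aging, dp, ap = self._toy(1)
        with pytest.raises(ValueError, match="unknown statistic"):
            period_difference_test(dev, aging, dp, ap, "bogus")

    def test_zero_permutations_rejected(self):
        dev, aging, *_ = self._toy(2)
        with pytest.raises(ValueError, match="empty"):
            period_difference_test(dev, aging, {}, {}, "median_rho_diff")

    def test_aging_only_heteroskedasticity_detected(self):
        # heterogeneity trend planted in aging, development homoskedastic:
        # the one-sided median-rho-difference test must fire
        cfg = SimulationConfig(
            n_studies=2, regions_per_study=(2, 1), n_individuals=(120, 120),
            n_genes=500, frac_het_increase=1.0, var_slope_range=(1.0, 1.0), seed=30,
        )
        coll = simulate_collection(cfg)
        from agehet.pipeline import split_collection

        dev, aging = split_collection(coll)
        dev_t, dev_r, aging_t, aging_r = {}, {}, {}, {}
        for name in coll.names:
            dev_t[name], dev_r[name] = fit_dataset(dev.datasets[name])
            aging_t[name], aging_r[name] = fit_dataset(aging.datasets[name])
        pset = permute_individual_ages(coll, n_perm=199, seed=0)
        obs, p, _ = period_difference_test(
            pd.DataFrame({n: t["rho"] for n, t in dev_t.items()}),
            pd.DataFrame({n: t["rho"] for n, t in aging_t.items()}),
            permuted_heterogeneity(dev, dev_r, pset),
            permuted_heterogeneity(aging, aging_r, pset),
            "median_rho_diff",
        )
        assert obs > 0
        assert p <= 0.05

    def test_n_significant_diff_runs_and_bounds(self):
        dev, aging, dp, ap = self._toy(3)
        n_of = {n: 40 for n in dev.columns}
        obs, p, null = period_difference_test(
            dev, aging, dp, ap, "n_significant_diff", dev_n=n_of, aging_n=n_of
        )
        assert 0 < p <= 1 and null.size == 199


class TestPcaDispersion:
    def test_identical_datasets_have_zero_distance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        stat = pd.DataFrame({"a": v, "b": v, "c": rng.normal(size=50)})
        _, disp = pca_dispersion_summary(stat, {"a": "x", "b": "x", "c": "y"})
        assert disp["x"] == pytest.approx(0.0, abs=1e-8)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        stat = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        labels = {"a": "p", "b": "p", "c": "q", "d": "q"}
        _, d1 = pca_dispersion_summary(stat, labels)
        shuffled = stat.sample(frac=1.0, random_state=0)
        _, d2 = pca_dispersion_summary(shuffled, labels)
        assert d1["p"] == pytest.approx(d2["p"], abs=1e-8)
        assert d1["q"] == pytest.approx(d2["q"], abs=1e-8)

    def test_too_few_datasets_rejected(self):
        stat = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError):
            pca_dispersion_summary(stat, {0: "a", 1: "b"})


class TestConsistencyAnalysis:
    def test_planted_consistent_genes_enriched_at_max_level(self):
        cfg = SimulationConfig(
            n_studies=2, regions_per_study=(2, 1), n_individuals=(50, 50),
            n_genes=120, frac_het_increase=0.1, var_slope_range=(1.5, 1.5), seed=21,
        )
        coll = simulate_collection(cfg)
        from agehet.pipeline import split_collection

        _, aging = split_collection(coll)
        tables, residuals = {}, {}
        for name, ds in aging.datasets.items():
            tables[name], residuals[name] = fit_dataset(ds)
        rho = pd.DataFrame({n: t["rho"] for n, t in tables.items()})
        pset = permute_individual_ages(coll, n_perm=199, seed=5)
        perm_rho = permuted_heterogeneity(aging, residuals, pset)
        result = consistency_analysis(rho, perm_rho)
        assert result.p_per_level[result.n_datasets] <= 0.05
        hits = set(result.consistent_genes()) & set(coll.planted_increase)
        assert len(hits) >= len(coll.planted_increase) // 2
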