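import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from agehet.core_data import (
    ExpressionDataset,
    StudyCollection,
    batch_mean_restore,
    intersect_common_genes,
    quantile_normalize,
    read_expression_dataset,
    scale_genes,
    split_periods,
    transform_age,
    write_expression_dataset,
)
from conftest import make_dataset


def write_toy_tsvs(tmp_path, expr_rows, meta_rows):
    expr_path = tmp_path / "expr.tsv"
    meta_path = tmp_path / "meta.tsv"
    expr_path.write_text("\n".join("\t".join(map(str, r)) for r in expr_rows) + "\n")
    header = ["sample_id", "individual_id", "age_days", "sex", "region", "study", "batch"]
    lines = ["\t".join(header)] + ["\t".join(map(str, r)) for r in meta_rows]
    meta_path.write_text("\n".join(lines) + "\n")
    return expr_path, meta_path


class TestReader:
    def test_reads_toy_dataset(self, tmp_path):
        expr_path, meta_path = write_toy_tsvs(
            tmp_path,
            [["gene_id", "s1", "s2", "s3"], ["ENSG1", 1.0, 2.0, 3.0], ["ENSG2", 4.0, 5.0, 6.0]],
            [
                ["s1", "i1", 365, "male", "ctx", "st1", ""],
                ["s2", "i2", 730, "female", "ctx", "st1", ""],
                ["s3", "i3", 1095, "male", "ctx", "st1", ""],
            ],
        )
        ds = read_expression_dataset(expr_path, meta_path)
        assert ds.expr.shape == (2, 3)
        assert list(ds.samples) == ["s1", "s2", "s3"]
        assert ds.meta.loc["s2", "age_days"] == 730.0

    def test_missing_sample_in_metadata_names_it(self, tmp_path):
        expr_path, meta_path = write_toy_tsvs(
            tmp_path,
            [["gene_id", "s1", "s9"], ["ENSG1", 1.0, 2.0]],
            [["s1", "i1", 365, "male", "ctx", "st1", ""]],
        )
        with pytest.raises(ValueError, match="s9"):
            read_expression_dataset(expr_path, meta_path)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        expr_path, meta_path = write_toy_tsvs(
            tmp_path,
            [["gene_id", "s1"], ["ENSG1", 1.0], ["ENSG1", 2.0]],
            [["s1", "i1", 365, "male", "ctx", "st1", ""]],
        )
        with pytest.raises(ValueError, match="ENSG1"):
            read_expression_dataset(expr_path, meta_path)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        expr_path, meta_path = write_toy_tsvs(
            tmp_path,
            [["gene_id", "s1", "s2"], ["ENSG1", 1.0, "oops"]],
            [
                ["s1", "i1", 365, "male", "ctx", "st1", ""],
                ["s2", "i2", 730, "male", "ctx", "st1", ""],
            ],
        )
        with pytest.raises(ValueError, match="oops"):
            read_expression_dataset(expr_path, meta_path)

    def test_exclusion_list_and_roundtrip(self, tmp_path):
        ds = make_dataset(n_genes=5)
        write_expression_dataset(ds, tmp_path / "e.tsv", tmp_path / "m.tsv")
        back = read_expression_dataset(tmp_path / "e.tsv", tmp_path / "m.tsv", name=ds.name)
        pd.testing.assert_frame_equal(ds.expr, back.expr, atol=1e-9)
        trimmed = read_expression_dataset(
            tmp_path / "e.tsv", tmp_path / "m.tsv",
            exclude_samples=[ds.samples[0]],
        )
        assert trimmed.n_samples == ds.n_samples - 1


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        X = np.array([[1.0, 2.0], [3.0, 8.0]])
        out = quantile_normalize(X)
        np.testing.assert_allclose(out, [[1.5, 1.5], [5.5, 5.5]])

    def test_order_preserving(self):
        X = np.array([[3.0, 2.0], [1.0, 8.0]])
        out = quantile_normalize(X)
        np.testing.assert_allclose(out, [[5.5, 1.5], [1.5, 5.5]])

    def test_identical_columns_unchanged(self):
        X = np.tile(np.array([[1.0], [4.0], [2.0]]), (1, 3))
        np.testing.assert_allclose(quantile_normalize(X), X)

    def test_single_column_identity(self):
        X = np.array([[3.0], [1.0], [2.0]])
        np.testing.assert_allclose(quantile_normalize(X), X)

    def test_ties_receive_mean_of_reference_span(self):
        # column 2 has a tie at rank positions 1 and 2 -> mean of ref[0:2]
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 9.0]])
        ref = np.sort(X, axis=0).mean(axis=1)
        out = quantile_normalize(X)
        np.testing.assert_allclose(out[:, 1], [ref[:2].mean(), ref[:2].mean(), ref[2]])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.empty((0, 0)))

    @settings(deadline=None, max_examples=25)
    @given(
        arrays(
            np.float64, (6, 4),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
            unique=True,
        )
    )
    def test_idempotent(self, X):
        # tie-free columns: averaging tied ranks alters the column multiset,
        # so exact idempotence only holds without ties
        once = quantile_normalize(X)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice, once, atol=1e-10)


class TestBatchMeanRestore:
    def test_hand_example_restores_grand_mean(self):
        X = np.array([[1.0, 3.0, 10.0, 14.0]])
        out = batch_mean_restore(X, ["b1", "b1", "b2", "b2"])
        expected = 7.0 + np.array([-1, 1, -1, 1]) / np.sqrt(2)
        np.testing.assert_allclose(out, expected[None, :], atol=1e-9)
        assert np.isclose(out.mean(), 7.0)

    def test_single_standardized_batch_unchanged(self):
        x = np.array([[-1.0, 0.0, 1.0]]) / np.sqrt(1.0)  # mean 0, sd(n-1) 1
        out = batch_mean_restore(x, ["b"] * 3)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_constant_batch_rejected(self):
        with pytest.raises(ValueError, match="b1"):
            batch_mean_restore(np.array([[5.0, 5.0, 1.0, 2.0]]), ["b1", "b1", "b2", "b2"])

    def test_singleton_batch_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            batch_mean_restore(np.array([[1.0, 2.0, 3.0]]), ["b1", "b2", "b2"])

    def test_grand_mean_preserved_per_gene(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 12)) * 3 + 5
        labels = np.repeat(["a", "b", "c"], 4)
        out = batch_mean_restore(X, labels)
        np.testing.assert_allclose(out.mean(axis=1), X.mean(axis=1), atol=1e-10)


class TestScaleGenes:
    def test_simple_row(self):
        np.testing.assert_allclose(scale_genes(np.array([[1.0, 2.0, 3.0]])), [[-1, 0, 1]])

    def test_idempotent_on_scaled(self):
        X = scale_genes(np.random.default_rng(1).normal(size=(4, 6)))
        np.testing.assert_allclose(scale_genes(X), X, atol=1e-12)

    def test_constant_gene_listed_in_error(self):
        X = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            scale_genes(X)


class TestTransformAge:
    def test_known_values(self):
        assert transform_age(16.0) == pytest.approx(2.0)
        assert transform_age(0.0) == 0.0
        # 7300 days = 20 years; 7300**(1/4) to high precision
        assert transform_age(7300.0) == pytest.approx(9.2433780325796, abs=1e-10)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            transform_age(-1.0)

    @pytest.mark.parametrize("scale", ["fourth_root", "linear", "sqrt", "log2"])
    def test_strictly_monotone(self, scale):
        ages = np.linspace(0.5, 40000, 200)
        out = transform_age(ages, scale)
        assert np.all(np.diff(out) > 0)


class TestSplitPeriods:
    def test_boundary_goes_to_aging(self):
        ds = make_dataset(ages_years=(1, 19, 20, 30), n_genes=3)
        dev, aging = split_periods(ds)
        assert sorted(dev.ages_years()) == [1, 19]
        assert sorted(aging.ages_years()) == [20, 30]
        assert dev.period == "development" and aging.period == "aging"
        assert dev.n_samples + aging.n_samples == ds.n_samples

    def test_empty_period_warns(self):
        ds = make_dataset(ages_years=(1, 2, 3, 4), n_genes=3)
        with pytest.warns(UserWarning, match="aging"):
            _, aging = split_periods(ds)
        assert aging.n_samples == 0

    def test_cutoff_zero_puts_all_in_aging(self):
        ds = make_dataset(ages_years=(1, 2, 3, 4), n_genes=3)
        with pytest.warns(UserWarning):
            dev, aging = split_periods(ds, cutoff_years=0)
        assert dev.n_samples == 0 and aging.n_samples == ds.n_samples


class TestIntersectCommonGenes:
    def test_restricts_to_intersection(self):
        a = make_dataset(n_genes=6, seed=1)
        b = make_dataset("study2_r1", study="study2", n_genes=6, seed=2)
        b = b.subset_genes([f"G{i:03d}" for i in range(2, 6)])
        out = intersect_common_genes(StudyCollection({a.name: a, b.name: b}))
        for ds in out.datasets.values():
            assert list(ds.genes) == [f"G{i:03d}" for i in range(2, 6)]

    def test_identical_gene_lists_unchanged(self, two_region_collection):
        out = intersect_common_genes(two_region_collection)
        for name, ds in out.datasets.items():
            assert list(ds.genes) == list(two_region_collection.datasets[name].genes)

    def test_disjoint_lists_rejected(self):
        a = make_dataset(n_genes=3, seed=1)
        b = make_dataset("study2_r1", study="study2", n_genes=6, seed=2)
        b = b.subset_genes(["G003", "G004"])
        with pytest.raises(ValueError, match="no genes"):
            intersect_common_genes(StudyCollection({a.name: a, b.name: b}))


def test_inconsistent_individual_age_across_regions_rejected():
    a = make_dataset("study1_region01", region="region01")
    b = make_dataset("study1_region02", region="region02")
    meta = b.meta.copy()
    meta.loc[meta.index[0], "age_days"] = 9999.0
    b = ExpressionDataset(b.name, b.expr, meta)
    with pytest.raises(ValueError, match="different datasets"):
        StudyCollection({a.name: a, b.name: b})
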