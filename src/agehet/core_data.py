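"""Data containers, TSV readers/writers, and preprocessing transforms.

The unit of analysis is an :class:`ExpressionDataset`: one study x brain-region
gene-by-sample matrix of log2-scale relative expression together with per-sample
metadata (individual, age in days, sex, region, study, batch).  Several region
datasets of one study may share individuals; :class:`StudyCollection` keeps that
structure because the downstream permutation scheme depends on it.

Preprocessing follows the order used throughout the package: quantile
normalization, optional per-batch mean-restoring standardization, per-gene
scaling to mean 0 / sd 1, and a fourth-root transform of age in days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "META_COLUMNS",
    "ExpressionDataset",
    "StudyCollection",
    "read_expression_dataset",
    "write_expression_dataset",
    "quantile_normalize",
    "batch_mean_restore",
    "scale_genes",
    "transform_age",
    "split_periods",
    "intersect_common_genes",
]

#: Required metadata columns, one row per sample.
META_COLUMNS = ("sample_id", "individual_id", "age_days", "sex", "region", "study", "batch")

DAYS_PER_YEAR = 365.0

AgeScale = Literal["fourth_root", "linear", "sqrt", "log2"]
Period = Literal["development", "aging", "full"]


@dataclass
class ExpressionDataset:
    """One study x region expression matrix plus per-sample metadata.

    Parameters
    ----------
    name
        Dataset identifier, conventionally ``"<study>_<region>"``.
    expr
        Genes x samples DataFrame of log2-scale relative expression.
    meta
        One row per sample, indexed by ``sample_id``, with columns
        ``individual_id, age_days, sex, region, study, batch``.
    period
        ``"development"``, ``"aging"`` or ``"full"``.
    """

    name: str
    expr: pd.DataFrame
    meta: pd.DataFrame
    period: Period = "full"

    def __post_init__(self) -> None:
        if list(self.expr.columns) != list(self.meta.index):
            raise ValueError(
                f"dataset {self.name!r}: expression columns and metadata rows "
                "must list the same samples in the same order"
            )
        if self.expr.index.has_duplicates:
            dups = self.expr.index[self.expr.index.duplicated()].unique().tolist()
            raise ValueError(f"dataset {self.name!r}: duplicate gene ids {dups}")
        ages = self.meta["age_days"].to_numpy(float)
        if np.any(ages < 0) or np.any(~np.isfinite(ages)):
            raise ValueError(f"dataset {self.name!r}: age_days must be finite and >= 0")
        # All samples of one individual must agree on age and sex.
        per_ind = self.meta.groupby("individual_id")[["age_days", "sex"]].nunique()
        bad = per_ind[(per_ind > 1).any(axis=1)].index.tolist()
        if bad:
            raise ValueError(
                f"dataset {self.name!r}: individuals with inconsistent age/sex: {bad}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def study(self) -> str:
        return str(self.meta["study"].iloc[0])

    def ages_years(self) -> np.ndarray:
        return self.meta["age_days"].to_numpy(float) / DAYS_PER_YEAR

    def ages_transformed(self, scale: AgeScale = "fourth_root") -> np.ndarray:
        return transform_age(self.meta["age_days"].to_numpy(float), scale)

    def with_values(self, values: np.ndarray | pd.DataFrame) -> "ExpressionDataset":
        """Return a copy with the expression values replaced (same genes/samples)."""
        expr = pd.DataFrame(np.asarray(values, float), index=self.genes, columns=self.samples)
        return replace(self, expr=expr)

    def subset_samples(self, sample_ids: Iterable[str], period: Period | None = None) -> "ExpressionDataset":
        ids = [s for s in self.samples if s in set(sample_ids)]
        return ExpressionDataset(
            name=self.name,
            expr=self.expr.loc[:, ids],
            meta=self.meta.loc[ids],
            period=period if period is not None else self.period,
        )

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionDataset":
        return replace(self, expr=self.expr.loc[list(gene_ids)])


@dataclass
class StudyCollection:
    """A named set of datasets plus the dataset -> study map.

    Region datasets of one study draw samples from the same individuals; an
    individual id appearing in several datasets of one study must carry the
    same age everywhere.  That dependence is what the individual-level
    permutation scheme preserves.
    """

    datasets: dict[str, ExpressionDataset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for study in self.studies:
            seen: dict[str, float] = {}
            for ds in self.datasets_of_study(study):
                for ind, age in ds.meta.groupby("individual_id")["age_days"].first().items():
                    if ind in seen and not np.isclose(seen[ind], age):
                        raise ValueError(
                            f"individual {ind!r} has age {seen[ind]} and {age} in "
                            f"different datasets of study {study!r}"
                        )
                    seen.setdefault(str(ind), float(age))

    @property
    def names(self) -> list[str]:
        return list(self.datasets)

    @property
    def source_of(self) -> dict[str, str]:
        return {name: ds.study for name, ds in self.datasets.items()}

    @property
    def studies(self) -> list[str]:
        out: list[str] = []
        for ds in self.datasets.values():
            if ds.study not in out:
                out.append(ds.study)
        return out

    def datasets_of_study(self, study: str) -> list[ExpressionDataset]:
        return [ds for ds in self.datasets.values() if ds.study == study]

    def individual_ages(self, study: str) -> pd.Series:
        """Observed age (days) per individual of one study, union over its datasets."""
        frames = [ds.meta[["individual_id", "age_days"]] for ds in self.datasets_of_study(study)]
        if not frames:
            raise KeyError(f"no datasets for study {study!r}")
        merged = pd.concat(frames).groupby("individual_id")["age_days"].first()
        return merged

    def map(self, fn) -> "StudyCollection":
        return StudyCollection({name: fn(ds) for name, ds in self.datasets.items()})


# ---------------------------------------------------------------------------
# I/O


def read_expression_dataset(
    expr_path: str | Path,
    meta_path: str | Path,
    name: str | None = None,
    exclude_samples: str | Path | Iterable[str] | None = None,
    log2: bool = False,
    min_median_expression: float | None = None,
) -> ExpressionDataset:
    """Read one dataset from an expression TSV and a metadata TSV.

    The expression TSV has a first column ``gene_id`` and one column per
    sample; the metadata TSV has one row per sample with the columns in
    :data:`META_COLUMNS`.  Samples are kept in matrix order and joined to
    metadata by ``sample_id``.

    Parameters
    ----------
    exclude_samples
        Optional outlier list: a path to a file with one sample id per line,
        or an iterable of sample ids.  Applied before any other filter.
    log2
        Apply ``log2(x + 1)`` to the matrix (for inputs on a linear scale).
    min_median_expression
        Drop genes whose median expression (after the optional log transform)
        is at or below this value.
    """
    expr_path, meta_path = Path(expr_path), Path(meta_path)
    expr = pd.read_csv(expr_path, sep="\t", dtype={0: str})
    if expr.columns[0] != "gene_id":
        raise ValueError(f"{expr_path}: first column must be 'gene_id', got {expr.columns[0]!r}")
    expr = expr.set_index("gene_id")
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"{expr_path}: duplicate gene ids {dups}")
    try:
        expr = expr.astype(float)
    except (TypeError, ValueError):
        for j, col in enumerate(expr.columns):
            coerced = pd.to_numeric(expr[col], errors="coerce")
            if coerced.isna().sum() > expr[col].isna().sum():
                i = int(np.where(coerced.isna() & expr[col].notna())[0][0])
                raise ValueError(
                    f"{expr_path}: non-numeric value {expr[col].iloc[i]!r} at "
                    f"gene {expr.index[i]!r}, sample {col!r}"
                ) from None
        raise
    if expr.isna().any().any():
        raise ValueError(f"{expr_path}: missing values in expression matrix")

    meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"{meta_path}: missing metadata columns {missing_cols}")
    meta = meta.set_index("sample_id")
    absent = [s for s in expr.columns if s not in meta.index]
    if absent:
        raise ValueError(f"sample(s) {absent} present in {expr_path} but not in {meta_path}")
    meta = meta.loc[list(expr.columns)]
    meta["age_days"] = meta["age_days"].astype(float)

    if exclude_samples is not None:
        if isinstance(exclude_samples, (str, Path)):
            excluded = {
                line.strip()
                for line in Path(exclude_samples).read_text().splitlines()
                if line.strip()
            }
        else:
            excluded = set(exclude_samples)
        keep = [s for s in expr.columns if s not in excluded]
        expr, meta = expr[keep], meta.loc[keep]

    if log2:
        expr = np.log2(expr + 1.0)
    if min_median_expression is not None:
        expr = expr[expr.median(axis=1) > min_median_expression]

    if name is None:
        name = f"{meta['study'].iloc[0]}_{meta['region'].iloc[0]}" if len(meta) else expr_path.stem
    return ExpressionDataset(name=name, expr=expr, meta=meta)


def write_expression_dataset(ds: ExpressionDataset, expr_path: str | Path, meta_path: str | Path) -> None:
    """Write a dataset to the TSV dialect :func:`read_expression_dataset` reads."""
    ds.expr.rename_axis("gene_id").to_csv(expr_path, sep="\t", float_format="%.10g")
    ds.meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# Transforms


def _as_2d_float(matrix) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(float), matrix
    X = np.asarray(matrix, float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D genes x samples matrix")
    return X, None


def _like(values: np.ndarray, template: pd.DataFrame | None):
    if template is None:
        return values
    return pd.DataFrame(values, index=template.index, columns=template.columns)


def quantile_normalize(matrix):
    """Quantile-normalize columns so every sample has the same value distribution.

    The reference distribution is the row-wise mean of the column-sorted
    matrix.  Ties within a column all receive the mean of the reference values
    over their tied rank span, so equal inputs map to equal outputs.
    """
    X, template = _as_2d_float(matrix)
    if X.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        assigned = np.empty_like(ref)
        assigned[order[:, j]] = ref
        # average the reference over tie blocks
        _, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        sums = np.bincount(inv, weights=assigned)
        out[:, j] = (sums / counts)[inv]
    return _like(out, template)


def batch_mean_restore(matrix, batch_labels):
    """Standardize each batch per gene, then restore the gene's grand mean.

    For each gene: compute the grand mean M over all samples, scale each
    batch's values to mean 0 / sd 1 (sample sd, n-1), and add M back.  After
    the transform every batch has mean M for that gene, which removes additive
    and multiplicative batch effects while keeping genes comparable.
    """
    X, template = _as_2d_float(matrix)
    labels = np.asarray(batch_labels)
    if labels.shape[0] != X.shape[1]:
        raise ValueError("batch_labels must have one entry per sample")
    grand_mean = X.mean(axis=1, keepdims=True)
    out = np.empty_like(X)
    gene_names = template.index if template is not None else pd.RangeIndex(X.shape[0])
    for batch in np.unique(labels):
        mask = labels == batch
        if mask.sum() < 2:
            raise ValueError(f"batch {batch!r} has fewer than 2 samples; sd undefined")
        sub = X[:, mask]
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        zero = np.where(sd[:, 0] == 0)[0]
        if zero.size:
            raise ValueError(
                f"zero within-batch variance for gene(s) {list(gene_names[zero])} in batch {batch!r}"
            )
        out[:, mask] = (sub - sub.mean(axis=1, keepdims=True)) / sd + grand_mean
    return _like(out, template)


def scale_genes(matrix):
    """Scale each gene row to mean 0 and sd 1 (sample sd, n-1)."""
    X, template = _as_2d_float(matrix)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    constant = np.where(sd[:, 0] == 0)[0]
    if constant.size:
        gene_names = template.index if template is not None else pd.RangeIndex(X.shape[0])
        raise ValueError(f"constant gene(s) cannot be scaled: {list(gene_names[constant])}")
    out = (X - X.mean(axis=1, keepdims=True)) / sd
    return _like(out, template)


def transform_age(age_days, scale: AgeScale = "fourth_root"):
    """Transform age in days onto the modelling scale.

    The default fourth-root transform spreads samples roughly uniformly over
    the lifespan, making a linear age trend a reasonable model within each
    period.  ``log2`` uses log2(age + 1) so age 0 is defined.  All scales are
    strictly monotone on age > 0.
    """
    age = np.asarray(age_days, float)
    if np.any(age < 0):
        raise ValueError("age_days must be >= 0")
    if scale == "fourth_root":
        out = age ** 0.25
    elif scale == "linear":
        out = age.copy()
    elif scale == "sqrt":
        out = np.sqrt(age)
    elif scale == "log2":
        out = np.log2(age + 1.0)
    else:
        raise ValueError(f"unknown age scale {scale!r}")
    return float(out) if np.isscalar(age_days) else out


def split_periods(
    ds: ExpressionDataset, cutoff_years: float = 20.0
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Split a dataset into development (age < cutoff) and aging (age >= cutoff).

    The boundary age goes to aging so the two periods partition the samples.
    An empty period triggers a warning and is returned as an empty dataset.
    """
    years = ds.ages_years()
    dev_ids = ds.samples[years < cutoff_years]
    old_ids = ds.samples[years >= cutoff_years]
    for label, ids in (("development", dev_ids), ("aging", old_ids)):
        if len(ids) == 0:
            warnings.warn(f"dataset {ds.name!r}: no samples in the {label} period", stacklevel=2)
    dev = ds.subset_samples(dev_ids, period="development")
    aging = ds.subset_samples(old_ids, period="aging")
    return dev, aging


def intersect_common_genes(collection: StudyCollection) -> StudyCollection:
    """Restrict every dataset to the genes measured in all datasets.

    Gene order is canonical: the order of the first dataset, restricted to the
    intersection.
    """
    if not collection.datasets:
        raise ValueError("empty collection")
    names = collection.names
    common = set(collection.datasets[names[0]].genes)
    for name in names[1:]:
        common &= set(collection.datasets[name].genes)
    if not common:
        raise ValueError("no genes shared by all datasets")
    canonical = [g for g in collection.datasets[names[0]].genes if g in common]
    return collection.map(lambda ds: ds.subset_genes(canonical))
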