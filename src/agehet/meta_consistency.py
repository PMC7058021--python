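"""Cross-dataset consistency meta-analysis with dependence-aware permutations.

Region datasets of one study profile the same individuals, so their per-gene
statistics are not independent.  Every null distribution here is therefore
built by permuting ages *among individuals* (not samples), once per study per
permutation, and propagating each individual's permuted age to all of their
samples in every dataset of that study.  This "dependent" null is more
stringent than shuffling samples independently per dataset.

Two permutation statistics follow the asymmetry of the two observed
statistics:

* heterogeneity change: residuals are kept from the fit against *observed*
  ages, and rho* is the Spearman correlation of |residuals| with the permuted
  ages — the age-expression relationship is deliberately preserved;
* expression change: beta* is refit against the permuted ages.

All permutation tests are one-sided; empirical p-values use the
(1 + exceedances) / (n_perm + 1) convention and are never exactly 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .change_models import adjust_fdr, rank_rows
from .core_data import StudyCollection

__all__ = [
    "PermutationSet",
    "permute_individual_ages",
    "permuted_heterogeneity",
    "permuted_expression_change",
    "consistency_counts",
    "count_distribution",
    "consistency_null_test",
    "ConsistencyResult",
    "consistency_analysis",
    "independent_triple_correlation_test",
    "period_difference_test",
    "pca_dispersion_summary",
]


def empirical_p(observed: float, null: np.ndarray) -> float:
    """One-sided empirical p with the +1 convention (never exactly 0)."""
    null = np.asarray(null, float)
    return float(1 + np.sum(null >= observed - 1e-12)) / (null.size + 1)


@dataclass
class PermutationSet:
    """Seeded individual-level age permutations, shared across a collection.

    ``perm_ages[study]`` is an (n_perm, n_individuals) array whose row k holds
    the k-th permuted age of each individual (column order given by
    ``individuals[study]``).  Every row is a permutation of the observed ages,
    so the per-study age multiset is preserved exactly.
    """

    n_perm: int
    seed: int
    individuals: dict[str, list[str]]
    observed_ages: dict[str, np.ndarray]
    perm_ages: dict[str, np.ndarray]

    def ages_for_dataset(self, ds) -> np.ndarray:
        """(n_perm, n_samples) permuted ages aligned to the dataset's samples."""
        study = ds.study
        idx = pd.Index(self.individuals[study])
        pos = idx.get_indexer(ds.meta["individual_id"])
        if np.any(pos < 0):
            raise KeyError(f"dataset {ds.name!r} has individuals unknown to the permutation set")
        return self.perm_ages[study][:, pos]


def permute_individual_ages(
    collection: StudyCollection, n_perm: int = 1000, seed: int = 0
) -> PermutationSet:
    """Draw ``n_perm`` age permutations over individuals, per study.

    Within a study the multiset of permuted ages equals the observed multiset
    of individual ages, and all samples of one individual receive the same
    permuted age in every dataset of the study.  Deterministic given seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    individuals: dict[str, list[str]] = {}
    observed: dict[str, np.ndarray] = {}
    perms: dict[str, np.ndarray] = {}
    for study in collection.studies:
        ages = collection.individual_ages(study)
        if len(ages) < 2:
            raise ValueError(f"study {study!r} has fewer than 2 individuals; nothing to permute")
        individuals[study] = list(ages.index)
        obs = ages.to_numpy(float)
        observed[study] = obs
        out = np.empty((n_perm, obs.size))
        for k in range(n_perm):
            out[k] = obs[rng.permutation(obs.size)]
        perms[study] = out
    return PermutationSet(
        n_perm=n_perm, seed=seed, individuals=individuals,
        observed_ages=observed, perm_ages=perms,
    )


def _normalized_ranks(M: np.ndarray) -> np.ndarray:
    """Mid-rank rows and scale to zero mean, unit sum of squares."""
    R = rank_rows(M)
    R = R - R.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", R, R))
    norms[norms == 0] = np.inf  # constant rows correlate as 0
    return R / norms[:, None]


def permuted_heterogeneity(
    collection: StudyCollection,
    residuals: Mapping[str, pd.DataFrame],
    perm_set: PermutationSet,
) -> dict[str, np.ndarray]:
    """rho* per dataset: Spearman(|observed-age residuals|, permuted ages).

    Residuals are **not** refit; only the age vector is permuted.  Returns a
    genes x n_perm array per dataset (genes ordered as in ``residuals``).
    """
    out: dict[str, np.ndarray] = {}
    gene_index = None
    for name, ds in collection.datasets.items():
        resid = residuals[name]
        if gene_index is None:
            gene_index = resid.index
        elif not resid.index.equals(gene_index):
            raise ValueError(f"residual matrix of {name!r} has a mismatched gene set")
        H = _normalized_ranks(np.abs(resid.to_numpy(float)))
        A = _normalized_ranks(perm_set.ages_for_dataset(ds))
        out[name] = H @ A.T
    return out


def permuted_expression_change(
    collection: StudyCollection,
    perm_set: PermutationSet,
    age_scale: str = "fourth_root",
) -> dict[str, dict[str, np.ndarray]]:
    """beta* per dataset: the slope refit against each permuted age vector.

    Because each permuted age vector is a rearrangement of the observed ages,
    its mean and sum of squares are unchanged, so the refit is a single matrix
    product.  Returns per dataset ``{"beta": genes x n_perm, "p": genes x
    n_perm}`` with p from the two-sided slope t-test.
    """
    from .core_data import transform_age

    out: dict[str, dict[str, np.ndarray]] = {}
    for name, ds in collection.datasets.items():
        Y = ds.expr.to_numpy(float)
        n = Y.shape[1]
        perm_t = transform_age(perm_set.ages_for_dataset(ds), age_scale)
        Xc = perm_t - perm_t.mean(axis=1, keepdims=True)
        sxx = np.einsum("ij,ij->i", Xc, Xc)  # constant across perms up to ties
        Yc = Y - Y.mean(axis=1, keepdims=True)
        beta = (Yc @ Xc.T) / sxx[None, :]
        syy = np.einsum("ij,ij->i", Yc, Yc)
        sse = syy[:, None] - beta**2 * sxx[None, :]
        sse = np.maximum(sse, 0.0)
        dfree = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sse / dfree / sxx[None, :])
            t = np.where(se > 0, beta / se, 0.0)
        p = 2 * stats.t.sf(np.abs(t), dfree)
        out[name] = {"beta": beta, "p": p}
    return out


def consistency_counts(stat_matrix: pd.DataFrame) -> pd.Series:
    """Per-gene count of datasets with a positive statistic (0 is not-up)."""
    if stat_matrix.isna().any().any():
        raise ValueError("stat matrix contains missing values")
    return (stat_matrix > 0).sum(axis=1).rename("n_up")


def count_distribution(n_up: np.ndarray | pd.Series, n_datasets: int) -> np.ndarray:
    """Number of genes at each consistency level N = 0..K."""
    return np.bincount(np.asarray(n_up, int), minlength=n_datasets + 1)


def consistency_null_test(
    observed_counts: np.ndarray, perm_counts: np.ndarray
) -> np.ndarray:
    """One-sided empirical p per consistency level N = 0..K.

    ``perm_counts`` is (n_perm, K+1); p[N] asks whether the observed number of
    genes at level N exceeds what the dependent permutation null produces.
    """
    perm_counts = np.atleast_2d(np.asarray(perm_counts))
    if perm_counts.shape[0] < 100:
        raise ValueError("need at least 100 permutations for the consistency null")
    obs = np.asarray(observed_counts)
    n_perm = perm_counts.shape[0]
    exceed = (perm_counts >= obs[None, :] - 1e-12).sum(axis=0)
    return (1 + exceed) / (n_perm + 1)


@dataclass
class ConsistencyResult:
    """Observed consistency counts with their dependent-permutation null."""

    n_up: pd.Series                    # per-gene count of datasets with stat > 0
    observed_counts: np.ndarray        # genes per level N = 0..K
    perm_counts: np.ndarray            # (n_perm, K+1)
    p_per_level: np.ndarray            # one-sided empirical p, index N = 0..K
    n_datasets: int

    def consistent_genes(self, level: int | None = None) -> list[str]:
        """Genes whose statistic is positive in at least ``level`` datasets
        (default: all of them)."""
        level = self.n_datasets if level is None else level
        return list(self.n_up.index[self.n_up >= level])

    def expected_at(self, level: int) -> float:
        """Mean number of genes at exactly this level under the null."""
        return float(self.perm_counts[:, level].mean())


def consistency_analysis(
    stat_matrix: pd.DataFrame, perm_stats: Mapping[str, np.ndarray]
) -> ConsistencyResult:
    """Count per-gene cross-dataset consistency and test it against the null.

    ``stat_matrix`` is genes x datasets (rho, or beta); ``perm_stats`` maps
    each dataset to its genes x n_perm permuted statistics.  For each
    permutation the same counting is applied, giving the null distribution of
    the number of genes at every consistency level.
    """
    names = list(stat_matrix.columns)
    missing = [n for n in names if n not in perm_stats]
    if missing:
        raise ValueError(f"permuted statistics missing for datasets {missing}")
    K = len(names)
    n_up = consistency_counts(stat_matrix)
    observed = count_distribution(n_up, K)

    stack = np.stack([np.asarray(perm_stats[n]) > 0 for n in names], axis=0)  # K x genes x n_perm
    perm_n_up = stack.sum(axis=0)  # genes x n_perm
    n_perm = perm_n_up.shape[1]
    perm_counts = np.zeros((n_perm, K + 1), dtype=int)
    for k in range(n_perm):
        perm_counts[k] = np.bincount(perm_n_up[:, k], minlength=K + 1)
    p = consistency_null_test(observed, perm_counts)
    return ConsistencyResult(
        n_up=n_up, observed_counts=observed, perm_counts=perm_counts,
        p_per_level=p, n_datasets=K,
    )


# ---------------------------------------------------------------------------
# Cross-dataset correlation tests


def _pairwise_spearman(stat_matrix: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation across genes for every pair of datasets."""
    return stat_matrix.corr(method="spearman")


def _perm_pair_correlations(
    perm_stats: Mapping[str, np.ndarray], pairs: Sequence[tuple[str, str]]
) -> dict[tuple[str, str], np.ndarray]:
    """Per-permutation Spearman correlation (across genes) for given pairs."""
    ranked = {
        name: _normalized_ranks(np.asarray(perm_stats[name]).T)  # n_perm x genes, ranked per perm
        for name in {n for pair in pairs for n in pair}
    }
    return {
        (a, b): np.einsum("ij,ij->i", ranked[a], ranked[b])
        for a, b in pairs
    }


def independent_triple_correlation_test(
    stat_matrix: pd.DataFrame,
    study_of: Mapping[str, str],
    perm_stats: Mapping[str, np.ndarray],
) -> tuple[float, float, np.ndarray]:
    """Median cross-dataset correlation over independent triples, with its null.

    A triple takes one dataset from each study, so its three pairwise
    correlations involve no shared individuals.  The observed statistic is the
    median over all triples of the median of the three pairwise Spearman
    correlations (across genes).  The null recomputes the same statistic from
    the permuted statistics; the test is one-sided (observed high).

    Returns (observed, empirical p, null distribution).
    """
    by_study: dict[str, list[str]] = {}
    for name in stat_matrix.columns:
        by_study.setdefault(study_of[name], []).append(name)
    if len(by_study) < 2:
        raise ValueError("need datasets from at least 2 studies to form independent tuples")
    for study, members in by_study.items():
        if not members:
            raise ValueError(f"study {study!r} contributes no dataset")

    triples = list(itertools.product(*by_study.values()))
    pairs = sorted({tuple(sorted(p)) for tri in triples for p in itertools.combinations(tri, 2)})

    obs_corr = _pairwise_spearman(stat_matrix)
    observed = float(np.median([
        np.median([obs_corr.loc[a, b] for a, b in itertools.combinations(tri, 2)])
        for tri in triples
    ]))

    perm_pairs = _perm_pair_correlations(perm_stats, pairs)
    tri_pair_idx = [
        [tuple(sorted(p)) for p in itertools.combinations(tri, 2)] for tri in triples
    ]
    pair_mat = np.stack([perm_pairs[p] for p in pairs], axis=0)  # pairs x n_perm
    pair_pos = {p: i for i, p in enumerate(pairs)}
    tri_medians = np.stack([
        np.median(pair_mat[[pair_pos[p] for p in tri_pairs], :], axis=0)
        for tri_pairs in tri_pair_idx
    ], axis=0)  # triples x n_perm
    null = np.median(tri_medians, axis=0)
    return observed, empirical_p(observed, null), null


# ---------------------------------------------------------------------------
# Period comparison


_PERIOD_STATISTICS = ("median_correlation_diff", "n_significant_diff", "median_rho_diff")


def period_difference_test(
    dev_stat: pd.DataFrame,
    aging_stat: pd.DataFrame,
    dev_perm: Mapping[str, np.ndarray],
    aging_perm: Mapping[str, np.ndarray],
    statistic: str = "median_rho_diff",
    alpha: float = 0.05,
    dev_n: Mapping[str, int] | None = None,
    aging_n: Mapping[str, int] | None = None,
) -> tuple[float, float, np.ndarray]:
    """One-sided test that a summary is larger in aging than in development.

    Statistics (observed difference, aging minus development):

    * ``median_rho_diff`` — median over datasets of (median aging statistic -
      median development statistic) per dataset; the headline heterogeneity
      comparison.
    * ``median_correlation_diff`` — median pairwise Spearman correlation
      (across genes) among aging datasets minus among development datasets.
    * ``n_significant_diff`` — total number of (gene, dataset) entries with
      BH q < alpha in aging minus development; requires ``dev_n``/``aging_n``
      sample sizes and interprets the statistic as a correlation (rho).

    The null recomputes the chosen statistic from the permuted statistics;
    p = (1 + exceedances) / (n_perm + 1).
    Returns (observed, p, null distribution).
    """
    if statistic not in _PERIOD_STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {_PERIOD_STATISTICS}")
    names_dev, names_aging = list(dev_stat.columns), list(aging_stat.columns)
    n_perm = next(iter(dev_perm.values())).shape[1] if dev_perm else 0
    if n_perm == 0:
        raise ValueError("permutation set is empty")

    if statistic == "median_rho_diff":
        if len(names_dev) != len(names_aging):
            raise ValueError("median_rho_diff needs matched development/aging dataset pairs")
        obs = float(np.median(
            aging_stat.median(axis=0).to_numpy() - dev_stat.median(axis=0).to_numpy()
        ))
        aging_med = np.stack([np.median(aging_perm[n], axis=0) for n in names_aging])
        dev_med = np.stack([np.median(dev_perm[n], axis=0) for n in names_dev])
        null = np.median(aging_med - dev_med, axis=0)

    elif statistic == "median_correlation_diff":
        def median_pair_corr(M: pd.DataFrame) -> float:
            C = _pairwise_spearman(M).to_numpy()
            iu = np.triu_indices_from(C, k=1)
            return float(np.median(C[iu]))

        obs = median_pair_corr(aging_stat) - median_pair_corr(dev_stat)

        def perm_median_pair_corr(perm: Mapping[str, np.ndarray], names: list[str]) -> np.ndarray:
            pairs = [tuple(sorted(p)) for p in itertools.combinations(names, 2)]
            pc = _perm_pair_correlations(perm, pairs)
            return np.median(np.stack(list(pc.values())), axis=0)

        null = perm_median_pair_corr(aging_perm, names_aging) - perm_median_pair_corr(
            dev_perm, names_dev
        )

    else:  # n_significant_diff
        if dev_n is None or aging_n is None:
            raise ValueError("n_significant_diff needs per-dataset sample sizes")

        def rho_to_p(rho: np.ndarray, n: int) -> np.ndarray:
            rho = np.clip(rho, -1.0, 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = rho * np.sqrt((n - 2) / (1 - rho**2))
            t = np.nan_to_num(t, posinf=np.inf, neginf=-np.inf)
            return 2 * stats.t.sf(np.abs(t), n - 2)

        def n_sig(stat: pd.DataFrame, n_of: Mapping[str, int]) -> int:
            total = 0
            for name in stat.columns:
                p = rho_to_p(stat[name].to_numpy(float), n_of[name])
                total += int((adjust_fdr(p) < alpha).sum())
            return total

        obs = float(n_sig(aging_stat, aging_n) - n_sig(dev_stat, dev_n))

        def perm_n_sig(perm: Mapping[str, np.ndarray], names: list[str], n_of) -> np.ndarray:
            counts = np.zeros(n_perm)
            for name in names:
                P = rho_to_p(np.asarray(perm[name]), n_of[name])  # genes x n_perm
                for k in range(n_perm):
                    counts[k] += (adjust_fdr(P[:, k]) < alpha).sum()
            return counts

        null = perm_n_sig(aging_perm, names_aging, aging_n) - perm_n_sig(
            dev_perm, names_dev, dev_n
        )

    return float(obs), empirical_p(float(obs), null), null


# ---------------------------------------------------------------------------
# PCA dispersion


def pca_dispersion_summary(
    stat_matrix: pd.DataFrame, period_labels: Mapping[str, str] | pd.Series
) -> tuple[pd.DataFrame, dict[str, float]]:
    """PCA of datasets over their per-gene statistics, plus per-period spread.

    Each dataset's gene vector is scaled to mean 0 / sd 1, then the
    dataset-by-gene matrix is decomposed by SVD with no further centering.
    Returns the dataset PC coordinates and, per period, the median pairwise
    Euclidean distance between its datasets on the PC1-PC2 plane — the
    dispersion summary that contrasts how scattered aging and development
    datasets are.
    """
    if stat_matrix.shape[1] < 3:
        raise ValueError("need at least 3 datasets for a PCA dispersion summary")
    if stat_matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    X = stat_matrix.to_numpy(float).T  # datasets x genes
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("a dataset has a constant statistic vector; cannot scale")
    X = (X - X.mean(axis=1, keepdims=True)) / sd
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    coords = U * S[None, :]
    n_pc = coords.shape[1]
    pcs = pd.DataFrame(
        coords, index=stat_matrix.columns, columns=[f"PC{i + 1}" for i in range(n_pc)]
    )
    labels = pd.Series(period_labels).reindex(stat_matrix.columns)
    dispersion: dict[str, float] = {}
    for period in labels.dropna().unique():
        members = pcs.loc[labels == period, ["PC1", "PC2"]].to_numpy()
        if members.shape[0] < 2:
            dispersion[str(period)] = float("nan")
            continue
        d = [
            float(np.linalg.norm(members[i] - members[j]))
            for i, j in itertools.combinations(range(members.shape[0]), 2)
        ]
        dispersion[str(period)] = float(np.median(d))
    return pcs, dispersion
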