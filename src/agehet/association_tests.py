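"""Downstream association analyses for consistently heterogeneous genes.

Covers: correlation between a gene's number of distinct regulators (TFs or
miRNAs) and its heterogeneity change, with a cross-period permutation test;
protein-interaction degree of a target gene list against a resampling null;
cell-type-specific gene calling (one-vs-rest Cohen's D) and Fisher overlap
tests; per-sample cell-type deconvolution by linear regression on reference
profiles; and a per-gene sex check on signed residuals.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .change_models import adjust_fdr

__all__ = [
    "regulator_count_association",
    "load_network",
    "ppi_degree_test",
    "cohens_d",
    "cell_type_specific_genes",
    "gene_set_overlap_test",
    "deconvolve_cell_types",
    "sex_difference_check",
]


# ---------------------------------------------------------------------------
# Regulator counts


def regulator_counts_from_sets(regulator_sets: Mapping[str, Sequence[str]]) -> pd.Series:
    """Per-gene number of distinct regulators, from regulator -> targets sets."""
    counts: dict[str, int] = {}
    for _, targets in regulator_sets.items():
        for g in set(targets):
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, name="n_regulators", dtype=int)


def regulator_count_association(
    dev_stat: pd.DataFrame,
    aging_stat: pd.DataFrame,
    regulator_counts: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Is heterogeneity change more correlated with regulator count in aging?

    Per dataset, the Spearman correlation between the per-gene statistic
    (rho) and the number of regulators is computed; the observed test
    statistic is the fraction of (aging, development) dataset pairs in which
    the aging correlation is the larger.  The null permutes the regulator
    counts across genes — one shared permutation per iteration, applied to
    every dataset — and the empirical p is one-sided (observed fraction
    high).

    Genes with a count are intersected with the statistic tables; a constant
    count vector makes the correlation undefined and is reported as 0 with a
    degeneracy flag.
    """
    genes = dev_stat.index.intersection(aging_stat.index).intersection(regulator_counts.index)
    if genes.empty:
        raise ValueError("regulator counts share no genes with the statistic tables")
    dev = dev_stat.loc[genes]
    aging = aging_stat.loc[genes]
    counts = regulator_counts.loc[genes].to_numpy(float)

    degenerate = np.ptp(counts) == 0

    def corrs(stat: pd.DataFrame, c: np.ndarray) -> np.ndarray:
        if np.ptp(c) == 0:
            return np.zeros(stat.shape[1])
        return np.array([
            stats.spearmanr(stat[col].to_numpy(float), c)[0] for col in stat.columns
        ])

    def fraction_aging_higher(dev_c: np.ndarray, aging_c: np.ndarray) -> float:
        pairs = [(a, d) for a in aging_c for d in dev_c]
        return float(np.mean([a > d for a, d in pairs]))

    obs_dev, obs_aging = corrs(dev, counts), corrs(aging, counts)
    observed = fraction_aging_higher(obs_dev, obs_aging)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = counts[rng.permutation(counts.size)]
        null[k] = fraction_aging_higher(corrs(dev, shuffled), corrs(aging, shuffled))
    p = float(1 + np.sum(null >= observed - 1e-12)) / (n_perm + 1)
    return {
        "correlation_development": pd.Series(obs_dev, index=dev.columns),
        "correlation_aging": pd.Series(obs_aging, index=aging.columns),
        "observed_fraction": observed,
        "p": p,
        "null": null,
        "degenerate": bool(degenerate),
    }


# ---------------------------------------------------------------------------
# Protein interaction network


def load_network(path, score_cutoff: float = 0.0) -> nx.Graph:
    """Load an undirected edge list TSV (gene_a, gene_b, combined_score).

    Self-loops are dropped; only edges with score >= cutoff are kept.
    """
    edges = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "combined_score"}
    if not required.issubset(edges.columns):
        raise ValueError(f"network TSV needs columns {sorted(required)}")
    G = nx.Graph()
    kept = edges[edges["combined_score"] >= score_cutoff]
    for a, b in zip(kept["gene_a"], kept["gene_b"]):
        if a != b:
            G.add_edge(a, b)
    return G


def ppi_degree_test(
    target_genes: Sequence[str],
    network: nx.Graph,
    n_samples: int = 10000,
    seed: int = 0,
) -> dict:
    """Are target genes better connected than random genes of the network?

    The observed statistic is the median degree of the targets present in the
    network (k genes).  The null draws k random network genes ``n_samples``
    times and records each draw's median degree; the empirical p asks how
    often a draw matches or beats the observed median.
    """
    nodes = list(network.nodes)
    if not nodes:
        raise ValueError("network is empty after score filtering")
    present = [g for g in target_genes if network.has_node(g)]
    k = len(present)
    if k == 0:
        raise ValueError("no target gene found in the network (k = 0)")
    degrees = dict(network.degree)
    observed = float(np.median([degrees[g] for g in present]))
    all_deg = np.array([degrees[g] for g in nodes], float)
    rng = np.random.default_rng(seed)
    medians = np.empty(n_samples)
    for i in range(n_samples):
        medians[i] = np.median(all_deg[rng.choice(all_deg.size, size=k, replace=False)])
    p = float(1 + np.sum(medians >= observed - 1e-12)) / (n_samples + 1)
    return {"k": k, "median_degree": observed, "p": p, "null_medians": medians}


# ---------------------------------------------------------------------------
# Cell types


def cohens_d(group: np.ndarray, rest: np.ndarray) -> float:
    """Cohen's D with pooled (n-1) sd; antisymmetric under swapping the groups."""
    group = np.asarray(group, float)
    rest = np.asarray(rest, float)
    n1, n2 = group.size, rest.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 values per group")
    v1 = group.var(ddof=1)
    v2 = rest.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if pooled == 0:
        return float("nan")
    return float((group.mean() - rest.mean()) / pooled)


def cell_type_specific_genes(
    profiles: pd.DataFrame,
    cell_type_of: Mapping[str, str],
    threshold: float = 2.0,
) -> dict[str, list[str]]:
    """Call genes specific to a cell type by one-vs-rest effect size.

    ``profiles`` is genes x replicate columns; ``cell_type_of`` maps each
    column to its cell type (>= 2 replicates each).  Per gene and cell type,
    Cohen's D contrasts that cell type's replicates against all others
    pooled; genes at D >= ``threshold`` are assigned to the type.  A gene
    with zero pooled sd is excluded for that type.  Lists may in principle
    overlap; disjointness is a property of the data, not enforced.
    """
    types = pd.Series({c: cell_type_of[c] for c in profiles.columns})
    out: dict[str, list[str]] = {}
    X = profiles.to_numpy(float)
    for ct in types.unique():
        mask = (types == ct).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"cell type {ct!r} needs >= 2 replicates on each side")
        hits = []
        for i, gene in enumerate(profiles.index):
            d = cohens_d(X[i, mask], X[i, ~mask])
            if np.isfinite(d) and d >= threshold:
                hits.append(str(gene))
        out[str(ct)] = hits
    return out


def gene_set_overlap_test(
    set_a: Sequence[str], set_b: Sequence[str], universe: Sequence[str]
) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 membership table."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a = set(set_a) & uni
    b = set(set_b) & uni
    both = len(a & b)
    only_a = len(a) - both
    only_b = len(b) - both
    neither = len(uni) - both - only_a - only_b
    odds, p = stats.fisher_exact([[both, only_a], [only_b, neither]], alternative="two-sided")
    return float(odds), float(p)


def deconvolve_cell_types(
    sample_expr: pd.Series, profiles: pd.DataFrame
) -> tuple[pd.Series, float, np.ndarray]:
    """Estimate relative cell-type contributions to one bulk sample.

    OLS of the sample's per-gene expression on the per-cell-type mean
    profiles plus an intercept:

        expr = a + sum_c beta_c * profile_c + eps

    Returns (coefficients per cell type, intercept, residuals).  Age trends
    and heterogeneity of the contributions are obtained by running the usual
    per-gene machinery on the coefficient series across samples.
    """
    genes = profiles.index
    y = sample_expr.loc[genes].to_numpy(float)
    Z = profiles.to_numpy(float)
    n, c = Z.shape
    if n < c + 1:
        raise ValueError(f"need at least {c + 1} genes for {c} cell types")
    rank = np.linalg.matrix_rank(Z)
    if rank < c:
        corr = np.corrcoef(Z.T)
        pairs = [
            (profiles.columns[i], profiles.columns[j])
            for i in range(c)
            for j in range(i + 1, c)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"cell-type profiles are collinear: {pairs or 'rank deficient'}")
    X = np.column_stack([np.ones(n), Z])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return pd.Series(coef[1:], index=profiles.columns), float(coef[0]), resid


# ---------------------------------------------------------------------------
# Sex differences


def sex_difference_check(
    residuals: pd.DataFrame, sex: pd.Series, exact_max_n: int = 20
) -> pd.DataFrame:
    """Two-sided rank-sum test of signed residuals between sexes, per gene.

    Signed (not absolute) residuals are compared, so a significant result
    means male and female expression deviate from the shared age trend in
    different directions.  The exact null is used for combined n <= 20, the
    normal approximation with continuity correction above.  Genes where one
    sex is absent or all residuals are equal are skipped with a flag; BH
    correction runs over the tested genes.
    """
    sex = sex.reindex(residuals.columns)
    male = (sex == "male").to_numpy()
    female = (sex == "female").to_numpy()
    rows = []
    for gene, series in residuals.iterrows():
        r = series.to_numpy(float)
        if male.sum() < 2 or female.sum() < 2 or np.ptp(r) == 0:
            rows.append({"gene_id": gene, "p": np.nan, "skipped": True})
            continue
        method = "exact" if (male.sum() + female.sum()) <= exact_max_n and np.unique(r).size == r.size else "asymptotic"
        _, p = stats.mannwhitneyu(
            r[male], r[female], alternative="two-sided", method=method,
            use_continuity=True,
        )
        rows.append({"gene_id": gene, "p": float(p), "skipped": False})
    table = pd.DataFrame(rows).set_index("gene_id")
    table["q"] = np.nan
    tested = ~table["skipped"]
    if tested.any():
        table.loc[tested, "q"] = adjust_fdr(table.loc[tested, "p"].to_numpy())
    return table
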