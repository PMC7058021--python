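"""Preranked gene-set enrichment on consistency ranks.

The headline ranking statistic is the per-gene count of datasets with a
consistent heterogeneity increase (``n_up``), sorted descending.  Enrichment
uses the weighted Kolmogorov-Smirnov running sum: walking down the ranking,
the sum rises by ``|score|^weight`` (normalized within the set) at each set
member and falls by a uniform decrement at each non-member; the enrichment
score (ES) is the signed extremum.  The normalized score (NES) divides ES by
the mean magnitude of same-sign scores from gene-label permutations, and the
permutation one-sided p is BH-corrected across sets.

Because ``n_up`` takes only a handful of integer values, the ranking is full
of ties and a single run may be unstable.  ``tie_robustness_gsea`` reruns the
analysis many times with random shuffles inside tie blocks and reports, per
set, the fraction of runs in which it stays significant.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .change_models import adjust_fdr

__all__ = [
    "read_gmt",
    "filter_sets",
    "enrichment_score",
    "preranked_gsea",
    "tie_robustness_gsea",
]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line as ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def filter_sets(
    sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    min_size: int = 5,
    max_size: int = 500,
) -> dict[str, list[str]]:
    """Restrict sets to genes in the universe and keep sizes within bounds."""
    uni = set(universe)
    out = {}
    for name, members in sets.items():
        present = sorted(set(members) & uni)
        if min_size <= len(present) <= max_size:
            out[name] = present
    return out


def _es_from_positions(
    positions: np.ndarray, abs_scores_ranked: np.ndarray, n: int, weight: float
) -> np.ndarray:
    """Enrichment scores for one or many sets given member positions.

    ``positions`` is (B, m) with 0-based positions in the descending ranking
    (rows need not be sorted).  Vectorized closed form of the running-sum
    extremum: at the i-th hit (position p_i), the running sum right after the
    hit is ``cum_w_i - miss * (p_i - i)`` and right before it is that minus
    ``w_i``; the extrema over hits bound the whole path, which starts and ends
    at exactly 0.
    """
    P = np.sort(np.atleast_2d(positions), axis=1)
    B, m = P.shape
    if m >= n:
        raise ValueError("set size must be smaller than the number of ranked genes")
    w = abs_scores_ranked[P] ** weight if weight != 0 else np.ones_like(P, dtype=float)
    totals = w.sum(axis=1, keepdims=True)
    # an all-zero-score set falls back to uniform hit increments
    w = np.where(totals > 0, w / np.where(totals == 0, 1.0, totals), 1.0 / m)
    miss = 1.0 / (n - m)
    idx = np.arange(m)[None, :]
    after = np.cumsum(w, axis=1) - miss * (P - idx)
    before = after - w
    es_pos = after.max(axis=1)
    es_neg = np.minimum(before.min(axis=1), 0.0)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def enrichment_score(
    scores: pd.Series, members: Sequence[str], weight: float = 1.0
) -> float:
    """ES of one gene set against a descending ranking of ``scores``."""
    ranked = scores.sort_values(ascending=False, kind="stable")
    pos_index = pd.Index(ranked.index)
    pos = pos_index.get_indexer([g for g in members if g in pos_index])
    if pos.size == 0:
        raise ValueError("no set member present in the ranking")
    return float(
        _es_from_positions(pos[None, :], np.abs(ranked.to_numpy(float)), len(ranked), weight)[0]
    )


def preranked_gsea(
    scores: pd.Series,
    sets: Mapping[str, Sequence[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA over a collection of gene sets.

    Sets are filtered to members present in ``scores`` and to sizes within
    ``[min_size, max_size]``; sets failing the filter are skipped.  The null
    is gene-label permutation: for each permutation, a random set of the same
    size is scored.  NES = ES / mean(|ES*|) over same-sign permutation
    scores; p is one-sided within the same sign with the +1 floor; q is BH
    across the reported sets.

    Returns a DataFrame indexed by set name with columns
    ``size, es, nes, p, q``.
    """
    ranked = scores.sort_values(ascending=False, kind="stable")
    n = len(ranked)
    kept = filter_sets(sets, ranked.index, min_size=min_size, max_size=max_size)
    if not kept:
        return pd.DataFrame(columns=["size", "es", "nes", "p", "q"])
    abs_ranked = np.abs(ranked.to_numpy(float))
    pos_index = pd.Index(ranked.index)

    rng = np.random.default_rng(seed)
    perm_orders = np.stack([rng.permutation(n) for _ in range(n_perm)])

    rows = {}
    for name, members in kept.items():
        pos = pos_index.get_indexer(members)
        m = pos.size
        es = float(_es_from_positions(pos[None, :], abs_ranked, n, weight)[0])
        es_null = _es_from_positions(perm_orders[:, :m], abs_ranked, n, weight)
        same_sign = es_null >= 0 if es >= 0 else es_null < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            nes, p = float("nan"), 1.0
        else:
            nes = es / float(np.mean(np.abs(es_null[same_sign])))
            if es >= 0:
                exceed = int((es_null[same_sign] >= es - 1e-12).sum())
            else:
                exceed = int((es_null[same_sign] <= es + 1e-12).sum())
            p = (1 + exceed) / (1 + n_same)
        rows[name] = {"size": m, "es": es, "nes": nes, "p": p}
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("set")
    table["q"] = adjust_fdr(table["p"].to_numpy())
    return table


def tie_robustness_gsea(
    scores: pd.Series,
    sets: Mapping[str, Sequence[str]],
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    weight: float = 1.0,
    n_perm: int = 200,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.Series:
    """Fraction of tie-shuffled reruns in which each set stays significant.

    Each repetition permutes the order of genes inside every tie block of the
    score vector (the stable sort then fixes a random order among equals) and
    reruns :func:`preranked_gsea`.  The GSEA permutation seed is held fixed
    across repetitions so that tie-breaking is the only source of
    variability; with a tie-free score the shuffle is a no-op and every
    frequency is exactly 0 or 1.  A set counts as significant at BH q <
    ``alpha``.
    """
    rng = np.random.default_rng(seed)
    gsea_seed = int(rng.integers(0, 2**31 - 1))
    counts: dict[str, int] = {}
    for _ in range(n_reps):
        order = np.arange(len(scores))
        rng.shuffle(order)
        shuffled = scores.iloc[order]
        table = preranked_gsea(
            shuffled, sets, weight=weight, n_perm=n_perm, seed=gsea_seed,
            min_size=min_size, max_size=max_size,
        )
        for name in table.index:
            counts.setdefault(name, 0)
        for name in table.index[table["q"] < alpha]:
            counts[name] += 1
    return pd.Series({k: v / n_reps for k, v in counts.items()}, name="robustness_frequency")
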