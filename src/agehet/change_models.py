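"""Per-gene, per-dataset age-trend statistics.

Two statistics drive everything downstream:

* **expression change** ``beta1`` — the OLS slope of scaled log2 expression on
  transformed (fourth-root) age, ``Y = beta0 + beta1 * age_t + eps``;
* **heterogeneity change** ``rho`` — the Spearman correlation between the
  absolute residuals of that fit and age.  Positive rho means inter-individual
  spread grows with age.

Heterogeneity is computed for every gene, whether or not its mean expression
changes significantly with age.  Two sensitivity alternatives are provided:
a Breusch-Pagan score test for heteroskedasticity and a loess-residual variant
of rho.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .core_data import ExpressionDataset

__all__ = [
    "GeneFit",
    "fit_expression_change",
    "heterogeneity_change",
    "adjust_fdr",
    "breusch_pagan_check",
    "loess_heterogeneity",
    "fit_dataset",
]


@dataclass
class GeneFit:
    """Age-trend fit for one gene in one dataset."""

    beta0: float
    beta1: float
    residuals: np.ndarray
    p_beta: float
    rho: float
    p_rho: float
    degenerate: bool = False


def _check_lengths(y: np.ndarray, x: np.ndarray, min_n: int = 4) -> None:
    if y.shape != x.shape:
        raise ValueError("expression and age vectors must have equal length")
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {y.size}")


def fit_expression_change(expr, age_t) -> GeneFit:
    """OLS fit of expression on transformed age; slope p from the two-sided t-test.

    A constant expression vector is degenerate, not an error: it returns
    beta1 = 0, p = 1 and a degeneracy flag so a large synthetic run is not
    aborted by a flat gene.  A constant age vector is an error.
    """
    y = np.asarray(expr, float)
    x = np.asarray(age_t, float)
    _check_lengths(y, x)
    if np.ptp(x) == 0:
        raise ValueError("age is constant; slope undefined")
    if np.ptp(y) == 0:
        rho, p_rho, degen = _spearman_abs_resid(np.zeros_like(y), x)
        return GeneFit(
            beta0=float(y[0]), beta1=0.0, residuals=np.zeros_like(y),
            p_beta=1.0, rho=rho, p_rho=p_rho, degenerate=True,
        )
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    residuals = y - fitted
    rho, p_rho, degen = _spearman_abs_resid(residuals, x)
    return GeneFit(
        beta0=float(res.intercept), beta1=float(res.slope), residuals=residuals,
        p_beta=float(res.pvalue), rho=rho, p_rho=p_rho, degenerate=degen,
    )


def _exact_spearman_p(a_rank: np.ndarray, b_rank: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    n = a_rank.size
    a = a_rank - a_rank.mean()
    b = b_rank - b_rank.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    count = total = 0
    for perm in itertools.permutations(range(n)):
        r = float(a[list(perm)] @ b) / denom
        total += 1
        if abs(r) >= abs(observed) - 1e-12:
            count += 1
    return count / total


def _spearman_abs_resid(residuals: np.ndarray, age: np.ndarray) -> tuple[float, float, bool]:
    h = np.abs(residuals)
    if np.ptp(h) == 0:
        return 0.0, 1.0, True
    n = h.size
    if n < 10:
        a = stats.rankdata(h)
        b = stats.rankdata(age)
        rho = float(np.corrcoef(a, b)[0, 1])
        p = _exact_spearman_p(a, b, rho)
        return rho, p, False
    rho, p = stats.spearmanr(h, age)
    return float(rho), float(p), False


def heterogeneity_change(residuals, age) -> tuple[float, float]:
    """Spearman correlation of |residuals| with age (mid-rank ties).

    Rank-based, hence invariant to any strictly monotone transform of age.
    If all |residuals| are equal, rho is undefined and returned as 0 with
    p = 1 (the degeneracy is flagged by :func:`fit_expression_change`).
    The p-value uses the t approximation for n >= 10 and an exact permutation
    null below that.
    """
    r = np.asarray(residuals, float)
    x = np.asarray(age, float)
    _check_lengths(r, x)
    rho, p, _ = _spearman_abs_resid(r, x)
    return rho, p


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (cumulative-minimum enforced)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def breusch_pagan_check(expr, age_t) -> tuple[float, float]:
    """Breusch-Pagan score test for age-dependent residual variance.

    Squared residuals from the age-linear fit are regressed on transformed
    age; the statistic is n * R^2, referred to chi-square with 1 df.  This is
    the auxiliary-regression check used to confirm the rank-based rho.
    """
    y = np.asarray(expr, float)
    x = np.asarray(age_t, float)
    _check_lengths(y, x)
    if np.ptp(x) == 0:
        raise ValueError("age is constant")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    u = resid**2
    if np.ptp(u) == 0:
        return 0.0, 1.0
    r = np.corrcoef(u, x)[0, 1]
    stat = float(u.size * r**2)
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def loess_heterogeneity(expr, age, span: float = 0.75) -> tuple[float, float]:
    """rho computed from loess residuals instead of the linear model.

    Sensitivity-only variant: the local fit absorbs non-linear mean trends but
    is more dependent on the span and the sample size than the linear model,
    so the linear-model rho remains the headline statistic.
    """
    y = np.asarray(expr, float)
    x = np.asarray(age, float)
    _check_lengths(y, x, min_n=10)
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if span * y.size < 3:
        raise ValueError(f"span {span} too small for n = {y.size}")
    fitted = lowess(y, x, frac=span, return_sorted=False)
    resid = y - fitted
    return heterogeneity_change(resid, x)


def fit_dataset(
    ds: ExpressionDataset, age_scale: str = "fourth_root"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every gene of a dataset; vectorized across genes.

    Returns ``(table, residuals)``: the per-gene statistics table with columns
    ``beta1, p_beta, q_beta, rho, p_rho, q_rho, n_samples, degenerate_flag``
    and the genes x samples residual matrix (needed later for the permutation
    null, which keeps residuals fixed while ages are shuffled).
    """
    x = ds.ages_transformed(age_scale)
    if np.ptp(x) == 0:
        raise ValueError(f"dataset {ds.name!r}: age is constant")
    n = x.size
    if n < 4:
        raise ValueError(f"dataset {ds.name!r}: need at least 4 samples, got {n}")
    Y = ds.expr.to_numpy(float)

    xc = x - x.mean()
    sxx = float(xc @ xc)
    beta1 = (Y @ xc) / sxx
    beta0 = Y.mean(axis=1) - beta1 * x.mean()
    resid = Y - (beta0[:, None] + np.outer(beta1, x))

    # two-sided t-test on the slope
    dfree = n - 2
    sse = np.einsum("ij,ij->i", resid, resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / dfree / sxx)
        t = np.where(se > 0, beta1 / se, 0.0)
    p_beta = 2 * stats.t.sf(np.abs(t), dfree)

    degen_expr = np.ptp(Y, axis=1) == 0
    beta1[degen_expr] = 0.0
    p_beta[degen_expr] = 1.0
    resid[degen_expr] = 0.0

    rho, p_rho, degen_rho = spearman_rho_matrix(np.abs(resid), x)
    degenerate = degen_expr | degen_rho

    table = pd.DataFrame(
        {
            "beta1": beta1,
            "p_beta": p_beta,
            "q_beta": adjust_fdr(p_beta),
            "rho": rho,
            "p_rho": p_rho,
            "q_rho": adjust_fdr(p_rho),
            "n_samples": n,
            "degenerate_flag": degenerate,
        },
        index=ds.genes.rename("gene_id"),
    )
    residuals = pd.DataFrame(resid, index=ds.genes, columns=ds.samples)
    return table, residuals


def rank_rows(M: np.ndarray) -> np.ndarray:
    """Mid-rank each row of a matrix (average ranks for ties)."""
    return np.apply_along_axis(stats.rankdata, 1, M)


def spearman_rho_matrix(H: np.ndarray, age: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Spearman correlation of a genes x samples matrix with one age vector.

    Returns (rho, p, degenerate) arrays; degenerate rows (constant values)
    get rho 0, p 1.  p uses the t approximation (n >= 10 in all vectorized
    call sites).
    """
    n = age.size
    R = rank_rows(H)
    a = stats.rankdata(age)
    Rc = R - R.mean(axis=1, keepdims=True)
    ac = a - a.mean()
    denom = np.sqrt(np.einsum("ij,ij->i", Rc, Rc) * float(ac @ ac))
    degenerate = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (Rc @ ac) / denom
    rho[degenerate] = 0.0
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    t[~np.isfinite(t)] = np.inf * np.sign(rho[~np.isfinite(t)])
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[degenerate] = 1.0
    return rho, p, degenerate
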