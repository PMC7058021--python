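"""Synthetic multi-study expression collections with planted heterogeneity trends.

The generator emulates the structure the meta-analysis assumes: several data
sources ("studies"), each contributing one dataset per brain region, where all
region datasets of a study sample the *same individuals*; ages span the
lifespan; each gene has an age-linear mean trend on the fourth-root age scale;
and a configurable fraction of genes has residual spread that grows (or
shrinks) with age.

Each gene's mean trend is piecewise linear in transformed age with an
independent slope per period and a continuous hinge at 20 years (mirroring
the reversal patterns between postnatal development and aging):

    E[Y](t) = beta_dev * min(t, t20) + beta_aging * max(t - t20, 0)

Residuals are Gaussian.  During development the residual sd is ``base_sd``
for every gene; during aging a configurable fraction of genes carries a
heterogeneity trend,

    sd(t) = base_sd * exp(var_slope_g * z(t)),

where ``z(t)`` standardizes the transformed ages of the aging samples.  The
multiplicative form keeps the sd positive for any slope; ``var_slope_g > 0``
plants an aging heterogeneity increase.  Gene identities, their mean-trend
slopes and their heterogeneity classes are shared across all datasets, so
cross-dataset consistency of the planted signal is meaningful; the noise is
independent per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core_data import (
    DAYS_PER_YEAR,
    ExpressionDataset,
    StudyCollection,
    transform_age,
    write_expression_dataset,
)

__all__ = ["SimulationConfig", "simulate_gene_profile", "simulate_collection", "write_collection", "read_collection"]


@dataclass
class SimulationConfig:
    """Parameters of a simulated multi-study collection.

    Defaults mirror the design of the brain meta-analysis at a reduced scale:
    three studies contributing 16, 2 and 1 region datasets (19 datasets in
    total), individuals aged 0-98 years, and a small fraction of genes with a
    planted heterogeneity increase during aging.
    """

    n_studies: int = 3
    regions_per_study: Sequence[int] = (16, 2, 1)
    n_individuals: Sequence[int] = (40, 40, 40)
    age_range_years: tuple[float, float] = (0.0, 98.0)
    n_genes: int = 500
    frac_het_increase: float = 0.05
    frac_het_decrease: float = 0.0
    beta_distribution: tuple[float, float] = (0.0, 0.5)
    base_sd: float = 0.5
    var_slope_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        self.regions_per_study = tuple(int(r) for r in self.regions_per_study)
        if isinstance(self.n_individuals, int):
            self.n_individuals = (self.n_individuals,) * self.n_studies
        self.n_individuals = tuple(int(n) for n in self.n_individuals)
        if len(self.regions_per_study) != self.n_studies:
            raise ValueError("regions_per_study must have n_studies entries")
        if len(self.n_individuals) != self.n_studies:
            raise ValueError("n_individuals must have n_studies entries")
        if self.frac_het_increase + self.frac_het_decrease > 1:
            raise ValueError("frac_het_increase + frac_het_decrease must be <= 1")
        if not (0 <= self.frac_het_increase and 0 <= self.frac_het_decrease):
            raise ValueError("heterogeneity fractions must be non-negative")
        if self.base_sd <= 0:
            raise ValueError("base_sd must be positive")
        if any(n < 8 for n in self.n_individuals):
            raise ValueError("need at least 8 individuals per study (4 per period)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def simulate_gene_profile(
    ages_t,
    beta1: float,
    var_slope: float,
    base_sd: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Simulate one gene's expression over the given transformed ages.

    The mean is linear in transformed age with slope ``beta1``; the residual
    sd is ``base_sd * exp(var_slope * z)`` with ``z`` the standardized
    transformed age, so it is strictly increasing in age iff var_slope > 0.
    """
    t = np.asarray(ages_t, float)
    if t.size < 4:
        raise ValueError("need at least 4 ages")
    if base_sd <= 0:
        raise ValueError("base_sd must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sd_t = t.std(ddof=0)
    z = (t - t.mean()) / sd_t if sd_t > 0 else np.zeros_like(t)
    sd = base_sd * np.exp(var_slope * z)
    return beta1 * t + rng.normal(0.0, sd)


def _draw_ages_days(n: int, age_range_years: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Draw ages uniformly on the fourth-root-of-days scale, half per period.

    Half the individuals fall in development (< 20 years) and half in aging
    (>= 20 years) so both period splits are usable; within each period ages
    are uniform on the transformed scale, mimicking sampling that spreads
    evenly over the lifespan.
    """
    lo, hi = age_range_years
    cut = 20.0
    lo, hi = max(lo, 0.0), max(hi, 0.0)
    bounds = []
    if lo < cut:
        bounds.append((lo, min(hi, cut)))
    if hi >= cut:
        bounds.append((max(lo, cut), hi))
    if len(bounds) == 1:
        bounds = bounds * 2
    n_dev = n // 2
    sizes = (n_dev, n - n_dev)
    ages = []
    for (a, b), size in zip(bounds, sizes):
        t_lo = transform_age(a * DAYS_PER_YEAR)
        t_hi = transform_age(b * DAYS_PER_YEAR)
        t = rng.uniform(t_lo, t_hi, size=size)
        days = np.round(t**4, 3)
        # rounding must not move a sample across its period boundary
        if b <= cut:
            days = np.minimum(days, cut * DAYS_PER_YEAR - 0.001)
        elif a >= cut:
            days = np.maximum(days, cut * DAYS_PER_YEAR)
        ages.append(days)
    return np.concatenate(ages)


def simulate_collection(config: SimulationConfig) -> StudyCollection:
    """Simulate a full multi-study collection per the configuration.

    Gene heterogeneity classes (increase / decrease / null) and true
    mean-trend slopes are drawn once and reused for every dataset; individuals
    are drawn per study and shared across that study's region datasets.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    n_inc = int(round(config.frac_het_increase * config.n_genes))
    n_dec = int(round(config.frac_het_decrease * config.n_genes))
    if n_inc + n_dec > config.n_genes:
        raise ValueError("heterogeneity fractions infeasible for n_genes")
    var_slopes = np.zeros(config.n_genes)
    lo, hi = config.var_slope_range
    var_slopes[:n_inc] = rng.uniform(lo, hi, size=n_inc)
    var_slopes[n_inc : n_inc + n_dec] = -rng.uniform(lo, hi, size=n_dec)
    bmean, bsd = config.beta_distribution
    beta_dev = rng.normal(bmean, bsd, size=config.n_genes)
    beta_aging = rng.normal(bmean, bsd, size=config.n_genes)
    t20 = transform_age(20.0 * DAYS_PER_YEAR)

    datasets: dict[str, ExpressionDataset] = {}
    for s in range(config.n_studies):
        study = f"study{s + 1}"
        n_ind = config.n_individuals[s]
        ages_days = _draw_ages_days(n_ind, config.age_range_years, rng)
        individuals = [f"{study}_i{j:03d}" for j in range(n_ind)]
        sexes = rng.choice(["female", "male"], size=n_ind)
        for r in range(config.regions_per_study[s]):
            region = f"region{r + 1:02d}"
            name = f"{study}_{region}"
            sample_ids = [f"{name}_s{j:03d}" for j in range(n_ind)]
            t = transform_age(ages_days)
            is_aging = t >= t20
            values = np.empty((config.n_genes, n_ind))
            for g in range(config.n_genes):
                row = np.empty(n_ind)
                if (~is_aging).any():
                    row[~is_aging] = simulate_gene_profile(
                        t[~is_aging], beta_dev[g], 0.0, config.base_sd, rng
                    )
                if is_aging.any():
                    # continuous hinge at 20 years; heterogeneity trend acts
                    # over the aging samples only
                    row[is_aging] = beta_dev[g] * t20 + simulate_gene_profile(
                        t[is_aging] - t20, beta_aging[g], var_slopes[g], config.base_sd, rng
                    )
                values[g] = row
            expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
            meta = pd.DataFrame(
                {
                    "individual_id": individuals,
                    "age_days": ages_days,
                    "sex": sexes,
                    "region": region,
                    "study": study,
                    "batch": "",
                },
                index=pd.Index(sample_ids, name="sample_id"),
            )
            datasets[name] = ExpressionDataset(name=name, expr=expr, meta=meta)
    collection = StudyCollection(datasets)
    collection.planted_increase = genes[:n_inc]  # type: ignore[attr-defined]
    collection.planted_decrease = genes[n_inc : n_inc + n_dec]  # type: ignore[attr-defined]
    return collection


def write_collection(collection: StudyCollection, out_dir: str | Path) -> None:
    """Write every dataset as <name>_expr.tsv / <name>_meta.tsv plus an index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = {}
    for name, ds in collection.datasets.items():
        write_expression_dataset(ds, out / f"{name}_expr.tsv", out / f"{name}_meta.tsv")
        index[name] = {"study": ds.study, "period": ds.period}
    with open(out / "collection.yaml", "w") as fh:
        yaml.safe_dump({"datasets": index}, fh, sort_keys=True)
    planted = getattr(collection, "planted_increase", None)
    if planted is not None:
        (out / "planted_increase.txt").write_text("\n".join(planted) + ("\n" if planted else ""))


def read_collection(in_dir: str | Path) -> StudyCollection:
    """Read a collection written by :func:`write_collection`."""
    from .core_data import read_expression_dataset

    root = Path(in_dir)
    with open(root / "collection.yaml") as fh:
        index = yaml.safe_load(fh)["datasets"]
    datasets = {}
    for name, entry in index.items():
        ds = read_expression_dataset(root / f"{name}_expr.tsv", root / f"{name}_meta.tsv", name=name)
        ds.period = entry.get("period", "full")
        datasets[name] = ds
    collection = StudyCollection(datasets)
    planted_path = root / "planted_increase.txt"
    if planted_path.exists():
        collection.planted_increase = [  # type: ignore[attr-defined]
            line for line in planted_path.read_text().splitlines() if line
        ]
    return collection
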