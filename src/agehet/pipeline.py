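"""End-to-end orchestration: simulate/load -> preprocess -> fit -> meta-analysis.

Every stage reads and writes plain TSV/JSON, so stages can be re-run
independently from the CLI.  One global seed deterministically derives the
stage seeds; re-running with the same config and seed reproduces identical
statistical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import core_data, meta_consistency
from .change_models import fit_dataset
from .core_data import StudyCollection
from .enrichment import preranked_gsea, read_gmt, tie_robustness_gsea
from .synthetic_data import SimulationConfig, read_collection, simulate_collection, write_collection
from .trajectory_clustering import cluster_trajectories, smooth_and_interpolate

logger = logging.getLogger("agehet")

__all__ = ["PipelineConfig", "run_pipeline", "preprocess_collection", "split_collection"]


def _derive_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run.

    Defaults are the analysis' canonical settings: a 20-year development /
    aging cutoff, fourth-root age scale, 1,000 individual-level permutations,
    k = 8 trajectory clusters from splines with 3 effective degrees of
    freedom evaluated at 11 age points, and gene-set size bounds 5-500
    (10-500 for regulator sets).
    """

    out_dir: str = "agehet_out"
    input_dir: str | None = None
    simulation: dict[str, Any] | None = None
    age_cutoff_years: float = 20.0
    age_scale: str = "fourth_root"
    n_perm: int = 1000
    seed: int = 0
    k_clusters: int = 8
    spline_df: float = 3.0
    interpolation_points: int = 11
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    regulator_min_size: int = 10
    regulator_max_size: int = 500
    gene_sets_gmt: str | None = None
    tie_robustness_reps: int = 0
    quantile_normalization: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError(f"n_perm must be >= 100, got {self.n_perm}")
        if self.input_dir is None and self.simulation is None:
            raise ValueError("config needs either input_dir or a simulation section")
        if self.age_scale not in ("fourth_root", "linear", "sqrt", "log2"):
            raise ValueError(f"unknown age_scale {self.age_scale!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def preprocess_collection(
    collection: StudyCollection, quantile_normalization: bool = True
) -> StudyCollection:
    """Quantile-normalize, batch-restore where batches exist, scale, intersect.

    Per dataset: quantile normalization across samples; if the metadata
    carries more than one batch label, within-batch standardization with the
    gene's grand mean restored; then per-gene scaling to mean 0 / sd 1.
    A gene left constant by quantile normalization (same rank in every
    sample) carries no signal and is dropped with a warning before scaling.
    Finally all datasets are restricted to their common genes.

    Quantile normalization assumes that differences between the per-sample
    value distributions are technical.  Synthetic collections have no
    technical artifacts and their between-sample differences are the age
    trends themselves, so simulated runs should pass
    ``quantile_normalization=False``; applying QN there rescales samples by
    their biological spread and injects a spurious negative heterogeneity
    trend.
    """

    def _one(ds):
        values = core_data.quantile_normalize(ds.expr) if quantile_normalization else ds.expr
        batches = ds.meta["batch"].astype(str)
        if batches.nunique() > 1:
            values = core_data.batch_mean_restore(values, batches.to_numpy())
        sd = values.std(axis=1, ddof=1)
        constant = sd.index[sd == 0]
        if len(constant):
            logger.warning(
                "dataset %s: dropping %d constant gene(s) after normalization",
                ds.name, len(constant),
            )
            values = values.drop(index=constant)
            ds = ds.subset_genes(values.index)
        values = core_data.scale_genes(values)
        return ds.with_values(values)

    return core_data.intersect_common_genes(collection.map(_one))


def split_collection(
    collection: StudyCollection, cutoff_years: float = 20.0
) -> tuple[StudyCollection, StudyCollection]:
    """Split every dataset into its development and aging parts."""
    dev, aging = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, ds in collection.datasets.items():
            d, a = core_data.split_periods(ds, cutoff_years)
            dev[name], aging[name] = d, a
    return StudyCollection(dev), StudyCollection(aging)


def _fit_period(collection: StudyCollection, age_scale: str):
    tables, residuals = {}, {}
    for name, ds in collection.datasets.items():
        tables[name], residuals[name] = fit_dataset(ds, age_scale)
    return tables, residuals


def _stat_matrix(tables: dict[str, pd.DataFrame], column: str) -> pd.DataFrame:
    return pd.DataFrame({name: tbl[column] for name, tbl in tables.items()})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write TSV/JSON outputs plus a manifest.

    Returns the manifest dictionary.  On a stage failure the exception
    propagates after a FAILED marker naming the stage is written to the
    output directory, so partial outputs remain inspectable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    stage = "load"
    try:
        # ---- load or simulate -------------------------------------------
        if config.simulation is not None:
            sim_cfg = SimulationConfig(**{**config.simulation, "seed": _derive_seed(config.seed, "simulate")})
            collection = simulate_collection(sim_cfg)
            write_collection(collection, out / "simulated")
            manifest["stages"]["simulate"] = {"n_datasets": len(collection.datasets)}
        else:
            collection = read_collection(config.input_dir)
            manifest["input_checksums"] = {
                p.name: _sha256(p) for p in sorted(Path(config.input_dir).glob("*.tsv"))
            }
        logger.info("loaded %d datasets, %d studies", len(collection.datasets), len(collection.studies))

        # ---- preprocess --------------------------------------------------
        stage = "preprocess"
        processed = preprocess_collection(
            collection, quantile_normalization=config.quantile_normalization
        )
        n_genes = processed.datasets[processed.names[0]].n_genes
        manifest["stages"]["preprocess"] = {
            "n_common_genes": int(n_genes),
            "n_samples": {n: ds.n_samples for n, ds in processed.datasets.items()},
        }
        logger.info("preprocessed: %d common genes", n_genes)

        dev_coll, aging_coll = split_collection(processed, config.age_cutoff_years)

        # ---- per-gene fits ----------------------------------------------
        stage = "fit"
        fits = {}
        for period, coll in (("development", dev_coll), ("aging", aging_coll)):
            tables, residuals = _fit_period(coll, config.age_scale)
            fits[period] = {"tables": tables, "residuals": residuals, "collection": coll}
            fit_dir = out / "change_tables"
            fit_dir.mkdir(exist_ok=True)
            for name, tbl in tables.items():
                tbl.to_csv(fit_dir / f"{name}_{period}.tsv", sep="\t", float_format="%.6g")
            manifest["stages"].setdefault("fit", {})[period] = {
                name: int(tbl.shape[0]) for name, tbl in tables.items()
            }
        logger.info("fitted %d datasets x 2 periods", len(processed.datasets))

        # ---- permutations and consistency --------------------------------
        stage = "consistency"
        perm_set = meta_consistency.permute_individual_ages(
            processed, n_perm=config.n_perm, seed=_derive_seed(config.seed, "permute")
        )
        consistency_out: dict[str, Any] = {}
        summary: dict[str, Any] = {"seed": config.seed, "n_perm": config.n_perm}
        for period in ("development", "aging"):
            coll = fits[period]["collection"]
            rho = _stat_matrix(fits[period]["tables"], "rho")
            perm_rho = meta_consistency.permuted_heterogeneity(
                coll, fits[period]["residuals"], perm_set
            )
            result = meta_consistency.consistency_analysis(rho, perm_rho)
            consistency_out[period] = {"result": result, "rho": rho, "perm_rho": perm_rho}
            null_df = pd.DataFrame(
                result.perm_counts, columns=[f"N{i}" for i in range(result.n_datasets + 1)]
            )
            null_df.to_csv(out / f"consistency_null_{period}.tsv", sep="\t", index=False)
            summary[period] = {
                "observed_counts": result.observed_counts.tolist(),
                "p_per_level": result.p_per_level.tolist(),
                "n_consistent_all": len(result.consistent_genes()),
                "expected_at_max": result.expected_at(result.n_datasets),
            }

        cons_table = pd.DataFrame({
            "n_up_development": consistency_out["development"]["result"].n_up,
            "n_up_aging": consistency_out["aging"]["result"].n_up,
        })
        K = consistency_out["aging"]["result"].n_datasets
        cons_table["p_all_development"] = consistency_out["development"]["result"].p_per_level[K]
        cons_table["p_all_aging"] = consistency_out["aging"]["result"].p_per_level[K]
        cons_table.rename_axis("gene_id").to_csv(out / "consistency_table.tsv", sep="\t")

        # period-difference tests on rho
        dev_rho = consistency_out["development"]["rho"]
        aging_rho = consistency_out["aging"]["rho"]
        dev_perm = consistency_out["development"]["perm_rho"]
        aging_perm = consistency_out["aging"]["perm_rho"]
        for statistic in ("median_rho_diff", "median_correlation_diff"):
            obs, p, _ = meta_consistency.period_difference_test(
                dev_rho, aging_rho, dev_perm, aging_perm, statistic=statistic
            )
            summary[statistic] = {"observed": obs, "p": p}

        full_rho = pd.concat(
            [aging_rho.add_suffix(":aging"), dev_rho.add_suffix(":development")], axis=1
        )
        labels = {c: c.rsplit(":", 1)[1] for c in full_rho.columns}
        pcs, dispersion = meta_consistency.pca_dispersion_summary(full_rho, labels)
        pcs.rename_axis("dataset").to_csv(out / "pca_coordinates.tsv", sep="\t", float_format="%.6g")
        summary["pca_dispersion"] = dispersion

        with open(out / "consistency_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        manifest["stages"]["consistency"] = {
            k: v for k, v in summary.items() if k in ("development", "aging")
        }
        logger.info(
            "consistency: %d genes consistent in all aging datasets",
            summary["aging"]["n_consistent_all"],
        )

        # ---- trajectory clustering ---------------------------------------
        stage = "cluster"
        consistent = consistency_out["aging"]["result"].consistent_genes()
        min_n = min(ds.n_samples for ds in aging_coll.datasets.values())
        if len(consistent) >= 2 and min_n >= config.interpolation_points:
            heterogeneity = {
                name: fits["aging"]["residuals"][name].abs()
                for name in aging_coll.datasets
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traj = smooth_and_interpolate(
                    aging_coll.datasets, heterogeneity, consistent,
                    df=config.spline_df, n_points=config.interpolation_points,
                    age_scale=config.age_scale,
                )
            k = min(config.k_clusters, traj.shape[0])
            assignments, wcss, centers = cluster_trajectories(
                traj, k=k, seed=_derive_seed(config.seed, "cluster")
            )
            assignments.rename_axis("gene_id").to_csv(out / "clusters.tsv", sep="\t")
            centers.to_csv(out / "cluster_trajectories.tsv", sep="\t", float_format="%.6g")
            manifest["stages"]["cluster"] = {"n_genes": int(traj.shape[0]), "k": k, "wcss": wcss}
        else:
            manifest["stages"]["cluster"] = {
                "skipped": True,
                "reason": f"{len(consistent)} consistent genes, min aging n = {min_n}",
            }

        # ---- enrichment ---------------------------------------------------
        stage = "gsea"
        if config.gene_sets_gmt is not None:
            sets = read_gmt(config.gene_sets_gmt)
            scores = consistency_out["aging"]["result"].n_up.astype(float)
            gsea = preranked_gsea(
                scores, sets, n_perm=config.n_perm,
                seed=_derive_seed(config.seed, "gsea"),
                min_size=config.gsea_min_size, max_size=config.gsea_max_size,
            )
            if config.tie_robustness_reps > 0:
                gsea["robustness_frequency"] = tie_robustness_gsea(
                    scores, sets, n_reps=config.tie_robustness_reps,
                    seed=_derive_seed(config.seed, "gsea-ties"),
                    min_size=config.gsea_min_size, max_size=config.gsea_max_size,
                )
            gsea.to_csv(out / "gsea_aging.tsv", sep="\t", float_format="%.6g")
            manifest["stages"]["gsea"] = {"n_sets": int(gsea.shape[0])}

        manifest["config_hash"] = hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %r", stage)
        raise
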