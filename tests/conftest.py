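import numpy as np
import pandas as pd
import pytest

from agehet.core_data import ExpressionDataset, StudyCollection


def make_dataset(
    name="study1_region01",
    n_genes=20,
    ages_years=(1, 5, 10, 15, 25, 40, 60, 80),
    study="study1",
    region="region01",
    seed=0,
    individual_prefix=None,
):
    """Small deterministic dataset with one sample per individual."""
    rng = np.random.default_rng(seed)
    n = len(ages_years)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"{name}_s{j}" for j in range(n)]
    prefix = individual_prefix if individual_prefix is not None else study
    meta = pd.DataFrame(
        {
            "individual_id": [f"{prefix}_i{j}" for j in range(n)],
            "age_days": [y * 365.0 for y in ages_years],
            "sex": ["female" if j % 2 else "male" for j in range(n)],
            "region": region,
            "study": study,
            "batch": "",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    expr = pd.DataFrame(
        rng.normal(size=(n_genes, n)), index=pd.Index(genes, name="gene_id"), columns=samples
    )
    return ExpressionDataset(name=name, expr=expr, meta=meta)


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def two_region_collection():
    """One study with two regions sharing individuals, plus a second study."""
    a = make_dataset("study1_region01", region="region01", seed=1)
    b = make_dataset("study1_region02", region="region02", seed=2)
    c = make_dataset(
        "study2_region01", study="study2", region="region01",
        ages_years=(2, 8, 12, 18, 30, 50, 70, 90), seed=3,
    )
    return StudyCollection({ds.name: ds for ds in (a, b, c)})
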