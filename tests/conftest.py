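import numpy as np
import pandas as pd
import pytest

from metascreener import (BinaryLabels, ContinuousState, ExpressionDataset,
                          RunConfig, SignatureCollection)
from metascreener.synthetic import generate_cohort


@pytest.fixture(scope="session")
def small_dataset() -> ExpressionDataset:
    """60 genes x 12 samples, deterministic, with binary labels."""
    rng = np.random.default_rng(42)
    genes = [f"G{i:03d}" for i in range(60)]
    samples = [f"S{j:02d}" for j in range(12)]
    X = rng.normal(5.0, 1.0, size=(60, 12))
    labels = BinaryLabels({s: ("activation" if j < 6 else "inhibition")
                           for j, s in enumerate(samples)})
    return ExpressionDataset("small", pd.DataFrame(X, index=genes, columns=samples), labels)


@pytest.fixture(scope="session")
def small_signatures() -> SignatureCollection:
    return SignatureCollection({
        "SET_A": [f"G{i:03d}" for i in range(0, 10)],
        "SET_B": [f"G{i:03d}" for i in range(20, 35)],
        "SET_C": [f"G{i:03d}" for i in range(40, 52)],
    })


@pytest.fixture(scope="session")
def fast_config() -> RunConfig:
    return RunConfig(seed=7, n_perm_scorer=50, n_perm_fgsea=200, n_perm_assoc=200)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 datasets, 200 genes x 24 samples, one activated and one inhibited
    signature among 6."""
    return generate_cohort(n_datasets=2, n_genes=200, n_samples=24,
                           signature_sizes=[12] * 6,
                           directions=[1, -1, 0, 0, 0, 0],
                           effect_size=2.0, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort_cont():
    return generate_cohort(n_datasets=2, n_genes=200, n_samples=24,
                           signature_sizes=[12] * 6,
                           directions=[1, -1, 0, 0, 0, 0],
                           effect_size=2.0, mode="continuous", seed=12)


@pytest.fixture(scope="session")
def reduced_diff_config() -> RunConfig:
    return RunConfig(mode="diff", seed=5,
                     scorers=["zscore", "mean", "ssgsea", "ulm"],
                     diff_tests=["ttest", "wilcoxon"],
                     n_perm_scorer=50, n_perm_fgsea=100, n_perm_assoc=100)


@pytest.fixture(scope="session")
def reduced_cor_config() -> RunConfig:
    return RunConfig(mode="cor", seed=5,
                     scorers=["zscore", "mean", "ssgsea", "ulm"],
                     cor_tests=["pearson", "spearman"],
                     n_perm_scorer=50, n_perm_fgsea=100, n_perm_assoc=100)
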