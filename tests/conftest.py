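import numpy as np
import pandas as pd
import pytest

from organnet import synthetic
from organnet.normalization import ExpressionStudy, normalize_study


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimulationConfig(
        n_genes=300,
        n_modules=2,
        module_sizes=(40, 40),
        organ_effect=2.0,
        factor_loading_range=(0.8, 1.0),
        dispersion=0.1,
        n_tfs=10,
        n_pathway_genes=4,
        n_planted_links=4,
        n_organ_specific=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthetic.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    study, _ = small_dataset
    return normalize_study(study)


@pytest.fixture
def tiny_study():
    """Hand-sized study: 4 genes x 4 samples (2 organs x 2 reps)."""
    counts = pd.DataFrame(
        {
            "a_1": [10, 0, 5, 100],
            "a_2": [12, 0, 6, 90],
            "b_1": [9, 40, 0, 110],
            "b_2": [11, 44, 0, 95],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    design = pd.DataFrame(
        {"organ": ["a", "a", "b", "b"], "replicate": [1, 2, 1, 2]},
        index=pd.Index(counts.columns, name="sample_id"),
    )
    lengths = pd.Series([1000.0, 2000.0, 500.0, 1500.0], index=counts.index)
    return ExpressionStudy(counts=counts, gene_length=lengths, design=design)


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Independent triple-loop topological overlap oracle."""
    n = a.shape[0]
    a = a.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = 0.0
            for u in range(n):
                if u != i and u != j:
                    shared += a[i, u] * a[u, j]
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def brute_force_ari(x, y) -> float:
    """Adjusted Rand index straight from the contingency-table formula."""
    from math import comb

    x = list(x)
    y = list(y)
    xs, ys = sorted(set(x)), sorted(set(y))
    table = np.zeros((len(xs), len(ys)), dtype=int)
    for xi, yi in zip(x, y):
        table[xs.index(xi), ys.index(yi)] += 1
    sum_comb = sum(comb(int(n), 2) for n in table.ravel())
    sum_a = sum(comb(int(n), 2) for n in table.sum(axis=1))
    sum_b = sum(comb(int(n), 2) for n in table.sum(axis=0))
    total = comb(len(x), 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)
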