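import numpy as np
import pandas as pd
import pytest

from gxetools import (
    CategoryCounts,
    GeneCategoryClassifier,
    SimulationConfig,
    generate_dataset,
)
from gxetools.dataset import ExpressionDataset


@pytest.fixture(scope="session")
def table2_counts() -> CategoryCounts:
    """The ten published study-scale category counts (used as an input)."""
    return CategoryCounts(
        {
            "Untested": 19391,
            "Low-expression": 8488,
            "E-only": 9208,
            "E-ambiguous": 3619,
            "G-only": 75,
            "GxE": 542,
            "G+E": 84,
            "G+E-ambiguous": 1437,
            "Constant": 7290,
            "Ambiguous": 3511,
        }
    )


@pytest.fixture(scope="session")
def noiseless_sim():
    """Small planted dataset with zero replicate noise, plus its truth."""
    cfg = SimulationConfig(n_genes=250, noise_cv=0.0, seed=42)
    dataset, truth = generate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Planted dataset at the default study noise level (CV 0.05 here)."""
    cfg = SimulationConfig(n_genes=400, noise_cv=0.05, seed=17)
    dataset, truth = generate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def fitted_noiseless(noiseless_sim):
    _, dataset, truth = noiseless_sim
    clf = GeneCategoryClassifier().fit(dataset)
    return dataset, truth, clf


def make_dataset(cell_means: dict, reps=3, noise=0.0, seed=0, genotypes=("G1", "G2"),
                 times=(0.0, 6.0, 12.0, 24.0)) -> ExpressionDataset:
    """Tiny hand-built dataset from per-gene (genotype, time) -> mean FPKM."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene, cells in cell_means.items():
        for g in genotypes:
            for t in times:
                m = cells[(g, t)]
                for r in range(reps):
                    val = m * (1 + noise * rng.standard_normal()) if noise else m
                    rows.append((gene, g, t, r, max(val, 0.0)))
    df = pd.DataFrame(
        rows, columns=["gene_id", "genotype", "time_hr", "replicate", "fpkm"]
    )
    return ExpressionDataset(df, genotypes[0], genotypes[1], times)
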