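from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from reosig import SimulationConfig

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def rat_reference() -> pd.DataFrame:
    """Published 16-gene reference table from a 6-vs-6 rat COPD treatment
    study: model-vs-control fold-change/t/p plus four per-treatment p-values
    and the printed reversal counts at thresholds 0.05 / 0.1 / 0.2."""
    return pd.read_csv(DATA_DIR / "rat_de_reference.tsv", sep="\t", comment="#").set_index(
        "gene", drop=False
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast cohort configuration for unit tests (not the study conditions)."""
    return SimulationConfig(
        n_genes=60, n_planted_pairs=10, n_samples_per_group=15, seed=1234
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(99)


def random_matrix(rng: np.random.Generator, n_genes: int, n_samples: int) -> pd.DataFrame:
    """A positive random expression matrix with deterministic gene/sample ids."""
    return pd.DataFrame(
        np.exp(rng.normal(6.0, 1.0, size=(n_genes, n_samples))),
        index=pd.Index([f"G{i:04d}" for i in range(n_genes)], name="feature_id"),
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )
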