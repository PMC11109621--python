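import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for reference_impl

from scmformer import (ModalityMatrix, PreprocessConfig, ScmModelConfig,
                       SimConfig, pair, preprocess_dataset, simulate_paired)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """Tiny paired dataset for fast unit tests (200 cells)."""
    cfg = SimConfig(n_cells=200, n_genes=120, n_proteins=24, seed=7)
    ds, truth = simulate_paired(cfg)
    return ds, truth, cfg


@pytest.fixture(scope="session")
def small_reduced(small_sim):
    ds, truth, cfg = small_sim
    pp = PreprocessConfig(aligned_dim=32)
    return preprocess_dataset(ds, pp)


@pytest.fixture
def tiny_config():
    return ScmModelConfig(s=8, H=2, aligned_dim=32, epochs=2, batch_size=32,
                          drop_rate=0.0, lr=1e-3, seed=1)


@pytest.fixture
def csv_matrix(tmp_path):
    """3-cell x 4-feature CSV fixture."""
    path = tmp_path / "m.csv"
    path.write_text(
        "cell,f1,f2,f3,f4\n"
        "c1,1,0,2,3\n"
        "c2,0,1,1,0\n"
        "c3,4,2,0,1\n"
    )
    return path
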