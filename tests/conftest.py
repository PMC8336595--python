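import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `reference` importable

from circnet import ModelConfig, SimConfig, init_params, simulate_dataset


@pytest.fixture
def tiny_model_config():
    return ModelConfig(K=2, l=3, L=4, h=4, a_dim=2, f_dim=3, lambda_l2=1e-3, seed=5)


@pytest.fixture
def tiny_params(tiny_model_config):
    return init_params(tiny_model_config)


@pytest.fixture
def small_dataset():
    return simulate_dataset(SimConfig(n_genes=12, exon_count_range=(1, 3), seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def write_fasta(path: Path, entries: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n{seq}\n")
    return path
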