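import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small, quickly generated synthetic dataset shared across tests."""
    from raybok import GeneratorConfig, generate_dataset

    cfg = GeneratorConfig(
        n_images=144, height_range=(96, 160), width_range=(96, 160), seed=5
    )
    out = tmp_path_factory.mktemp("tiny_ds")
    path, table = generate_dataset(cfg, out)
    return cfg, path, table
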