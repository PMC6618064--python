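import warnings

import numpy as np
import pytest

import bvnma
from bvnma.data_model import ContrastObservation, NetworkData

warnings.filterwarnings("ignore", message="contrast")


@pytest.fixture(scope="session")
def toy_pair_network() -> NetworkData:
    """Three complete studies on a single A-B contrast."""
    rows = [
        ("s1", "A", "B", 0.50, 0.20, 0.80, 0.25, 0.4),
        ("s2", "A", "B", 0.30, 0.15, 0.55, 0.20, 0.4),
        ("s3", "A", "B", 0.65, 0.25, 0.95, 0.30, 0.4),
    ]
    return NetworkData(
        [
            ContrastObservation(sid, k, l, y1, se1, y2, se2, rw)
            for sid, k, l, y1, se1, y2, se2, rw in rows
        ]
    )


@pytest.fixture(scope="session")
def triangle_network() -> NetworkData:
    """One study per contrast of a three-treatment loop (A-B, B-C, A-C)."""
    rows = [
        ("t1", "A", "B", 0.9, 0.20, 1.9, 0.25, 0.6),
        ("t2", "B", "C", 2.1, 0.18, 1.1, 0.22, 0.6),
        ("t3", "A", "C", 3.1, 0.22, 2.9, 0.28, 0.6),
    ]
    return NetworkData(
        [
            ContrastObservation(sid, k, l, y1, se1, y2, se2, rw)
            for sid, k, l, y1, se1, y2, se2, rw in rows
        ]
    )


@pytest.fixture(scope="session")
def scenario1_data() -> NetworkData:
    return bvnma.generate_dataset(bvnma.builtin_scenarios()["1"], seed=42)


@pytest.fixture(scope="session")
def fast_cfg() -> bvnma.McmcConfig:
    return bvnma.McmcConfig(n_chains=2, n_warmup=300, n_draws=500, thin=2, seed=7)


@pytest.fixture(scope="session")
def brma_scenario1_draws(scenario1_data, fast_cfg):
    """One shared BRMA fit on a scenario-1 dataset (reused read-only)."""
    model = bvnma.build_model(scenario1_data, "brma")
    return bvnma.fit(model, fast_cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
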