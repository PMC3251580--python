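import numpy as np
import pandas as pd
import pytest

from pathgwas import simulate as sim


@pytest.fixture(scope="session")
def small_dataset() -> sim.SimulatedDataset:
    """Small 5-study null dataset reused across read-only tests."""
    cfg = sim.SimConfig(
        n_cases=(40,) * 5,
        n_controls=(40,) * 5,
        n_snps=100,
        block_size=10,
        snps_per_gene=5,
        pathway_sizes=(5, 10),
        n_pathways=10,
        seed=20,
    )
    return sim.simulate_dataset(cfg)


@pytest.fixture
def tiny_samples() -> pd.DataFrame:
    """Minimal two-study sample table for hand-built genotype tests."""
    rng = np.random.default_rng(5)
    n = 200
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "status": rng.integers(0, 2, n),
            "age": rng.integers(40, 76, n),
            "sex": rng.integers(0, 2, n),
            "study": np.where(np.arange(n) < n // 2, "study1", "study2"),
            "dna_source": rng.integers(0, 2, n),
            "smoking": rng.choice(["never", "former", "occasional", "current"], n),
        }
    )
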