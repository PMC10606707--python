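import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from rohscan.genotypes import GenotypeDataset
from rohscan.simulate import SimConfig, simulate


def random_dataset(rng, n_samples=8, markers_per_chrom=(10, 8), missing_rate=0.0):
    """Small random GenotypeDataset for round-trip and ROH tests."""
    rows = []
    for c, m in enumerate(markers_per_chrom, 1):
        pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=m, replace=False))
        for j in range(m):
            rows.append((f"c{c}m{j}", str(c), int(pos[j])))
    markers = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])
    calls = rng.integers(0, 3, size=(n_samples, len(markers))).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = -1
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeDataset(samples, markers, calls)


@pytest.fixture(scope="session")
def small_sim():
    """One small but complete synthetic study shared across tests."""
    cfg = SimConfig(
        n_founders=12,
        n_generations=3,
        offspring_per_generation=40,
        n_chromosomes=5,
        snps_per_chromosome=60,
        n_hys=12,
        planted_effects=(("2", 20_000_000, 60_000_000, -0.8),),
        planted_carrier_freq=0.35,
        seed=42,
    )
    return cfg, simulate(cfg)
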