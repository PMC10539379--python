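import numpy as np
import pandas as pd
import pytest

from trdprs.genoprs import GenotypeMatrix
from trdprs.synthdata import SimulationConfig, simulate_study


def make_genotypes(n, m, seed=0, maf=(0.15, 0.5), missing_rate=0.0):
    """Independent binomial genotypes with plain metadata, for unit tests."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    if missing_rate:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    variants = pd.DataFrame(
        {
            "id": [f"rs{i}" for i in range(m)],
            "chrom": rng.integers(1, 23, size=m),
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    subjects = np.array([f"s{i:04d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(subjects, variants, dos), p


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared across read-only tests."""
    cfg = SimulationConfig(n_subjects=500, n_snps=400, seed=42)
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
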