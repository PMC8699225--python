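import numpy as np
import pandas as pd
import pytest

from polygs import DosageMatrix, PhenotypeVector, SimConfig, simulate_genotypes


def random_panel(n, m, ploidy=4, seed=0, polymorphic=True):
    """Small random dosage panel guaranteed polymorphic if requested."""
    rng = np.random.default_rng(seed)
    for attempt in range(100):
        vals = rng.binomial(ploidy, rng.uniform(0.15, 0.85, size=m), size=(n, m))
        p = vals.mean(axis=0) / ploidy
        if not polymorphic or np.all((p > 0) & (p < 1)):
            return DosageMatrix(vals.astype(float), ploidy, [f"S{i}" for i in range(n)])
    raise RuntimeError("could not draw a polymorphic panel")


@pytest.fixture
def toy_panel():
    """3 individuals x 2 markers, hand-pickable numbers."""
    vals = np.array([[0.0, 4.0], [2.0, 1.0], [4.0, 3.0]])
    return DosageMatrix(vals, 4, ["a", "b", "c"])


@pytest.fixture
def toy_phenotype():
    return PhenotypeVector([1.0, 2.5, 0.5], ["a", "b", "c"])


@pytest.fixture(scope="session")
def sim_dataset():
    """Shared mid-size simulated dataset (genotypes only)."""
    return simulate_genotypes(SimConfig(n=200, m=400, seed=42))
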