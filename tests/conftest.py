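import numpy as np
import pytest

from npmap4 import GeneratorConfig, generate_dataset, signatures_for

#: small named structures used across tests
FIXTURE_SMILES = {
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "glycylglycine": "NCC(=O)NCC(=O)O",
    "methyl_glucoside": "COC1OC(CO)C(O)C(O)C1O",
    "caffeine": "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
}


@pytest.fixture(scope="session")
def small_dataset():
    """Substructure-signal two-class set, 30 molecules per origin."""
    return generate_dataset(GeneratorConfig(n_per_class=30, seed=5))


@pytest.fixture(scope="session")
def small_signatures(small_dataset):
    return signatures_for(small_dataset.smiles)


@pytest.fixture(scope="session")
def small_index(small_dataset):
    return {r.id: i for i, r in enumerate(small_dataset)}


def random_signatures(n: int, seed: int, n_shared: int = 200) -> np.ndarray:
    """Synthetic signature stacks with controlled overlap (not molecules)."""
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 2**31 - 1, size=(1, 1024), dtype=np.uint32)
    sigs = np.repeat(base, n, axis=0)
    for i in range(n):
        pos = rng.choice(1024, size=1024 - n_shared, replace=False)
        sigs[i, pos] = rng.integers(0, 2**31 - 1, size=pos.size, dtype=np.uint32)
    return sigs
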