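import numpy as np
import pytest

from straindrift.simulate import DriftConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated cell line, two strains, three timepoints, small sizes."""
    cfg = DriftConfig(n_strains=2, seed=7)
    return simulate_dataset(
        "demo", cfg, n_loci=1500, n_cpgs=800, n_genes=400, n_compounds=10
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
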