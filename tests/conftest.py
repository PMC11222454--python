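from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from temponet.simulate import generate_scenario, simulate_expression

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def mature_fasta_path() -> Path:
    """Synthetic mature-sequence FASTA (constructed fixture, not a database export)."""
    return DATA_DIR / "synthetic_mature.fa"


@pytest.fixture(scope="session")
def small_scenario():
    return generate_scenario(
        n_mirna=4, n_mrna=8, edge_density=0.15, frac_repressive=1.0, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return simulate_expression(small_scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_frame(rng, p, n, index=None):
    index = index or [f"v{i}" for i in range(p)]
    return pd.DataFrame(rng.normal(size=(p, n)), index=index)
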