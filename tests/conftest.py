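import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from lncsponge.simulate import default_config, simulate_mirnas, simulate_transcriptomes


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def sim_dataset():
    """One default synthetic dataset shared across tests."""
    config = default_config(seed=7)
    sets, truth = simulate_transcriptomes(config)
    mirnas = simulate_mirnas(config)
    return config, sets, truth, mirnas
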