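import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

import iistruct as ii


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_tpm():
    """Factory for random dense state-by-node TPMs."""

    def make(n_nodes: int, seed: int) -> ii.StateByNodeTPM:
        r = np.random.default_rng(seed)
        return ii.StateByNodeTPM(
            r.uniform(0.0, 1.0, size=(2**n_nodes, n_nodes)), n_nodes=n_nodes
        )

    return make


@pytest.fixture
def self_coupled_2node():
    """Two channels with strong self- and weak cross-connections."""
    probs = np.zeros((4, 2))
    for s in range(4):
        a, b = s & 1, (s >> 1) & 1
        probs[s, 0] = 0.1 + 0.8 * a + 0.05 * b
        probs[s, 1] = 0.1 + 0.8 * b + 0.05 * a
    return ii.StateByNodeTPM(probs, n_nodes=2)


@pytest.fixture(scope="session")
def tiny_study_table():
    """A 4-channel, short-epoch study pushed through the whole pipeline."""
    from iistruct.pipeline import binarize_study, run_study
    from iistruct.synthetic import SyntheticStudyConfig, generate_pseudo_lfp

    config = SyntheticStudyConfig(
        n_subjects=1,
        n_channels=4,
        samples_per_epoch=400,
        n_epochs_per_condition=4,
        seed=7,
    )
    study = generate_pseudo_lfp(config)
    return run_study(binarize_study(study), k=3, tau_samples=4)
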