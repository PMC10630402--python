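import numpy as np
import pytest

from socialcpm import PlantedSignalSpec, simulate_cpm_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """Small planted-signal dataset shared by CPM tests: 60 subjects,
    20 nodes (190 edges), 12 signal edges at effect 0.5."""
    rng = np.random.default_rng(42)
    signal = tuple(sorted(rng.choice(190, size=12, replace=False)))
    spec = PlantedSignalSpec(
        n_subjects=60, n_nodes=20, signal_edges=signal, effect_size=0.5, seed=7
    )
    return simulate_cpm_dataset(spec)


@pytest.fixture(scope="session")
def null_dataset():
    """Null dataset: no planted edges, uncorrelated confound."""
    return simulate_cpm_dataset(
        PlantedSignalSpec(n_subjects=60, n_nodes=20, signal_edges=(), confound_r=0.0, seed=11)
    )
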