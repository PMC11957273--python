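import numpy as np
import pytest

from gkan.synthetic_data import SyntheticDatasetSpec, make_dataset


@pytest.fixture(scope="session")
def zdna_small():
    """Small planted Z-DNA dataset shared by training-level tests."""
    spec = SyntheticDatasetSpec(motif_class="zdna", n_sequences=400,
                                seq_length=80, motif_strength=0.9,
                                motif_length=20, seed=11)
    return make_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
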