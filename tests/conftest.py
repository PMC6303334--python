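import numpy as np
import pytest

import morphosym as ms


@pytest.fixture(scope="session")
def lantern_params():
    return ms.VarianceComponents(seed=42)


@pytest.fixture(scope="session")
def lantern_dataset(lantern_params):
    dataset, truth = ms.simulate_lanterns(lantern_params)
    return dataset, truth


@pytest.fixture(scope="session")
def object_components(lantern_dataset):
    dataset, _ = lantern_dataset
    return ms.prepare_object(dataset)


@pytest.fixture(scope="session")
def matching_components(lantern_dataset):
    dataset, _ = lantern_dataset
    return ms.prepare_matching(dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_scheme():
    """5-landmark bilateral scheme: pairs (1,2), (4,5); landmark 3 on the axis."""
    return ms.SymmetryScheme(
        mode="object", n_landmarks=5, pairing=((1, 2), (4, 5)), unpaired=(3,)
    )
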