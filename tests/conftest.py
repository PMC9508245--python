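import numpy as np
import pytest

from connvar import Parcellation, make_parcellation


@pytest.fixture
def tiny_parc():
    """Handcrafted 6-ROI, 2-cluster atlas on a radius-100 sphere."""
    coords = np.array(
        [
            [100.0, 0.0, 0.0],
            [0.0, 100.0, 0.0],
            [0.0, 0.0, 100.0],
            [-100.0, 0.0, 0.0],
            [0.0, -100.0, 0.0],
            [0.0, 0.0, -100.0],
        ]
    )
    return Parcellation(
        roi_ids=np.array([f"r{i}" for i in range(6)], dtype=object),
        roi_names=np.array([f"ROI {i}" for i in range(6)], dtype=object),
        roi_size=np.array([300.0, 250.0, 400.0, 320.0, 280.0, 350.0]),
        cluster_of=np.array([0, 0, 0, 1, 1, 1]),
        coords=coords,
        radius=100.0,
    )


@pytest.fixture(scope="session")
def parc60():
    """Synthetic 60-ROI, 6-cluster atlas shared across tests."""
    return make_parcellation(60, 6, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
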