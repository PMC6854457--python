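import numpy as np
import pytest

from opmbeam.geometry import (
    REFERENCE,
    SCALP,
    SensorArray,
    SourceGrid,
    SphereHeadModel,
    make_reference_array,
    make_scalp_array,
)
from opmbeam.simulate import COUNTING, SCENE, EpochedData


@pytest.fixture(scope="session")
def head():
    return SphereHeadModel()


@pytest.fixture(scope="session")
def scalp(head):
    return make_scalp_array(21, head, seed=0)


@pytest.fixture(scope="session")
def refs(head):
    return make_reference_array(head)


@pytest.fixture(scope="session")
def small_grid(head):
    return SourceGrid.centered_cube(head, spacing=0.003, n=10)


def toy_sensor_array(n_scalp: int, n_ref: int = 0) -> SensorArray:
    """Geometry-free sensor array for tests that only need channel bookkeeping."""
    n = n_scalp + n_ref
    positions = np.column_stack(
        [np.linspace(0.1, 0.2, n), np.zeros(n), np.zeros(n)]
    )
    orientations = np.tile([1.0, 0.0, 0.0], (n, 1))
    roles = np.array([SCALP] * n_scalp + [REFERENCE] * n_ref, dtype=object)
    names = [f"ch{i}" for i in range(n)]
    return SensorArray(names, positions, orientations, roles)


def toy_epochs(data: np.ndarray, sfreq: float = 1200.0, labels=None,
               n_ref: int = 0) -> EpochedData:
    """Wrap a (trials, channels, samples) tensor with minimal metadata."""
    data = np.asarray(data, dtype=float)
    n_trials, n_channels, _ = data.shape
    if labels is None:
        half = n_trials // 2
        labels = np.array(
            [SCENE] * half + [COUNTING] * (n_trials - half), dtype=object
        )
    sensors = toy_sensor_array(n_channels - n_ref, n_ref)
    return EpochedData(data, labels, sfreq, sensors)
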