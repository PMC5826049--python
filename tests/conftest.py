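import numpy as np
import pytest

from embryodyn.config import GroundTruth, SimulationConfig


@pytest.fixture
def base_config():
    return SimulationConfig(seed=11)


@pytest.fixture
def brownian_truth():
    return GroundTruth(true_D=0.01)


@pytest.fixture
def perfect_lattice_truth():
    return GroundTruth(
        lattice_spacing=5.0, positional_noise_sd=0.0, defect_rate=0.0
    )


def rotate(points: np.ndarray, angle_rad: float, about=(0.0, 0.0)) -> np.ndarray:
    """Rigidly rotate a point set about a pivot."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s], [s, c]])
    about = np.asarray(about, float)
    return (np.asarray(points, float) - about) @ rot.T + about
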