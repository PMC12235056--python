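"""Shared fixtures: skeleton geometry, waveforms and small generated trials."""

import numpy as np
import pytest

from girdlekin import (
    ConditionScenario,
    default_skeleton,
    default_waveforms,
    generate_trial,
)


@pytest.fixture(scope="session")
def skeleton():
    return default_skeleton()


@pytest.fixture(scope="session")
def waveforms():
    return default_waveforms()


@pytest.fixture(scope="session")
def intact_scenario():
    return ConditionScenario.intact()


@pytest.fixture(scope="session")
def abduction_trial(skeleton, waveforms, intact_scenario):
    """Noise-free intact abduction trial (shared; treat as read-only)."""
    return generate_trial(skeleton, waveforms["abduction"], intact_scenario, sigma_mm=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
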