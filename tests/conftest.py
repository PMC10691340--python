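"""Shared fixtures: canonical small systems and session-scoped trained objects.

Expensive artifacts (trained attractor networks, synthetic recordings) are
session-scoped so the module tests and the acceptance tests share them.
"""

import numpy as np
import pytest

from infoload.attractor import AttractorNet, optimize_information_loading
from infoload.linear import LinearNetwork
from infoload.synth import RecordingConfig, make_synthetic_recording


@pytest.fixture(scope="session")
def canonical_A():
    """The canonical 2-neuron feedforward integrator: A = [[0, 5], [0, -1]]."""
    return np.array([[0.0, 5.0], [0.0, -1.0]])


@pytest.fixture(scope="session")
def canonical_net(canonical_A):
    return LinearNetwork(np.eye(2) + canonical_A, tau=1.0)


@pytest.fixture(scope="session")
def trained_attractor():
    """A 50-neuron unconstrained attractor net trained at reduced budget
    under variable delays and strong noise (stable-attractor regime)."""
    net = AttractorNet.random(kind="unconstrained", gain=1.5,
                              noise_sigma=0.45, seed=11)
    trained, history = optimize_information_loading(
        net, delay_T=(3.0, 12.0), iters=800, n_train_trials=8, seed=12)
    return trained, history


@pytest.fixture(scope="session")
def trained_symmetric_attractor():
    net = AttractorNet.random(kind="symmetric", gain=1.5,
                              noise_sigma=0.45, seed=21)
    trained, history = optimize_information_loading(
        net, delay_T=(3.0, 12.0), iters=800, n_train_trials=8, seed=22)
    return trained, history


@pytest.fixture(scope="session")
def amplifying_recording():
    """Default synthetic recording with most-amplifying loading."""
    cfg = RecordingConfig(loading="amplifying", seed=10,
                          trials_per_condition=20)
    trials, gt = make_synthetic_recording(cfg)
    return cfg, trials, gt
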