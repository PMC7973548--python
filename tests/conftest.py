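import numpy as np
import pytest

from obhfo.containers import ProbeGeometry
from obhfo.synthlfp import GroundTruth, generate_laminar_recording


@pytest.fixture(scope="session")
def long_probe():
    return ProbeGeometry(n_channels=32, spacing_um=100.0)


@pytest.fixture(scope="session")
def coupled_session(long_probe):
    """One strongly coupled 60 s session reused by several test modules."""
    gt = GroundTruth(seed=3, duration=60.0, fs=2000.0, coupling_kappa=8.0)
    return generate_laminar_recording(gt, long_probe)


@pytest.fixture(scope="session")
def hfo_best_channel(coupled_session):
    """Index of the channel with the strongest HFO dipole weight."""
    from obhfo.synthlfp import dipole_profile

    gt = coupled_session.ground_truth
    w = dipole_profile(
        coupled_session.geometry.depths_um,
        gt.hfo_dipole_depth,
        gt.hfo_dipole_halfwidth,
    )
    return int(np.argmax(w))
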