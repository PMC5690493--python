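import numpy as np
import pytest
from hypothesis import settings

from oofrecon import (BeamModelParams, BEVGrid, DetectorGeometry, OOFSettings,
                      generate_plan)

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def model():
    return BeamModelParams(energy_label="6X", edf=0.02, mlc_transmission=0.02,
                           jaw_transmission=0.002)


@pytest.fixture
def static_beam():
    return generate_plan("static", (100.0, 100.0), total_mu=100.0).beams[0]


@pytest.fixture
def sliding_beam():
    return generate_plan("sliding_window", (60.0, 60.0), n_control_points=5,
                         total_mu=50.0, aperture_width=10.0).beams[0]


@pytest.fixture
def phantom():
    return DetectorGeometry()


def random_dynamic_beam(rng, n_cp=5, n_leaves=20, total_mu=20.0):
    """A random 5-control-point dynamic beam with monotone metersets."""
    from oofrecon import Beam, ControlPoint

    bounds = np.linspace(-100.0, 100.0, n_leaves + 1)
    mus = np.sort(rng.uniform(0, total_mu, n_cp - 2))
    mus = np.concatenate([[0.0], mus, [total_mu]])
    cps = []
    for mu in mus:
        a = rng.uniform(-60, 20, n_leaves)
        b = a + rng.uniform(0, 60, n_leaves)
        cps.append(ControlPoint(
            cumulative_meterset=float(mu), gantry_angle=0.0,
            leaf_positions=np.vstack([a, b]),
            jaw_positions=(-50.0, 50.0, -50.0, 50.0),
            leaf_boundaries=bounds,
        ))
    return Beam(name="rand", energy="6X", control_points=cps)
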