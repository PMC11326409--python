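import numpy as np
import pytest

from octaxis import (
    Beam,
    MeasurementPair,
    apparent_from_true,
    axis_from_angles,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_pair(theta, alpha, dn, omega_deg=15.0) -> MeasurementPair:
    """Noiseless measurement pair generated by the forward model."""
    v = axis_from_angles(theta, alpha, dn)
    m1 = apparent_from_true(v, Beam.normal())
    m2 = apparent_from_true(v, Beam.tilted_y(omega_deg))
    return MeasurementPair(m1=m1, m2=m2, omega_deg=omega_deg)


@pytest.fixture
def pair_factory():
    return make_pair
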