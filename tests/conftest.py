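"""Shared desk-scale fixtures: the reference 128-element, 5 MHz acquisition."""

import numpy as np
import pytest

from fkbeam import (
    ImageGrid,
    LinearArray,
    Medium,
    PlaneWaveTransmit,
    Pulse,
    Scatterer,
    simulate_channel_data,
)

SOUND_SPEED = 1540.0
F0 = 5.0e6
WAVELENGTH = SOUND_SPEED / F0  # 308 um


@pytest.fixture(scope="session")
def array():
    return LinearArray(n_elements=128, pitch=0.3e-3)


@pytest.fixture(scope="session")
def small_array():
    return LinearArray(n_elements=32, pitch=0.3e-3)


@pytest.fixture(scope="session")
def medium():
    return Medium(SOUND_SPEED)


@pytest.fixture(scope="session")
def pulse():
    return Pulse(center_frequency=F0, fractional_bandwidth=0.6, sampling_rate=4 * F0)


@pytest.fixture(scope="session")
def point_channel(array, medium, pulse):
    """Noiseless single point target at (0, 25 mm), unsteered transmit."""
    return simulate_channel_data(
        [Scatterer(0.0, 25e-3, 1.0)],
        array,
        medium,
        PlaneWaveTransmit(0.0),
        pulse,
    )


@pytest.fixture(scope="session")
def point_grid():
    """Quarter-wavelength grid centered on the (0, 25 mm) point target."""
    return ImageGrid.regular(-3e-3, 3e-3, 22e-3, 28e-3, WAVELENGTH / 4)


def make_point_channel(array, medium, pulse, a_w, l_w, angle, duration=None):
    return simulate_channel_data(
        [Scatterer(a_w, l_w, 1.0)],
        array,
        medium,
        PlaneWaveTransmit(angle),
        pulse,
        duration=duration,
    )
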