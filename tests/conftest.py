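import pytest

from pentrack.pen_model import build_default_geometry


@pytest.fixture(scope="session")
def geom():
    """The bundled experimental pen: 6x5 grid, A2 defective, 0.2199 cm/px."""
    return build_default_geometry()


@pytest.fixture(scope="session")
def zero_gap_geom():
    """A pen exactly tiled by the antennas: centers 41 cm / 32 cm apart."""
    return build_default_geometry(
        {
            "pen_m": [2.46, 1.60],
            "gaps_cm": {"x": [0.0] * 7, "y": [0.0] * 6},
            "defective": [],
        }
    )
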