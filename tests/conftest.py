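import numpy as np
import pytest

from ventriflow import phantom as ph
from ventriflow.pipeline import analyze_study


@pytest.fixture(scope="session")
def plug_default_params():
    return ph.PlugFlowParams(L=100.0, v=80.0, T_d=1000.0, T_s=1000.0)


@pytest.fixture(scope="session")
def plug_default_study(plug_default_params):
    return ph.make_plug_flow_phantom(plug_default_params)


@pytest.fixture(scope="session")
def chamber_study():
    return ph.make_chamber_phantom(ph.ChamberPhantomParams(), seed=0)


@pytest.fixture(scope="session")
def chamber_analysis(chamber_study):
    """Full pipeline on the default chamber phantom at the default step."""
    return analyze_study(chamber_study)


def rotation_field(n: int = 21, dx: float = 2.0, period_ms: float = 2000.0):
    """Solid-body rotation about z through the grid centre (linear in space,
    constant in time), used for integrator-order and reversibility checks."""
    from ventriflow.field_io import VelocityField4D

    origin = np.array([-(n // 2) * dx] * 3)
    xs = origin[0] + dx * np.arange(n)
    X, Y, _ = np.meshgrid(xs, xs, xs, indexing="ij")
    omega = 2.0 * np.pi / (period_ms / 1000.0)
    vel = np.zeros((n, n, n, 2, 3))
    for k in range(2):
        vel[..., k, 0] = -omega * Y
        vel[..., k, 1] = omega * X
    return VelocityField4D(
        vel, np.array([dx] * 3), origin, rr_ms=period_ms,
        frame_times_ms=np.array([0.0, period_ms / 2.0]),
    ), omega
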