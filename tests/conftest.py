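import numpy as np
import pytest

from mcbridge import (
    CardiacParams,
    CompressionSchedule,
    PressureChannels,
    PressureDiameterFit,
    TubeGeometry,
)


@pytest.fixture
def geometry() -> TubeGeometry:
    """Silicone-phantom geometry: 2.465/2.165 mm unloaded radii, 1.2 axial stretch."""
    return TubeGeometry(R0_mm=2.465, Ri_mm=2.165, lambda_z=1.2)


@pytest.fixture
def fit() -> PressureDiameterFit:
    """Fitted compliance quartic of the phantom (p in mmHg)."""
    return PressureDiameterFit(a=4.91, b=3.17e-3, c=1.18e-5, d=4.81e-7, e=2.39e-9)


@pytest.fixture
def cardiac() -> CardiacParams:
    return CardiacParams()


@pytest.fixture
def full_compression() -> CompressionSchedule:
    return CompressionSchedule(level=1.0)


def constant_channels(q1: float, q2: float, n: int = 2000, rate: float = 1000.0,
                      period_s: float = 1.0) -> PressureChannels:
    """Uniform-grid channels with both sites at q1 and chamber at q2."""
    t = np.arange(n) / rate
    return PressureChannels(
        t=t,
        q1_prox=np.full(n, float(q1)),
        q1_dist=np.full(n, float(q1)),
        q2=np.full(n, float(q2)),
        meta={"period_s": period_s},
    )
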