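import numpy as np
import pytest

from nephelofit.preprocess import CurveId, GrowthCurve
from nephelofit.synthetic_data import GroupSpec, PeakArtifact, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def make_logistic_curve(K, N0, r, dt=1 / 6, duration=180.0, construct="AtLHT1", bio=1):
    """Exact logistic trace as an analysis-ready curve (no noise, no preprocessing)."""
    t = np.arange(0.0, duration + 1e-9, dt)
    v = K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))
    return GrowthCurve(CurveId(construct, "citrulline", bio), t, v)


def quiet_config(groups=None, **kwargs):
    """Simulation config with noise and artifact off unless overridden."""
    if groups is None:
        groups = [GroupSpec("AtLHT1", K=1000.0, r=0.1, max_slope_time=60.0)]
    kwargs.setdefault("noise_sd", 0.0)
    kwargs.setdefault("peak_artifact", PeakArtifact(enabled=False))
    kwargs.setdefault("control_background", None)
    return SimulationConfig(groups=groups, **kwargs)
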