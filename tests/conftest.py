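import numpy as np
import pytest

from antrosim import Config, Scenario, TractGeometry, Motility


@pytest.fixture()
def config():
    return Config()


@pytest.fixture()
def motility(config):
    return Motility(TractGeometry(config.geometry), config.antral_wave,
                    config.duodenal_wave, config.gate)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160619)


@pytest.fixture()
def uniform_tube_config():
    """Uniform straight tube, no wall motion, no gravity, one wall region:
    the configuration in which the 1D solver must reduce to the well-mixed
    reactor."""
    cfg = Config()
    g = cfg.geometry
    g.antrum_radius = g.duodenum_radius = g.pylorus_radius = 0.01
    g.duodenum_taper = 1e-9
    g.antrum_gravity_cos = g.duodenum_gravity_cos = 0.0
    g.region_override = 2
    # keep the pyloric gate open for the whole comparison window, with the
    # pyloric lumen matching the uniform tube
    cfg.gate.period = 1000.0
    cfg.gate.open_duration = 999.0
    cfg.gate.phase = 0.0
    cfg.gate.open_radius = 0.01
    return cfg


@pytest.fixture()
def motionless_scenario():
    """Baseline physiology but with peristalsis switched off (F motor = 0)."""
    return Scenario(1, motor_functionality=0.0)
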