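import dataclasses
import warnings

import pytest

from penflow import config, synthetic


def noise_free(cfg: config.GeneratorConfig) -> config.GeneratorConfig:
    """Zero out every random component of both responses."""
    zero = dict(
        pen_sd=0.0, day_sd=0.0, resid_sd=0.0, rho=0.0,
        amp_pen_cv=0.0, amp_day_cv=0.0, phase_pen_sd=0.0,
    )
    cfg.water = dataclasses.replace(cfg.water, **zero)
    cfg.activations = dataclasses.replace(cfg.activations, **zero)
    return cfg


@pytest.fixture(scope="session")
def roster8():
    return synthetic.generate_pen_roster(1, 1, seed=11)


@pytest.fixture(scope="session")
def roster56():
    return synthetic.generate_pen_roster(7, 1, seed=12)


@pytest.fixture(scope="session")
def diurnal_run56():
    """One 56-pen, 63-day harmonic-mode simulation shared across tests."""
    roster = synthetic.generate_pen_roster(7, 1, seed=12)
    cfg = config.make_diurnal_config()
    hourly, truth = synthetic.simulate_pen_hourly(roster, cfg, seed=1234)
    return roster, cfg, hourly, truth


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        warnings.filterwarnings("ignore", message=".*convergence.*")
        yield
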