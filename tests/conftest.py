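"""Shared fixtures: model configuration, pump table, and cached simulations.

Simulations are session-scoped because each 30 s run, while fast, is the
dominant cost of the suite; tests must not mutate fixture results.
"""

import numpy as np
import pytest

from lvadest import (HeartFailureParams, PumpSetting, default_config,
                     default_pump_table, simulate)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def table():
    return default_pump_table()


@pytest.fixture(scope="session")
def hf_mid():
    """Mid-range heart failure (near the sampling-range centroids)."""
    return HeartFailureParams(1.58, 1.30, 0.338, 0.0125)


@pytest.fixture(scope="session")
def hf_severe():
    """Severe failure: every parameter at its range minimum."""
    return HeartFailureParams(0.200, 0.200, 0.200, 0.0110)


@pytest.fixture(scope="session")
def sim_mid_5000(hf_mid, cfg, table):
    return simulate(hf_mid, PumpSetting(5000.0), config=cfg, table=table)


@pytest.fixture(scope="session")
def sim_mid_5000_nopulse(hf_mid, cfg, table):
    return simulate(hf_mid, PumpSetting(5000.0, artificial_pulse=False),
                    config=cfg, table=table)


@pytest.fixture(scope="session")
def sim_severe_4000(hf_severe, cfg, table):
    """Severe failure at low speed: native ejection coexists with pump flow,
    producing the most feature-rich arterial waveform."""
    return simulate(hf_severe, PumpSetting(4000.0), config=cfg, table=table)


@pytest.fixture(scope="session")
def sim_severe_6000(hf_severe, cfg, table):
    """Severe failure at full speed: complete unloading, closed aortic valve."""
    return simulate(hf_severe, PumpSetting(6000.0), config=cfg, table=table)


@pytest.fixture(scope="session")
def sim_healthy_nopump(cfg, table):
    return simulate(cfg.healthy_hf(), PumpSetting.off(), config=cfg, table=table)
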