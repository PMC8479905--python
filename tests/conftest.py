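import dataclasses

import pytest

import ffrwire as fw


@pytest.fixture(scope="session")
def blood():
    return fw.CARREAU_HUMAN_BLOOD


@pytest.fixture(scope="session")
def newtonian_blood():
    return fw.BloodModel.newtonian()


@pytest.fixture(scope="session")
def scenarios():
    return fw.reference_scenarios()


@pytest.fixture(scope="session")
def moderate_case(scenarios):
    cfg = scenarios["moderate"]
    return fw.build_idealized_rca(cfg), fw.waveform_for(cfg), cfg


@pytest.fixture(scope="session")
def single_tube(scenarios):
    """Uniform healthy trunk discharging straight to the outlet."""
    geom = fw.build_idealized_rca(scenarios["healthy"])
    return dataclasses.replace(geom, branches=None)


@pytest.fixture(scope="session")
def constant_waveform():
    """Steady 10 kPa inlet (pulse amplitude zero)."""
    return fw.synth_waveform(mean_pressure=1.0e4, pulse_amplitude=0.0)
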