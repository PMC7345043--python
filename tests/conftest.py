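"""Shared fixtures: materials, the reference device, and session-scoped
solved fields / scenario runs reused across test modules."""

import numpy as np
import pytest

import depsep as ds
from depsep.metrics import Scenario


@pytest.fixture(scope="session")
def medium():
    return ds.Medium()  # eps_m=78.5, sigma_m=1e-4 S/m, water viscosity/density


@pytest.fixture(scope="session")
def p_small():
    return ds.Particle(2.5e-6, ds.POLYSTYRENE)


@pytest.fixture(scope="session")
def p_big():
    return ds.Particle(5e-6, ds.POLYSTYRENE)


@pytest.fixture(scope="session")
def n_cr_big(p_big, medium):
    """Operating frequency: the big particle's DEP crossover."""
    return ds.crossover_frequency(p_big, medium)


@pytest.fixture(scope="session")
def geo_ref():
    """Reference operating point: 100x100 um channel, l=120/d=30 um
    electrodes, 30 per side, 20/12.5 Vpp."""
    return ds.DeviceGeometry(100e-6, 100e-6, 120e-6, 30e-6, 30, 20.0, 12.5)


@pytest.fixture(scope="session")
def small_geo():
    """Small unit for fast field tests: 40x40 um channel, l=20/d=10 um."""
    return ds.DeviceGeometry(40e-6, 40e-6, 20e-6, 10e-6, 2, 10.0, 5.0)


@pytest.fixture(scope="session")
def field_ref(geo_ref):
    """Solved 5-um-grid DEP drive field of the reference unit."""
    grid = ds.build_repeating_unit(geo_ref, 5e-6)
    ds.solve_potential(grid)
    return ds.dep_force_field(grid)


@pytest.fixture(scope="session")
def scenario_ref(geo_ref, medium, p_small, p_big):
    return Scenario(
        geometry=geo_ref,
        medium=medium,
        particle_small=p_small,
        particle_big=p_big,
        flow_rate=ds.ul_per_h_to_m3_per_s(200),
        spacing=5e-6,
    )


@pytest.fixture(scope="session")
def field_cache():
    """Session-wide repeating-unit field cache shared by scenario runs."""
    return {}


@pytest.fixture(scope="session")
def result_ref(scenario_ref, field_cache):
    """Full 2x81-particle run at the reference operating point."""
    return ds.run_scenario(scenario_ref, field_cache)
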