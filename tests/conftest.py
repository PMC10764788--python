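"""Shared fixtures.

The expensive simulation ensembles (unbiased baselines, metadynamics
ensembles) are session-scoped so that statistical and acceptance tests can
share them instead of re-simulating.
"""

import numpy as np
import pytest

import resetmetad as rm
from resetmetad.experiments import run_ensemble
from resetmetad.fpt import ensemble_from_records


@pytest.fixture(scope="session")
def two_wells():
    return rm.make_potential("two_wells")


@pytest.fixture(scope="session")
def faradjian_elber():
    return rm.make_potential("faradjian_elber")


@pytest.fixture(scope="session")
def thermo():
    return rm.ThermoConfig()


@pytest.fixture(scope="session")
def tw_stop():
    return rm.StopCriterion.x_le(-3.0)


@pytest.fixture(scope="session")
def tw_baseline(two_wells, thermo, tw_stop):
    """Unbiased two-wells first-passage ensemble, 200 trajectories."""
    recs = run_ensemble(two_wells, thermo, tw_stop, (3.0, 0.0), 200, seed=12345)
    return ensemble_from_records(recs, dt_fs=thermo.dt)


@pytest.fixture(scope="session")
def tw_metad_fast(two_wells, thermo, tw_stop):
    """MetaD ensemble at the fastest published pace (hill every 100 steps)."""
    md = rm.MetaDConfig(pace=100, sigma=1.3)
    recs = run_ensemble(two_wells, thermo, tw_stop, (3.0, 0.0), 300, seed=777,
                        cv=rm.CVSpec(0.0), metad=md, max_steps=10 ** 8)
    return ensemble_from_records(recs, dt_fs=thermo.dt)


@pytest.fixture(scope="session")
def fe_baseline(faradjian_elber, thermo):
    """Unbiased Faradjian-Elber ensemble, 100 trajectories."""
    stop = rm.StopCriterion.x_lt(-1.0)
    recs = run_ensemble(faradjian_elber, thermo, stop, (3.0, 0.0), 100, seed=2024)
    return ensemble_from_records(recs, dt_fs=thermo.dt)
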