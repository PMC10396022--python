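"""Shared fixtures.

The expensive scenario runs (200 s of simulated time) are session scoped and
shared between the acceptance tests and the physics tests that inspect the
same trajectories.  Problem sizes: the convergence pair uses N=200 cells and
dt=1e-2 s as anchored by the refinement study; the steady-state scenario
runs use N=100 cells, where the headline quantities are within a fraction
of a percent of their converged values.
"""

import numpy as np
import pytest

from astroflow import ModelParameters
from astroflow.solver import RunConfig, run_simulation


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def convergence_run():
    """M1, constant stimulus, N=200, dt=1e-2, to t=20 s."""
    cfg = RunConfig(scenario="M1", N=200, dt=1.0e-2, t_end=20.0, output_dt=1.0)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def m1_steady():
    """M1, constant stimulus, N=100, dt=1e-2, to t=200 s."""
    cfg = RunConfig(scenario="M1", N=100, dt=1.0e-2, t_end=200.0, output_dt=1.0)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def m2_steady():
    cfg = RunConfig(scenario="M2", N=100, dt=1.0e-2, t_end=200.0, output_dt=1.0)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def m3_steady():
    cfg = RunConfig(scenario="M3", N=100, dt=1.0e-2, t_end=200.0, output_dt=1.0)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def short_m1():
    """Small, cheap M1 run that crosses the stimulus onset (to t=12 s)."""
    cfg = RunConfig(scenario="M1", N=25, dt=1.0e-2, t_end=12.0, output_dt=1.0)
    return run_simulation(cfg)


def total_moles(res, m):
    """Domain integrals of alpha_i c_i + alpha_e c_e per ion (mol/m^2)."""
    V = res.domain.volumes
    alpha_i = m[:, 0]
    alpha_e = res.params.total_cell_fraction - alpha_i
    out = {}
    for ion, (ci, ce) in (("Na", (1, 2)), ("K", (3, 4)), ("Cl", (5, 6))):
        out[ion] = float(V @ (alpha_i * m[:, ci] + alpha_e * m[:, ce]))
    return out
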