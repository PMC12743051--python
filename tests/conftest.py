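"""Shared fixtures: boundary conditions, spun states, and the nominal run.

Spin-ups and the full nominal perturbation run are expensive enough to
share at session scope; tests must not mutate them.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from redoxbox import BoundaryConditions, Scenario, run_scenario, spinup
from redoxbox.driver import solve_steady_state


@pytest.fixture(scope="session")
def bc() -> BoundaryConditions:
    """Nominal Paleoproterozoic boundary conditions (F_red = 0.075 Tmol/yr)."""
    return BoundaryConditions()


@pytest.fixture(scope="session")
def bc_high_fred(bc) -> BoundaryConditions:
    """Temporary-oxidation boundary conditions (F_red = 0.3 Tmol/yr)."""
    return dataclasses.replace(bc, F_red=0.3e12)


@pytest.fixture(scope="session")
def steady_vector(bc) -> np.ndarray:
    """Raw fixed-point state vector of the nominal spin-up."""
    return solve_steady_state(bc)


@pytest.fixture(scope="session")
def spun(bc):
    """Spun-up (state, ledger) pair under nominal boundary conditions."""
    return spinup(bc)


@pytest.fixture(scope="session")
def spun_high_fred(bc_high_fred):
    return spinup(bc_high_fred)


@pytest.fixture(scope="session")
def nominal_run(bc, spun):
    """Full 1e8-yr perturbation run at pCO2_init = 0.7 atm, F_red = 0.075."""
    return run_scenario(Scenario(pCO2_init=0.7, bc=bc), spun=spun)


@pytest.fixture(scope="session")
def high_fred_run(bc_high_fred, spun_high_fred):
    """Full 1e8-yr run at pCO2_init = 0.7 atm under F_red = 0.3 Tmol/yr."""
    return run_scenario(Scenario(pCO2_init=0.7, bc=bc_high_fred),
                        spun=spun_high_fred)
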