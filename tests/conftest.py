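"""Shared fixtures: published-style parameter sets and synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest

from specbind import QuenchTruth, UnfoldTruth, generate_quench, generate_unfolding

#: (temperature K, Ksv M^-1, Ka M^-1, n) for the three-temperature study.
BINDING_STUDY = (
    (293.0, 4.59e4, 6.85e4, 1.04),
    (298.0, 4.40e4, 6.02e4, 1.03),
    (303.0, 3.74e4, 5.58e4, 1.04),
)

#: Apo/complex three-state free energies (J/mol) by fit method.
STABILITY_DG = {
    "nonlinear": {"apo": (17190.0, 15230.0), "complex": (19090.0, 15320.0)},
    "linear_LEM": {"apo": (15720.0, 9990.0), "complex": (17470.0, 10300.0)},
}

#: m-values (J/mol/M) adopted for simulations; never published, chosen once.
SIM_M_VALUES = (3500.0, 2500.0)

QUENCH_GRID = np.linspace(0.0, 18e-6, 19)


@pytest.fixture
def quench_grid():
    return QUENCH_GRID.copy()


@pytest.fixture
def noiseless_sv_series(quench_grid):
    """Noiseless n=1 titration with the 3 uM-protein Ksv as the truth."""
    return generate_quench(QuenchTruth(ka_assoc_per_M=4.59e4, n_sites=1.0),
                           quench_grid, protein_conc_M=3e-6)


@pytest.fixture
def noiseless_binding_series(quench_grid):
    """Noiseless titration with the 298 K binding parameters as the truth."""
    return generate_quench(QuenchTruth(ka_assoc_per_M=6.02e4, n_sites=1.03),
                           quench_grid)


@pytest.fixture
def zoned_unfold_truth():
    """Three-state truth at the published free energies with adopted m-values."""
    m1, m2 = SIM_M_VALUES
    apo = STABILITY_DG["nonlinear"]["apo"]
    return UnfoldTruth(apo[0], m1, apo[1], m2)


@pytest.fixture
def zoned_profile(zoned_unfold_truth):
    return generate_unfolding(zoned_unfold_truth, composition="two_state_zones")
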