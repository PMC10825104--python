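"""Shared fixtures: the reference simulation and its joint MDIF fit.

The joint fit is expensive (multi-start nonlinear least squares over 28
parameters), so it runs once per session and is shared by the SIME unit
tests and the acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from mdifkit import SimeProblem, fit_sime_mdif, fit_standalone, make_weights

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from mdifkit.simulate import REFERENCE_REGIONS, reference_simulation


@pytest.fixture(scope="session")
def ref_sim():
    """(aif, region_tacs, wb_tac, anchors) of the noiseless reference study."""
    return reference_simulation()


@pytest.fixture(scope="session")
def mdif_sime_result(ref_sim):
    """Full joint MDIF fit of the reference study (8 LHS starts + midpoint)."""
    aif, regions, wb, anchors = ref_sim
    problem = SimeProblem(wb_tac=wb, region_tacs=regions, anchors=anchors, R=1.0, mode="mdif")
    return fit_sime_mdif(problem, n_starts=8, seed=0)


@pytest.fixture(scope="session")
def mdif_refits(ref_sim, mdif_sime_result):
    """Standalone weighted refits of the six region TACs using the recovered MDIF."""
    aif, regions, wb, anchors = ref_sim
    cp = mdif_sime_result.input_function
    weights = make_weights(wb.grid, wb)
    return {
        tac.label: fit_standalone(tac, cp, weights=weights, R=1.0) for tac in regions
    }


@pytest.fixture(scope="session")
def true_params():
    return dict(REFERENCE_REGIONS)
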