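"""Shared fixtures: representative circuit conditions and cached solutions.

Solver outputs that several tests inspect (a benign two-pathway fixed
point, the single-pathway optimum at a moderate noise mix) are solved once
per session.
"""

import numpy as np
import pytest

from effcode.dual import picard_solve
from effcode.model import CircuitParams, rho_up_for_effective
from effcode.single import solve_single


def params_for(rho_eff, kappa, sigma_down, rho_down, sigma_s=1.0, sigma_up=2.0):
    """Two-pathway params realising a requested rho_eff at (sigma_s, sigma_up)."""
    return CircuitParams(
        sigma_s=sigma_s,
        sigma_up=sigma_up,
        kappa=kappa,
        sigma_down=sigma_down,
        rho_up=rho_up_for_effective(rho_eff, sigma_s, sigma_up),
        rho_down=rho_down,
        n_pathways=2,
    )


@pytest.fixture(scope="session")
def benign_dual_params():
    return params_for(0.5, 0.25, 0.25, 0.0)


@pytest.fixture(scope="session")
def benign_on_off(benign_dual_params):
    sol = picard_solve(benign_dual_params, init_class="on_off", seed=1)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def benign_on_on(benign_dual_params):
    sol = picard_solve(benign_dual_params, init_class="on_on", seed=1)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def moderate_single():
    return solve_single(CircuitParams(sigma_up=0.5, kappa=0.25, sigma_down=0.25))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
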