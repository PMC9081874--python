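"""Shared fixtures: a small synthetic study and independent oracles."""

import numpy as np
import pytest

from wcdyn import (SimulationConfig, build_network, nominal_params,
                   synth_connectome, synth_densities, synth_target_fc)
from wcdyn.synth import FIXTURE_B_E, FIXTURE_G, FIXTURE_SIM, SynthSpec


@pytest.fixture(scope="session")
def spec12():
    return SynthSpec(N=12, seed=0)


@pytest.fixture(scope="session")
def connectome12(spec12):
    return synth_connectome(spec12)


@pytest.fixture(scope="session")
def densities12(spec12):
    return synth_densities(spec12)


@pytest.fixture(scope="session")
def lc_params():
    return nominal_params("limit_cycle")


@pytest.fixture(scope="session")
def model12(connectome12, lc_params):
    """Homogeneous limit-cycle model at the fixture working point."""
    return build_network(connectome12, lc_params.with_(B_e=FIXTURE_B_E),
                         FIXTURE_G)


@pytest.fixture(scope="session")
def short_cfg():
    """Fast integration config: 6 s total, 1 s transient."""
    return SimulationConfig(dt=0.1, T=6000.0, transient=1000.0, seed=0)


@pytest.fixture(scope="session")
def target_fc12(model12):
    """Target FC planted at the fixture working point, low observation noise."""
    return synth_target_fc(model12, FIXTURE_SIM, observation_noise_sd=0.02,
                           seed=500)


# ---------------------------------------------------------------------------
# independent equilibrium oracle: dense grid sign scan + local refinement
# ---------------------------------------------------------------------------

def grid_scan_equilibria(p, J_tot, n_grid=200, dedupe=1e-4):
    """All equilibria of one node found by brute force, independently of the
    package's root-finding path.

    Both drift components are evaluated on an (n_grid x n_grid) lattice over
    [0, 1]^2; every cell whose corners show a sign change in dE/dt AND in
    dI/dt brackets a nullcline intersection, which is polished with a 2-d
    Newton iteration from the cell centre.  Nearby solutions are merged.
    """
    from scipy.optimize import fsolve

    from wcdyn import drift

    E = np.linspace(0.0, 1.0, n_grid)
    I = np.linspace(0.0, 1.0, n_grid)
    EE, II = np.meshgrid(E, I, indexing="ij")
    dE, dI = drift(EE, II, p, J_e=J_tot + p.B_e)

    def cell_has_change(F):
        c = np.stack([F[:-1, :-1], F[1:, :-1], F[:-1, 1:], F[1:, 1:]])
        return (c.min(axis=0) <= 0) & (c.max(axis=0) >= 0)

    # dilate each mask by one cell: an intersection can sit in a cell whose
    # corners miss one sign change when the nullclines cross obliquely; the
    # Newton polish plus residual check discards any spurious candidate
    from scipy.ndimage import binary_dilation

    cells = (binary_dilation(cell_has_change(dE))
             & binary_dilation(cell_has_change(dI)))
    roots = []
    for i, j in zip(*np.nonzero(cells)):
        x0 = (0.5 * (E[i] + E[i + 1]), 0.5 * (I[j] + I[j + 1]))
        sol, info, ok, _ = fsolve(
            lambda x: drift(x[0], x[1], p, J_e=J_tot + p.B_e),
            x0, full_output=True, xtol=1e-13)
        if ok != 1 or np.max(np.abs(info["fvec"])) > 1e-10:
            continue
        if not (-1e-9 <= sol[0] <= 1 + 1e-9 and -1e-9 <= sol[1] <= 1 + 1e-9):
            continue
        if not any(abs(sol[0] - r[0]) < dedupe and abs(sol[1] - r[1]) < dedupe
                   for r in roots):
            roots.append((float(sol[0]), float(sol[1])))
    roots.sort()
    return roots
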