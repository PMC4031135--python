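import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cryopif as cp

settings.register_profile(
    "default", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def ground_truth():
    return cp.default_ground_truth(seed=0)


@pytest.fixture(scope="session")
def cell(ground_truth):
    return ground_truth.cell


@pytest.fixture(scope="session")
def traj60(cell):
    """Dense dehydration trajectory at 60 K/min down to -50 C."""
    return cp.integrate_water_transport(
        cp.CoolingProtocol(B=60.0, T_end=223.15), cell)


@pytest.fixture(scope="session")
def traj60_deep(cell):
    """Trajectory at 60 K/min down to -100 C (extrapolation range)."""
    return cp.integrate_water_transport(
        cp.CoolingProtocol(B=60.0, T_end=173.15), cell)


def riemann_pif_oracle(traj, params, n_sub=100_000, fv=cp.FREE_VOLUME,
                       constants=cp.CONSTANTS):
    """Independent midpoint-Riemann quadrature of the mechanism hazard.

    Interpolates the trajectory state linearly onto a fine grid, evaluates
    the (gated) nucleation rate pointwise, and accumulates the hazard with
    a left-to-right midpoint sum — sharing no quadrature code with
    pif_mechanism.
    """
    from cryopif.nucleation import (SECONDS_PER_MINUTE, UM2_TO_M2, UM3_TO_M3,
                                    isotonic_reference, modified_nucleation_rate)

    Tf0, eta_ref = isotonic_reference(traj, fv, constants)
    T_rev = traj.T[::-1]
    edges = np.linspace(traj.T[0], traj.T[-1], n_sub + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    V = np.interp(mid, T_rev, traj.V[::-1])
    A = np.interp(mid, T_rev, traj.A[::-1])
    Tf = np.interp(mid, T_rev, traj.Tf[::-1])
    eta = np.interp(mid, T_rev, traj.eta[::-1])
    rate = modified_nucleation_rate(mid, V, Tf, eta, params, Tf0, eta_ref)
    S = A * UM2_TO_M2 if params.mechanism == "SCN" else V * UM3_TO_M3
    h = rate * S * SECONDS_PER_MINUTE / traj.protocol.B
    dT = edges[:-1] - edges[1:]
    H_mid = np.cumsum(h * dT)
    H = np.interp(traj.T[::-1], mid[::-1], H_mid[::-1])[::-1]
    H[0] = 0.0
    return 1.0 - np.exp(-H)


def euler_trajectory_terminal(protocol, cell, dT=1e-3, constants=cp.CONSTANTS):
    """Fixed-step explicit Euler integration of the dehydration ODE.

    Deliberately naive and independent of scipy's solvers; used as the
    integration oracle.
    """
    import math

    V = cell.V0
    T = protocol.T_start
    dHf_R = constants.dHf / constants.R_kcal
    ELp_R = cell.ELp / constants.R_kcal
    c_geom = (36.0 * math.pi) ** (1.0 / 3.0)
    while T > protocol.T_end:
        step = min(dT, T - protocol.T_end)
        x = (V - cell.Vb) / constants.vw
        x = x / (x + cell.phi_diss * cell.ns)
        A = c_geom * V ** (2.0 / 3.0)
        Lp = cell.Lpg * math.exp(-ELp_R * (1.0 / T - 1.0 / constants.T_R))
        dv = (Lp * A * constants.R_pv * T) / (protocol.B * constants.vw) \
            * (math.log(x) - dHf_R * (1.0 / constants.T_R - 1.0 / T))
        V -= dv * step
        T -= step
    return V
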