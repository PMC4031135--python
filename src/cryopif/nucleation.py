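"""Intracellular ice nucleation rates and probability-of-ice-formation curves.

Two catalytic mechanisms drive ice nucleation inside a freezing cell:
surface-catalyzed nucleation (SCN) at the plasma membrane, whose hazard
scales with membrane area, and volume-catalyzed nucleation (VCN) in the
cytoplasmic bulk, whose hazard scales with cell volume.  Each mechanism's
rate follows a heterogeneous-nucleation law

    I(T) = Ω₀ · (η_ref/η(T)) · exp[ −κ₀ · (T_f/T_f0)⁴ / ((T_f − T)² · T³) ]

with a kinetic prefactor Ω₀ (per m² per s for SCN, per m³ per s for VCN),
a thermodynamic barrier parameter κ₀ (K⁵), the composition-dependent
cytosol freezing point T_f, and the cytoplasm viscosity η.  η_ref and
T_f0 are the isotonic-composition values, so Ω₀ is the rate scale under
isotonic conditions.  The rate vanishes for T ≥ T_f (no supercooling) and
is suppressed again at deep supercooling where η diverges toward the
glass transition.

The critical-volume modification gates each mechanism on cell volume:
below a mechanism-specific critical volume V_f the rate is identically
zero.  Because dehydration is monotone along cooling, each gate closes
once and the cumulative ice-formation probability then plateaus — at a
value that may be well below 1, which the ungated model cannot produce.

The probability that a cell has formed ice by temperature T during a ramp
at rate B is one minus the survival of an inhomogeneous Poisson hazard:

    PIF(T) = 1 − exp[ −(1/B) ∫_T^{T_start} I(T′)·S(T′) dT′ ]

with S the membrane area (SCN) or cell volume (VCN) taken from the
dehydration trajectory.  SCN and VCN compete independently, so
PIF_total = 1 − (1 − PIF_SCN)(1 − PIF_VCN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import physics
from .constants import CONSTANTS, FREE_VOLUME, FreeVolumeParams, PhysicalConstants
from .errors import DomainError
from .transport import Trajectory

__all__ = ["NucleationParams", "PIFCurve", "nucleation_rate",
           "modified_nucleation_rate", "pif_mechanism", "pif_total",
           "compute_pif_curve", "isotonic_reference"]

#: m² per μm²
UM2_TO_M2 = 1.0e-12
#: m³ per μm³
UM3_TO_M3 = 1.0e-18
SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class NucleationParams:
    """Kinetic and thermodynamic parameters of one nucleation mechanism.

    ``Omega0`` is per m²·s for SCN and per m³·s for VCN; ``kappa0`` is in
    K⁵.  ``Vf`` (μm³) is the optional critical volume: absent means the
    original ungated rate law.
    """

    mechanism: Literal["SCN", "VCN"]
    Omega0: float
    kappa0: float
    Vf: float | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("SCN", "VCN"):
            raise DomainError("mechanism must be 'SCN' or 'VCN'")
        if self.Omega0 < 0:
            raise DomainError("Omega0 must be non-negative")
        if self.kappa0 <= 0:
            raise DomainError("kappa0 must be strictly positive")
        if self.Vf is not None and self.Vf <= 0:
            raise DomainError("critical volume Vf must be strictly positive")


@dataclass
class PIFCurve:
    """Cumulative ice-formation probabilities along a cooling trajectory."""

    T: np.ndarray
    pif_scn: np.ndarray
    pif_vcn: np.ndarray
    pif_total: np.ndarray
    trajectory: Trajectory


def isotonic_reference(traj: Trajectory, fv: FreeVolumeParams = FREE_VOLUME,
                       constants: PhysicalConstants = CONSTANTS) -> tuple[float, float]:
    """Isotonic freezing point T_f0 (K) and isotonic cytoplasm viscosity
    η_ref (mPa·s) for the trajectory's cell — the '0' reference state of
    the nucleation rate law."""
    cell = traj.cell
    Tf0 = physics.equilibrium_freezing_temperature(
        physics.water_mole_fraction(cell.V0, cell, constants), constants)
    eta_ref = physics.cytoplasm_viscosity(
        Tf0, physics.salt_volume_fraction(cell.V0, cell), fv, constants)
    return float(Tf0), float(eta_ref)


def nucleation_rate(T, Tf, eta, params: NucleationParams, Tf0: float,
                    eta_ref: float):
    """Ungated nucleation rate at temperature T (per m²·s or per m³·s).

    Zero whenever the cytosol is not supercooled (T ≥ T_f).
    """
    T = np.asarray(T, dtype=float)
    Tf = np.asarray(Tf, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(T <= 0):
        raise DomainError("absolute temperature must be strictly positive")
    if np.any(eta <= 0):
        raise DomainError("viscosity must be strictly positive")
    dT = Tf - T
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        barrier = params.kappa0 * (Tf / Tf0) ** 4 / (dT ** 2 * T ** 3)
        rate = params.Omega0 * (eta_ref / eta) * np.exp(-barrier)
    rate = np.where(dT > 0, rate, 0.0)
    return rate if rate.ndim else float(rate)


def modified_nucleation_rate(T, V, Tf, eta, params: NucleationParams,
                             Tf0: float, eta_ref: float):
    """Critical-volume-gated nucleation rate.

    Equals :func:`nucleation_rate` while the cell volume is at or above
    the critical volume ``params.Vf`` (boundary inclusive) and is exactly
    zero below it.  Without a critical volume the gate is always open.
    """
    rate = nucleation_rate(T, Tf, eta, params, Tf0, eta_ref)
    if params.Vf is None:
        return rate
    gate = np.asarray(V, dtype=float) >= params.Vf
    gated = np.where(gate, rate, 0.0)
    return gated if gated.ndim else float(gated)


def _mechanism_rate(traj: Trajectory, params: NucleationParams,
                    Tf0: float, eta_ref: float) -> np.ndarray:
    return np.asarray(modified_nucleation_rate(
        traj.T, traj.V, traj.Tf, traj.eta, params, Tf0, eta_ref))


def hazard_density(traj: Trajectory, params: NucleationParams,
                   fv: FreeVolumeParams = FREE_VOLUME,
                   constants: PhysicalConstants = CONSTANTS,
                   prefactor_mode: str = "off",
                   vcn_water_volume: bool = False) -> np.ndarray:
    """Per-kelvin hazard ``I(T)·S(T)/B`` on the trajectory grid.

    The single site of unit conversion: area μm²→m², volume μm³→m³,
    rate s⁻¹→min⁻¹ against B in K·min⁻¹.

    ``prefactor_mode='dehydration'`` multiplies the rate by the relative
    number of available water molecules (A/A0 for SCN, (V−Vb)/(V0−Vb) for
    VCN); the default leaves the dehydration dependence entirely to S(T)
    and η(T).  ``vcn_water_volume`` substitutes the osmotically active
    water volume for the total cell volume in the VCN hazard.
    """
    if prefactor_mode not in ("off", "dehydration"):
        raise ValueError(f"unknown prefactor_mode {prefactor_mode!r}")
    Tf0, eta_ref = isotonic_reference(traj, fv, constants)
    rate = _mechanism_rate(traj, params, Tf0, eta_ref)
    cell = traj.cell
    if params.mechanism == "SCN":
        S = traj.A * UM2_TO_M2
        if prefactor_mode == "dehydration":
            A0, _ = physics.sphere_geometry(cell.V0)
            rate = rate * (traj.A / A0)
    else:
        base = (traj.V - cell.Vb) if vcn_water_volume else traj.V
        S = base * UM3_TO_M3
        if prefactor_mode == "dehydration":
            rate = rate * ((traj.V - cell.Vb) / (cell.V0 - cell.Vb))
    return rate * S * SECONDS_PER_MINUTE / traj.protocol.B


def pif_mechanism(traj: Trajectory, params: NucleationParams,
                  fv: FreeVolumeParams = FREE_VOLUME,
                  constants: PhysicalConstants = CONSTANTS,
                  prefactor_mode: str = "off",
                  vcn_water_volume: bool = False) -> np.ndarray:
    """Cumulative ice-formation probability for one mechanism on traj.T.

    Cumulative trapezoidal quadrature of the per-kelvin hazard from
    T_start down; PIF(T_start) = 0, non-decreasing along cooling, in
    [0, 1].

    With a critical volume the cumulative hazard is truncated at the
    gate-closing temperature, located by interpolating the monotone
    volume trajectory; this keeps PIF continuous in V_f (important for
    gradient-based fitting) instead of snapping to grid nodes.
    """
    from dataclasses import replace as _replace

    ungated = params if params.Vf is None else _replace(params, Vf=None)
    h = hazard_density(traj, ungated, fv, constants, prefactor_mode,
                       vcn_water_volume)
    # traj.T is decreasing, so the signed cumtrapz is negative; negate.
    H = -cumulative_trapezoid(h, traj.T, initial=0.0)
    if params.Vf is not None:
        V = traj.V
        if params.Vf > V[0]:
            # gate closed from the start (boundary V = Vf inclusive)
            H = np.zeros_like(H)
        elif params.Vf > V[-1]:
            k = int(np.argmax(V < params.Vf))
            dv = V[k - 1] - V[k]
            frac = (V[k - 1] - params.Vf) / dv if dv > 0 else 1.0
            H_star = H[k - 1] + frac * (H[k] - H[k - 1])
            H = np.minimum(H, H_star)
    return -np.expm1(-H)


def pif_total(pif_scn, pif_vcn):
    """Combined ice-formation probability of two independently competing
    mechanisms: ``1 − (1 − PIF_SCN)(1 − PIF_VCN)``."""
    p1 = np.asarray(pif_scn, dtype=float)
    p2 = np.asarray(pif_vcn, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("mechanism PIF arrays must share one grid")
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise DomainError("PIF values must lie in [0, 1]")
    tot = p1 + (1.0 - p1) * p2
    return tot if tot.ndim else float(tot)


def compute_pif_curve(traj: Trajectory, scn: NucleationParams,
                      vcn: NucleationParams,
                      fv: FreeVolumeParams = FREE_VOLUME,
                      constants: PhysicalConstants = CONSTANTS,
                      prefactor_mode: str = "off",
                      vcn_water_volume: bool = False) -> PIFCurve:
    """SCN, VCN, and combined PIF curves along a dehydration trajectory."""
    if scn.mechanism != "SCN" or vcn.mechanism != "VCN":
        raise ValueError("expected (SCN, VCN) parameter pair in that order")
    p_s = pif_mechanism(traj, scn, fv, constants, prefactor_mode, vcn_water_volume)
    p_v = pif_mechanism(traj, vcn, fv, constants, prefactor_mode, vcn_water_volume)
    return PIFCurve(T=traj.T, pif_scn=p_s, pif_vcn=p_v,
                    pif_total=np.asarray(pif_total(p_s, p_v)), trajectory=traj)
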