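"""Solution thermodynamics, viscosity, and membrane permeability laws.

These are the scalar physical relations shared by the dehydration ODE and
the ice-nucleation model:

* water mole fraction of the cytosol as a function of cell volume,
* the equilibrium freezing temperature of the cytosol (ideal dilute
  solution, temperature-independent heat of fusion),
* water and cytoplasm viscosity from a free-volume model diverging toward
  the glass transition,
* Arrhenius temperature dependence of the membrane hydraulic permeability,
* spherical cell geometry.

All functions accept scalars or numpy arrays and operate in the internal
unit system of :mod:`cryopif.constants`.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .constants import CONSTANTS, FREE_VOLUME, CellParams, FreeVolumeParams, PhysicalConstants
from .errors import DomainError

__all__ = [
    "water_mole_fraction",
    "isotonic_salt_content",
    "equilibrium_freezing_temperature",
    "water_viscosity",
    "cytoplasm_viscosity",
    "salt_volume_fraction",
    "krieger_dougherty",
    "water_permeability",
    "sphere_geometry",
]


def water_mole_fraction(V, cell: CellParams,
                        constants: PhysicalConstants = CONSTANTS):
    """Mole fraction of water in the cytosol at cell volume ``V`` (μm³).

    The osmotically active water is ``(V − Vb)/vw`` mol; dissolved salt
    contributes ``phi_diss·ns`` osmotically active moles.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V <= cell.Vb):
        raise DomainError("cell volume must exceed the osmotically inactive volume Vb")
    moles_w = (V - cell.Vb) / constants.vw
    x = moles_w / (moles_w + cell.phi_diss * cell.ns)
    return x if x.ndim else float(x)


def equilibrium_freezing_temperature(x_w, constants: PhysicalConstants = CONSTANTS):
    """Equilibrium freezing temperature (K) of a solution with water mole
    fraction ``x_w``.

    Solves ``ln x_w = (dHf/R)·(1/T_R − 1/T_f)`` for ``T_f``; pure water
    (``x_w = 1``) freezes at T_R = 273.15 K and T_f decreases
    monotonically with solute load.
    """
    x_w = np.asarray(x_w, dtype=float)
    if np.any(x_w <= 0) or np.any(x_w > 1):
        raise DomainError("water mole fraction must lie in (0, 1]")
    Tf = 1.0 / (1.0 / constants.T_R - (constants.R_kcal / constants.dHf) * np.log(x_w))
    return Tf if Tf.ndim else float(Tf)


def isotonic_salt_content(V0: float, Vb: float, T0: float,
                          phi_diss: float = 2.0,
                          constants: PhysicalConstants = CONSTANTS) -> float:
    """Molar salt content (mol) consistent with an isotonic freezing point.

    The salt amount is never measured directly; it is pinned by requiring
    the cytosol at the isotonic volume ``V0`` to freeze at ``T0``
    (−0.5 °C for physiological saline).  Inverting the freezing-point
    relation is exact:

    ``x_w0 = exp[(dHf/R)(1/T_R − 1/T0)]``,
    ``ns = (V0 − Vb)/vw · (1 − x_w0)/(phi_diss · x_w0)``.
    """
    if not T0 < constants.T_R:
        raise DomainError("isotonic freezing point must be below 273.15 K")
    if not 0 < Vb < V0:
        raise DomainError("require 0 < Vb < V0")
    ln_xw0 = (constants.dHf / constants.R_kcal) * (1.0 / constants.T_R - 1.0 / T0)
    x_w0 = math.exp(ln_xw0)
    moles_w = (V0 - Vb) / constants.vw
    return moles_w * (1.0 - x_w0) / (phi_diss * x_w0)


def water_viscosity(T, fv: FreeVolumeParams = FREE_VOLUME,
                    constants: PhysicalConstants = CONSTANTS):
    """Viscosity of (supercooled) water in mPa·s from the free-volume model.

    ``η_w = η_w0 · exp[ Vhat_w / (K11/λ · (K21 + T − T_gw)) ]``

    The free volume vanishes as ``T → T_gw − K21`` from above and the
    viscosity diverges; temperatures at or below that limit are outside
    the model's domain.
    """
    T = np.asarray(T, dtype=float)
    free = fv.K21 + T - constants.T_gw
    if np.any(free <= 0):
        raise DomainError("free volume non-positive: temperature too close to the glass transition")
    with np.errstate(over="ignore"):
        # inf is the correct limit approaching the glass transition
        eta = fv.eta_w0 * np.exp(fv.Vhat_w / (fv.K11_over_lambda * free))
    return eta if eta.ndim else float(eta)


def krieger_dougherty(phi, phi_max: float = 0.64, intrinsic: float = 2.5):
    """Crowding correction ``g(φ) = (1 − φ/φ_max)^(−[η]·φ_max)``.

    Relative viscosity of a suspension/solution at solute volume fraction
    φ; g(0) = 1, strictly increasing, diverging at the packing limit.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi >= phi_max):
        raise DomainError(f"solute volume fraction must lie in [0, {phi_max})")
    g = (1.0 - phi / phi_max) ** (-intrinsic * phi_max)
    return g if g.ndim else float(g)


def salt_volume_fraction(V, cell: CellParams):
    """Volume fraction of salts in the cell, ``φ = ns·vs/V`` (dimensionless)."""
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise DomainError("cell volume must be strictly positive")
    phi = cell.ns * cell.vs / V
    return phi if phi.ndim else float(phi)


def cytoplasm_viscosity(T, phi_salt_vol, fv: FreeVolumeParams = FREE_VOLUME,
                        constants: PhysicalConstants = CONSTANTS,
                        crowding: Callable | None = None):
    """Cytoplasm viscosity in mPa·s: pure-water free-volume viscosity times
    a composition-dependent crowding factor.

    ``crowding`` is a pluggable strategy g(φ) with g(0) = 1; the default
    is :func:`krieger_dougherty` with φ_max = 0.64, [η] = 2.5.
    """
    g = (crowding or krieger_dougherty)(phi_salt_vol)
    eta = water_viscosity(T, fv, constants) * g
    return eta if np.ndim(eta) else float(eta)


def water_permeability(T, cell: CellParams,
                       constants: PhysicalConstants = CONSTANTS):
    """Membrane hydraulic permeability L_p (μm·min⁻¹·atm⁻¹) at temperature T.

    Arrhenius law anchored at the reference temperature:
    ``L_p = Lpg · exp[−(ELp/R)·(1/T − 1/T_R)]``, so ``L_p(T_R) = Lpg``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("absolute temperature must be strictly positive")
    Lp = cell.Lpg * np.exp(-(cell.ELp / constants.R_kcal) * (1.0 / T - 1.0 / constants.T_R))
    return Lp if Lp.ndim else float(Lp)


def sphere_geometry(V):
    """Surface area (μm²) and radius (μm) of a sphere of volume ``V`` μm³."""
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise DomainError("volume must be strictly positive")
    r = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
    A = 4.0 * math.pi * r ** 2
    if V.ndim:
        return A, r
    return float(A), float(r)
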