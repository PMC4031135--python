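"""Physical constants and parameter containers.

Internal unit system
--------------------
Length in μm, volume in μm³, time in minutes, pressure in atm, temperature
in K, molar energies in kcal·mol⁻¹.  This matches the units in which
membrane permeability (μm·min⁻¹·atm⁻¹), activation energy (kcal·mol⁻¹) and
cooling rate (K·min⁻¹ ≡ °C·min⁻¹) are conventionally reported for cell
freezing experiments.  Unit conversions to SI happen only at two places:
the config boundary and the hazard quadrature (μm²→m², μm³→m³, min→s).

The gas constant is kept in two unit views: a pressure–volume view for the
osmotic driving term of the dehydration ODE and a thermal view for
Arrhenius factors and the freezing-point relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import DomainError

#: μm³ per litre
LITER_TO_UM3 = 1.0e15
#: μm³ per cm³
CM3_TO_UM3 = 1.0e12
#: conversion °C -> K offset
CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET


@dataclass(frozen=True)
class PhysicalConstants:
    """Universal constants used by the freezing model.

    Attributes
    ----------
    R_Latm : gas constant, L·atm·mol⁻¹·K⁻¹ (pressure–volume view).
    R_kcal : gas constant, kcal·mol⁻¹·K⁻¹ (thermal view).
    dHf : molar heat of fusion of water, kcal·mol⁻¹ (temperature independent).
    vw : partial molar volume of water, μm³·mol⁻¹ (18.02 cm³·mol⁻¹).
    T_R : reference temperature, 273.15 K exactly.
    T_gw : glass-transition temperature of water, K.
    """

    R_Latm: float = 0.082057366
    R_kcal: float = 1.987204e-3
    dHf: float = 1.436
    vw: float = 18.02 * CM3_TO_UM3
    T_R: float = 273.15
    T_gw: float = 136.0

    def __post_init__(self) -> None:
        for name in ("R_Latm", "R_kcal", "dHf", "vw", "T_R", "T_gw"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.T_R != 273.15:
            raise DomainError("T_R must be 273.15 K exactly")

    @property
    def R_pv(self) -> float:
        """Gas constant in μm³·atm·mol⁻¹·K⁻¹ (for the ODE pressure term)."""
        return self.R_Latm * LITER_TO_UM3


#: module-level default constants set
CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class CellParams:
    """Membrane and osmotic parameters of one cell type.

    Attributes
    ----------
    V0 : isotonic cell volume, μm³.
    Vb : osmotically inactive volume, μm³ (solids and bound water).
    Lpg : membrane hydraulic permeability at T_R, μm·min⁻¹·atm⁻¹.
    ELp : activation energy of water transport, kcal·mol⁻¹.
    phi_diss : salt dissociation constant (dimensionless; 2 for NaCl-like).
    ns : molar amount of intracellular salt, mol.
    vs : partial molar volume of salt, μm³·mol⁻¹ (only enters the salt
        volume fraction of the viscosity law).
    """

    V0: float
    Vb: float
    Lpg: float
    ELp: float
    ns: float
    phi_diss: float = 2.0
    vs: float = 16.6 * CM3_TO_UM3

    def __post_init__(self) -> None:
        if not (0 < self.Vb < self.V0):
            raise DomainError("require 0 < Vb < V0")
        if self.Lpg < 0:
            raise DomainError("Lpg must be non-negative")
        if self.ELp <= 0:
            raise DomainError("ELp must be strictly positive")
        if self.ns <= 0:
            raise DomainError("ns must be strictly positive")
        if self.phi_diss <= 0 or self.vs <= 0:
            raise DomainError("phi_diss and vs must be strictly positive")

    def replace(self, **kw) -> "CellParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class FreeVolumeParams:
    """Free-volume (Vrentas–Duda type) viscosity parameters for water.

    The default set uses the literature water free-volume parameters
    (Vhat_w = 1.071 cm³·g⁻¹, K11/λ = 2.18·10⁻³ cm³·g⁻¹·K⁻¹,
    K21 − T_gw = −152.29 K) with the pre-exponential constant anchored so
    that the curve reproduces ≈1.00 mPa·s at 20 °C.

    Attributes
    ----------
    eta_w0 : pre-exponential viscosity constant, mPa·s.
    Vhat_w : specific volume of water at 0 K, cm³·g⁻¹.
    K11_over_lambda : free-volume parameter, cm³·g⁻¹·K⁻¹.
    K21 : free-volume parameter, K (may be negative; only K21 − T_gw
        enters the exponent).
    """

    eta_w0: float = 0.0306
    Vhat_w: float = 1.071
    K11_over_lambda: float = 2.18e-3
    K21: float = -16.29

    def __post_init__(self) -> None:
        if self.eta_w0 <= 0:
            raise DomainError("eta_w0 must be strictly positive")
        if self.K11_over_lambda <= 0:
            raise DomainError("K11_over_lambda must be strictly positive")
        if self.Vhat_w <= 0:
            raise DomainError("Vhat_w must be strictly positive")


#: module-level default free-volume parameter set
FREE_VOLUME = FreeVolumeParams()
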