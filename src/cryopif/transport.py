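"""Forward simulation of cell dehydration during linear cooling.

During freezing of a cell suspension, extracellular ice concentrates the
external solution and water leaves the cell osmotically.  With temperature
as the independent variable (linear ramp at cooling rate B), the cell
volume obeys the classical two-parameter water-transport ODE

    dV/dT = (L_p(T) · A(V) · R · T) / (B · v_w)
            · [ ln x_w(V) − (ΔH_f/R) · (1/T_R − 1/T) ],

whose fixed point at each temperature is the equilibrium volume — the
volume at which the cytosol's freezing point equals the current
temperature.  The permeability L_p collapses with an Arrhenius law as T
falls, so fast ramps trap water inside the cell.

The sign convention follows cooling: the bracket is positive whenever the
cell holds more water than its equilibrium share, and integrating toward
lower temperature then shrinks the cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import physics
from .constants import CONSTANTS, FREE_VOLUME, CellParams, FreeVolumeParams, PhysicalConstants
from .errors import DomainError, IntegrationError

__all__ = ["CoolingProtocol", "Trajectory", "dV_dT", "equilibrium_volume",
           "integrate_water_transport"]


@dataclass(frozen=True)
class CoolingProtocol:
    """Linear cooling ramp: from ``T_start`` to ``T_end`` at rate ``B``.

    Temperatures in K; B in K·min⁻¹ (positive, magnitude of the ramp).
    The default start is −0.5 °C, the isotonic freezing point at which
    cells are equilibrated after ice seeding.
    """

    B: float
    T_start: float = 272.65
    T_end: float = 223.15

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise DomainError("cooling rate B must be strictly positive")
        if not self.T_end < self.T_start:
            raise DomainError("T_end must be below T_start")

    def grid(self, step: float = 0.05) -> np.ndarray:
        """Strictly decreasing temperature grid including both endpoints."""
        n = int(math.ceil((self.T_start - self.T_end) / step))
        g = self.T_start - step * np.arange(n + 1)
        g[-1] = max(g[-1], self.T_end)
        if g[-1] > self.T_end + 1e-12:
            g = np.append(g, self.T_end)
        return g


@dataclass
class Trajectory:
    """Temperature-indexed record of the cell state along a cooling ramp.

    Arrays are aligned with the strictly decreasing temperature grid ``T``:
    volume ``V`` (μm³), surface area ``A`` (μm²), cytosol equilibrium
    freezing temperature ``Tf`` (K), cytoplasm viscosity ``eta`` (mPa·s),
    and membrane permeability ``Lp`` (μm·min⁻¹·atm⁻¹).
    """

    T: np.ndarray
    V: np.ndarray
    A: np.ndarray
    Tf: np.ndarray
    eta: np.ndarray
    Lp: np.ndarray
    protocol: CoolingProtocol
    cell: CellParams

    @property
    def norm_volume(self) -> np.ndarray:
        """Volume normalized to the equilibrated volume at T_start."""
        return self.V / self.V[0]

    def interp_volume(self, T) -> np.ndarray:
        """Linear interpolation of V at temperatures ``T`` (any order)."""
        return np.interp(np.asarray(T, float), self.T[::-1], self.V[::-1])

    def interp_norm_volume(self, T) -> np.ndarray:
        return self.interp_volume(T) / self.V[0]


def dV_dT(T: float, V: float, cell: CellParams, B: float,
          constants: PhysicalConstants = CONSTANTS) -> float:
    """Right-hand side of the dehydration ODE, μm³·K⁻¹.

    Zero exactly at the equilibrium volume; positive (volume decreasing
    along cooling) when the cell is supra-equilibrium.
    """
    if V <= cell.Vb:
        raise DomainError("cell volume must exceed Vb")
    if T <= 0:
        raise DomainError("absolute temperature must be strictly positive")
    x_w = physics.water_mole_fraction(V, cell, constants)
    A, _ = physics.sphere_geometry(V)
    Lp = physics.water_permeability(T, cell, constants)
    bracket = math.log(x_w) - (constants.dHf / constants.R_kcal) * (1.0 / constants.T_R - 1.0 / T)
    return (Lp * A * constants.R_pv * T) / (B * constants.vw) * bracket


def equilibrium_volume(T, cell: CellParams,
                       constants: PhysicalConstants = CONSTANTS):
    """Cell volume (μm³) whose cytosol freezes exactly at temperature T.

    The freezing-point relation is inverted in closed form: the target
    water mole fraction is ``x = exp[(ΔH_f/R)(1/T_R − 1/T)]`` and
    ``V = Vb + v_w·φ_diss·ns·x/(1−x)``.  Defined for temperatures at or
    below the cell's isotonic freezing point (where it returns V0).
    """
    T = np.asarray(T, dtype=float)
    T_iso = physics.equilibrium_freezing_temperature(
        physics.water_mole_fraction(cell.V0, cell, constants), constants)
    if np.any(T > T_iso + 1e-9):
        raise DomainError("temperature above the isotonic freezing point")
    x = np.exp((constants.dHf / constants.R_kcal) * (1.0 / constants.T_R - 1.0 / T))
    V = cell.Vb + constants.vw * cell.phi_diss * cell.ns * x / (1.0 - x)
    return V if V.ndim else float(V)


def integrate_water_transport(protocol: CoolingProtocol, cell: CellParams,
                              constants: PhysicalConstants = CONSTANTS,
                              fv: FreeVolumeParams = FREE_VOLUME,
                              grid_step: float = 0.05,
                              t_eval: np.ndarray | None = None,
                              rtol: float = 1e-8, atol: float = 1e-10,
                              area_mode: str = "sphere_dynamic") -> Trajectory:
    """Integrate the dehydration ODE along a linear cooling ramp.

    Starts from the isotonic volume V0 at ``protocol.T_start`` (the cell
    is equilibrated at the isotonic freezing point before the ramp) and
    returns a dense :class:`Trajectory` on a uniform grid (default 0.05 K),
    with area, cytosol freezing point, viscosity, and permeability filled
    in at every node.

    Parameters
    ----------
    t_eval : optional explicit (strictly decreasing) output temperatures;
        overrides the uniform grid.  Useful when only observation
        temperatures are needed, e.g. inside a fitting loop.
    area_mode : ``"sphere_dynamic"`` recomputes the exchange area from the
        instantaneous volume; ``"constant"`` freezes it at A(V0).
    """
    if area_mode not in ("sphere_dynamic", "constant"):
        raise ValueError(f"unknown area_mode {area_mode!r}")
    if t_eval is None:
        grid = protocol.grid(grid_step)
    else:
        grid = np.asarray(t_eval, dtype=float)
        if grid.size < 2 or np.any(np.diff(grid) >= 0):
            raise ValueError("t_eval must be strictly decreasing with >= 2 points")

    A0, _ = physics.sphere_geometry(cell.V0)
    V_floor = cell.Vb * (1.0 + 1e-12)

    if cell.Lpg == 0.0:
        # impermeable membrane: no water leaves, volume is constant
        V = np.full_like(grid, cell.V0)
    else:
        def rhs(T: float, y) -> list[float]:
            V = y[0]
            if V <= V_floor:
                return [0.0]
            x_w = (V - cell.Vb) / constants.vw
            x_w = x_w / (x_w + cell.phi_diss * cell.ns)
            if area_mode == "constant":
                A = A0
            else:
                A = (36.0 * math.pi) ** (1.0 / 3.0) * V ** (2.0 / 3.0)
            Lp = cell.Lpg * math.exp(-(cell.ELp / constants.R_kcal)
                                     * (1.0 / T - 1.0 / constants.T_R))
            bracket = math.log(x_w) - (constants.dHf / constants.R_kcal) \
                * (1.0 / constants.T_R - 1.0 / T)
            return [(Lp * A * constants.R_pv * T) / (protocol.B * constants.vw) * bracket]

        sol = solve_ivp(rhs, (grid[0], grid[-1]), [cell.V0], method="LSODA",
                        t_eval=grid, rtol=rtol, atol=atol)
        if not sol.success:
            lt = sol.t[-1] if sol.t.size else grid[0]
            lv = sol.y[0, -1] if sol.t.size else cell.V0
            raise IntegrationError(f"water-transport integration failed: {sol.message}",
                                   last_T=float(lt), last_V=float(lv))
        V = np.clip(sol.y[0], V_floor, None)

    A, _ = physics.sphere_geometry(V)
    if area_mode == "constant":
        A = np.full_like(V, A0)
    Tf = physics.equilibrium_freezing_temperature(
        physics.water_mole_fraction(V, cell, constants), constants)
    eta = physics.cytoplasm_viscosity(grid, physics.salt_volume_fraction(V, cell),
                                      fv, constants)
    Lp = physics.water_permeability(grid, cell, constants)
    return Trajectory(T=grid, V=V, A=np.asarray(A), Tf=np.asarray(Tf),
                      eta=np.asarray(eta), Lp=np.asarray(Lp),
                      protocol=protocol, cell=cell)
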