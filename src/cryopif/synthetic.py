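"""Synthetic cryomicroscopy data with known ground truth.

Emulates the two data products of a cell-freezing study so the whole
two-stage estimation pipeline is testable end to end:

* *volume observations* — per cooling rate, the mean normalized cell
  volume at a temperature grid, with multiplicative measurement noise per
  synthetic cell (image segmentation scatter), reported as mean ± SEM;
* *per-cell ice-formation events* — for each cell cooled at rate B, the
  temperature at which intracellular ice first formed (or censoring at
  the end of the ramp), drawn from the model's inhomogeneous hazard by
  inverse-CDF sampling, with the triggering mechanism attributed by a
  competing-risks Bernoulli draw on the hazard shares.

Events carry the microscopic appearance labels used in cryomicroscopy —
"darkening" (sudden gray-level change) and "twitching" (sudden tremble).
By default the generator labels SCN events darkening and VCN events
twitching; this is a configurable convenience, not a claimed physical
identity.

All randomness flows from one seed through named substreams, so every
table is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CONSTANTS, FREE_VOLUME, CellParams, FreeVolumeParams, PhysicalConstants
from .errors import DomainError
from .fitting import IIFObservations, VolumeObservations
from .nucleation import NucleationParams, hazard_density
from .transport import CoolingProtocol, Trajectory, integrate_water_transport

__all__ = ["GroundTruth", "IIFEventTable", "generate_volume_observations",
           "simulate_iif_events", "empirical_pif", "default_ground_truth"]

_SUBSTREAMS = {"volume-noise": 0, "event-draw": 1, "attribution": 2}


@dataclass(frozen=True)
class GroundTruth:
    """Generator configuration: the true model plus the study design.

    Defaults mirror a typical cryomicroscopy study of suspended HeLa-like
    cells: five slow-to-moderate ramps for volumetry (≈30 cells each, 2%
    multiplicative volume noise, readings every 2 K down to −45 °C) and
    four fast ramps for ice-formation scoring (200 cells each, ramp to
    −50 °C).
    """

    cell: CellParams
    scn: NucleationParams
    vcn: NucleationParams
    seed: int
    rates_volume: tuple[float, ...] = (5.0, 10.0, 15.0, 30.0, 60.0)
    rates_iif: tuple[float, ...] = (45.0, 60.0, 75.0, 100.0)
    sigma_volume: float = 0.02
    cells_per_rate_volume: int = 30
    cells_per_rate_iif: int = 200
    T_start: float = 272.65
    T_end_volume: float = 228.15
    T_end_iif: float = 223.15
    volume_grid_step: float = 2.0
    label_map: tuple[tuple[str, str], ...] = (("SCN", "darkening"),
                                              ("VCN", "twitching"))

    def __post_init__(self) -> None:
        if self.sigma_volume < 0:
            raise DomainError("sigma_volume must be non-negative")
        if self.cells_per_rate_volume < 1 or self.cells_per_rate_iif < 1:
            raise DomainError("cells per rate must be >= 1")

    def rng(self, substream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _SUBSTREAMS[substream]])

    def labels(self) -> dict[str, str]:
        return dict(self.label_map)


@dataclass
class IIFEventTable:
    """Per-cell first-ice-event records.

    ``data`` columns: ``rate`` (K·min⁻¹), ``cell_id``, ``event_T`` (K;
    NaN for cells censored at the end of the ramp), ``mechanism``
    ("SCN"/"VCN"; empty for censored cells), ``label`` ("darkening"/
    "twitching"/"none").
    """

    data: pd.DataFrame
    T_start: float
    T_end: float

    def __post_init__(self) -> None:
        ev = self.data["event_T"].dropna()
        if len(ev) and (ev.min() < self.T_end - 1e-9 or ev.max() > self.T_start + 1e-9):
            raise DomainError("event temperatures must lie within the ramp")


def _trajectory(gt: GroundTruth, B: float, T_end: float,
                constants: PhysicalConstants, fv: FreeVolumeParams) -> Trajectory:
    proto = CoolingProtocol(B=B, T_start=gt.T_start, T_end=T_end)
    return integrate_water_transport(proto, gt.cell, constants, fv)


def generate_volume_observations(gt: GroundTruth,
                                 constants: PhysicalConstants = CONSTANTS,
                                 fv: FreeVolumeParams = FREE_VOLUME) -> VolumeObservations:
    """Mean ± SEM normalized-volume tables for every volumetry rate.

    Each synthetic cell contributes an i.i.d. multiplicative Gaussian
    reading ``v·(1 + σz)`` at every grid temperature; the table reports
    the per-temperature sample mean, SEM, and count.
    """
    rng = gt.rng("volume-noise")
    rows = []
    n = gt.cells_per_rate_volume
    for B in gt.rates_volume:
        traj = _trajectory(gt, B, gt.T_end_volume, constants, fv)
        T_grid = np.arange(gt.T_start - gt.volume_grid_step, gt.T_end_volume - 1e-9,
                           -gt.volume_grid_step)
        v_true = traj.interp_norm_volume(T_grid)
        noise = rng.normal(size=(T_grid.size, n))
        samples = v_true[:, None] * (1.0 + gt.sigma_volume * noise)
        mean = samples.mean(axis=1)
        sem = samples.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(T_grid.size)
        for Tk, m, s in zip(T_grid, mean, sem):
            rows.append({"rate": B, "T": Tk, "mean": m, "sem": s, "n": n})
    return VolumeObservations(pd.DataFrame(rows))


def _hazards(gt: GroundTruth, traj: Trajectory,
             constants: PhysicalConstants, fv: FreeVolumeParams):
    h_scn = hazard_density(traj, gt.scn, fv, constants)
    h_vcn = hazard_density(traj, gt.vcn, fv, constants)
    return h_scn, h_vcn


def simulate_iif_events(gt: GroundTruth, B: float,
                        constants: PhysicalConstants = CONSTANTS,
                        fv: FreeVolumeParams = FREE_VOLUME) -> IIFEventTable:
    """Draw per-cell first-ice events for one cooling rate.

    The total per-kelvin hazard h(T) = [I_SCN·A + I_VCN·V]/B (unit-
    converted) is integrated cumulatively along the ramp; each cell draws
    a standard-exponential deviate e and ices where the cumulative hazard
    first reaches e, or is censored at the end of the ramp.  The
    triggering mechanism is a Bernoulli draw with probability equal to
    the SCN share of the instantaneous hazard at the event temperature —
    exact for independent competing risks.
    """
    traj = _trajectory(gt, B, gt.T_end_iif, constants, fv)
    h_scn, h_vcn = _hazards(gt, traj, constants, fv)
    h_tot = h_scn + h_vcn
    dT = -np.diff(traj.T)
    # cumulative trapezoid of the total hazard along cooling
    H = np.concatenate(([0.0], np.cumsum(0.5 * (h_tot[1:] + h_tot[:-1]) * dT)))

    rng_e = gt.rng("event-draw")
    rng_a = gt.rng("attribution")
    labels = gt.labels()
    n = gt.cells_per_rate_iif
    # independent draws per rate: advance substreams deterministically by rate order
    k_rate = list(gt.rates_iif).index(B) if B in gt.rates_iif else 0
    e = rng_e.exponential(size=(len(gt.rates_iif), n))[k_rate]
    u_attr = rng_a.random(size=(len(gt.rates_iif), n))[k_rate]

    rows = []
    for i in range(n):
        if e[i] >= H[-1]:
            rows.append({"rate": B, "cell_id": i, "event_T": np.nan,
                         "mechanism": "", "label": "none"})
            continue
        k = int(np.searchsorted(H, e[i], side="right"))
        k = min(max(k, 1), H.size - 1)
        dH = H[k] - H[k - 1]
        frac = (e[i] - H[k - 1]) / dH if dH > 0 else 1.0
        T_ev = traj.T[k - 1] + frac * (traj.T[k] - traj.T[k - 1])
        denom = h_scn[k] + h_vcn[k]
        p_scn = h_scn[k] / denom if denom > 0 else 0.5
        mech = "SCN" if u_attr[i] < p_scn else "VCN"
        rows.append({"rate": B, "cell_id": i, "event_T": float(T_ev),
                     "mechanism": mech, "label": labels[mech]})
    return IIFEventTable(pd.DataFrame(rows), T_start=gt.T_start, T_end=gt.T_end_iif)


def empirical_pif(events: IIFEventTable, grid: np.ndarray) -> IIFObservations:
    """Cumulative event fractions on a temperature grid, per rate and label.

    PIF(T) is the fraction of cells whose event temperature is at or
    above T (ice formed by the time the ramp reached T); censored cells
    never count as events.
    """
    d = events.data
    if d.empty:
        raise ValueError("empty event table")
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    rows = []
    for rate, grp in d.groupby("rate"):
        n = len(grp)
        ev = grp.dropna(subset=["event_T"])
        t_dark = ev.loc[ev["label"] == "darkening", "event_T"].to_numpy()
        t_twit = ev.loc[ev["label"] == "twitching", "event_T"].to_numpy()
        t_all = ev["event_T"].to_numpy()
        for T in grid:
            rows.append({
                "rate": rate, "T": T,
                "pif_darkening": np.count_nonzero(t_dark >= T) / n,
                "pif_twitching": np.count_nonzero(t_twit >= T) / n,
                "pif_both": np.count_nonzero(t_all >= T) / n,
                "n": n,
            })
    return IIFObservations(pd.DataFrame(rows))


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """A HeLa-like ground truth for fixtures and recovery studies.

    The cell has the measured isotonic radius 7.51 μm (V0 ≈ 1774 μm³),
    an assumed inactive fraction Vb = 0.25·V0, and the pooled-fit
    membrane parameters L_pg = 0.1166 μm·min⁻¹·atm⁻¹,
    E_Lp = 11.9236 kcal·mol⁻¹.  Nucleation parameters are chosen to give
    ice formation between roughly −10 and −45 °C with gate-limited
    plateaus rising with cooling rate: SCN dominates early and shuts off
    at the critical volume 0.50·V0; VCN activates at deep supercooling
    and shuts off at 0.40·V0.
    """
    from .physics import isotonic_salt_content, sphere_geometry

    V0 = 4.0 / 3.0 * np.pi * 7.51 ** 3
    Vb = 0.25 * V0
    ns = isotonic_salt_content(V0, Vb, 272.65)
    cell = CellParams(V0=V0, Vb=Vb, Lpg=0.1166, ELp=11.9236, ns=ns)
    scn = NucleationParams("SCN", Omega0=2.7e8, kappa0=3.5e9, Vf=0.50 * V0)
    vcn = NucleationParams("VCN", Omega0=3.0e18, kappa0=8.0e10, Vf=0.40 * V0)
    return GroundTruth(cell=cell, scn=scn, vcn=vcn, seed=seed)
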