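"""Delimited-text table formats and schema-validated run configuration.

All tabular I/O is comma-separated UTF-8 with a mandatory header row and
'.' decimals.  Temperatures are °C in files (matching how freezing
protocols are reported) and Kelvin everywhere in memory; the conversion
is an exact ±273.15.  Lines starting with '#' are metadata comments
(config hash, seed) and are ignored on read.

Three schemas:

* volume table   — ``cooling_rate_C_per_min, temperature_C,
  norm_volume_mean, norm_volume_sem, n_cells``
* per-cell event — ``cooling_rate_C_per_min, cell_id,
  event_temperature_C, event_type`` with event_type in
  {darkening, twitching, none}; censored cells use ``none`` and an empty
  temperature field
* aggregated PIF — ``cooling_rate_C_per_min, temperature_C,
  pif_darkening, pif_twitching, pif_both, n_cells``

:func:`read_iif_table` dispatches between the last two by header.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .constants import CELSIUS_OFFSET, celsius_to_kelvin, kelvin_to_celsius
from .errors import TableFormatError
from .fitting import IIFObservations, VolumeObservations
from .synthetic import IIFEventTable

__all__ = ["VOLUME_HEADER", "EVENT_HEADER", "PIF_HEADER",
           "read_volume_table", "write_volume_table", "read_iif_table",
           "write_iif_events", "write_pif_table", "write_trajectory",
           "RunConfig", "load_config", "config_sha256"]

VOLUME_HEADER = ["cooling_rate_C_per_min", "temperature_C",
                 "norm_volume_mean", "norm_volume_sem", "n_cells"]
EVENT_HEADER = ["cooling_rate_C_per_min", "cell_id",
                "event_temperature_C", "event_type"]
PIF_HEADER = ["cooling_rate_C_per_min", "temperature_C", "pif_darkening",
              "pif_twitching", "pif_both", "n_cells"]
TRAJECTORY_HEADER = ["temperature_C", "volume_um3", "norm_volume",
                     "area_um2", "Tf_C", "viscosity_mPas", "Lp_um_min_atm"]

_EVENT_TYPES = {"darkening", "twitching", "none"}


def _read_csv(path) -> tuple[pd.DataFrame, list[int]]:
    """Read a CSV skipping '#' comments; returns the frame and the 1-based
    source line number of each data row."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    kept, line_nos = [], []
    for i, ln in enumerate(lines, start=1):
        if ln.strip().startswith("#") or not ln.strip():
            continue
        kept.append(ln)
        line_nos.append(i)
    if not kept:
        raise TableFormatError("empty table")
    df = pd.read_csv(_io.StringIO("\n".join(kept)), skipinitialspace=True)
    return df, line_nos[1:]


def _require_header(df: pd.DataFrame, header: list[str], path) -> None:
    if list(df.columns) != header:
        raise TableFormatError(
            f"{path}: header {list(df.columns)} does not match required {header}")


def read_volume_table(path) -> VolumeObservations:
    """Parse and validate a normalized-volume table (temperatures -> K)."""
    df, line_nos = _read_csv(path)
    _require_header(df, VOLUME_HEADER, path)
    for i, row in df.iterrows():
        line = line_nos[i] if i < len(line_nos) else None
        try:
            m = float(row["norm_volume_mean"])
            n = float(row["n_cells"])
        except (TypeError, ValueError):
            raise TableFormatError("non-numeric field", line=line)
        if not (0 < m <= 1.2):
            raise TableFormatError(f"norm_volume_mean {m} outside (0, 1.2]", line=line)
        if n < 1 or n != int(n):
            raise TableFormatError(f"n_cells {n} must be an integer >= 1", line=line)
    dup = df.duplicated(subset=["cooling_rate_C_per_min", "temperature_C"])
    if dup.any():
        raise TableFormatError("duplicate (rate, temperature) record",
                               line=line_nos[int(np.flatnonzero(dup)[0])])
    out = pd.DataFrame({
        "rate": df["cooling_rate_C_per_min"].astype(float),
        "T": df["temperature_C"].astype(float) + CELSIUS_OFFSET,
        "mean": df["norm_volume_mean"].astype(float),
        "sem": df["norm_volume_sem"].astype(float),
        "n": df["n_cells"].astype(int),
    })
    return VolumeObservations(out)


def _metadata_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k} = {v}\n" for k, v in metadata.items())


def write_volume_table(obs: VolumeObservations, path, decimals: int = 6,
                       metadata: dict | None = None) -> None:
    df = obs.data
    out = pd.DataFrame({
        "cooling_rate_C_per_min": df["rate"],
        "temperature_C": df["T"] - CELSIUS_OFFSET,
        "norm_volume_mean": df["mean"].round(decimals),
        "norm_volume_sem": df["sem"].round(decimals),
        "n_cells": df["n"].astype(int),
    })
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(metadata))
        out.to_csv(fh, index=False, float_format=f"%.{decimals}g")


def read_iif_table(path) -> Union[IIFEventTable, IIFObservations]:
    """Parse an ice-formation table, auto-detecting the schema by header."""
    df, line_nos = _read_csv(path)
    cols = list(df.columns)
    if cols == EVENT_HEADER:
        return _parse_event_table(df, line_nos, path)
    if cols == PIF_HEADER:
        return _parse_pif_table(df, line_nos, path)
    raise TableFormatError(
        f"{path}: header matches neither the per-cell event schema "
        f"{EVENT_HEADER} nor the aggregated schema {PIF_HEADER}")


def _parse_event_table(df, line_nos, path) -> IIFEventTable:
    for i, row in df.iterrows():
        line = line_nos[i] if i < len(line_nos) else None
        et = str(row["event_type"]).strip()
        if et not in _EVENT_TYPES:
            raise TableFormatError(f"unknown event_type {et!r}", line=line)
        t = row["event_temperature_C"]
        if et == "none":
            if not (pd.isna(t) or str(t).strip() == ""):
                raise TableFormatError("censored cell must have empty temperature",
                                       line=line)
        elif pd.isna(t):
            raise TableFormatError("event row missing temperature", line=line)
    t_k = pd.to_numeric(df["event_temperature_C"], errors="coerce") + CELSIUS_OFFSET
    out = pd.DataFrame({
        "rate": df["cooling_rate_C_per_min"].astype(float),
        "cell_id": df["cell_id"],
        "event_T": t_k,
        "mechanism": "",
        "label": df["event_type"].astype(str).str.strip(),
    })
    tmin = float(np.nanmin(t_k)) if out["event_T"].notna().any() else 173.15
    tmax = float(np.nanmax(t_k)) if out["event_T"].notna().any() else 272.65
    return IIFEventTable(out, T_start=max(272.65, tmax), T_end=min(173.15, tmin))


def _parse_pif_table(df, line_nos, path) -> IIFObservations:
    for i, row in df.iterrows():
        line = line_nos[i] if i < len(line_nos) else None
        for c in ("pif_darkening", "pif_twitching", "pif_both"):
            v = float(row[c])
            if not 0.0 <= v <= 1.0:
                raise TableFormatError(f"{c} = {v} outside [0, 1]", line=line)
    out = pd.DataFrame({
        "rate": df["cooling_rate_C_per_min"].astype(float),
        "T": df["temperature_C"].astype(float) + CELSIUS_OFFSET,
        "pif_darkening": df["pif_darkening"].astype(float),
        "pif_twitching": df["pif_twitching"].astype(float),
        "pif_both": df["pif_both"].astype(float),
        "n": df["n_cells"].astype(int),
    })
    try:
        return IIFObservations(out)
    except ValueError as e:
        raise TableFormatError(str(e))


def write_iif_events(events: IIFEventTable, path, decimals: int = 4,
                     metadata: dict | None = None) -> None:
    d = events.data
    t_c = d["event_T"] - CELSIUS_OFFSET
    out = pd.DataFrame({
        "cooling_rate_C_per_min": d["rate"],
        "cell_id": d["cell_id"],
        "event_temperature_C": t_c.round(decimals),
        "event_type": d["label"],
    })
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(metadata))
        out.to_csv(fh, index=False)


def write_pif_table(obs: IIFObservations, path, decimals: int = 6,
                    metadata: dict | None = None) -> None:
    d = obs.data
    out = pd.DataFrame({
        "cooling_rate_C_per_min": d["rate"],
        "temperature_C": d["T"] - CELSIUS_OFFSET,
        "pif_darkening": d["pif_darkening"].round(decimals),
        "pif_twitching": d["pif_twitching"].round(decimals),
        "pif_both": d["pif_both"].round(decimals),
        "n_cells": d["n"].astype(int),
    })
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(metadata))
        out.to_csv(fh, index=False)


def write_trajectory(traj, path, decimals: int = 6,
                     metadata: dict | None = None) -> None:
    out = pd.DataFrame({
        "temperature_C": traj.T - CELSIUS_OFFSET,
        "volume_um3": traj.V,
        "norm_volume": traj.norm_volume,
        "area_um2": traj.A,
        "Tf_C": traj.Tf - CELSIUS_OFFSET,
        "viscosity_mPas": traj.eta,
        "Lp_um_min_atm": traj.Lp,
    })
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(metadata))
        out.to_csv(fh, index=False, float_format=f"%.{decimals}g")


# ---------------------------------------------------------------------------
# Run configuration


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConstantsSection(_Strict):
    dHf_kcal_mol: float = 1.436
    vw_cm3_mol: float = 18.02
    T_gw_K: float = 136.0


class CellSection(_Strict):
    V0_um3: float | None = None
    radius_um: float | None = 7.51
    Vb_frac: float = 0.25
    Lpg_um_min_atm: float = 0.1166
    ELp_kcal_mol: float = 11.9236
    phi_diss: float = 2.0
    vs_cm3_mol: float = 16.6
    T0_isotonic_C: float = -0.5


class FreeVolumeSection(_Strict):
    eta_w0_mPas: float = 0.0306
    Vhat_w_cm3_g: float = 1.071
    K11_over_lambda_cm3_gK: float = 2.18e-3
    K21_K: float = -16.29


class MechanismSection(_Strict):
    Omega0: float
    kappa0: float
    Vf_frac: float | None = None


class NucleationSection(_Strict):
    scn: MechanismSection = MechanismSection(Omega0=2.7e8, kappa0=3.5e9, Vf_frac=0.50)
    vcn: MechanismSection = MechanismSection(Omega0=3.0e18, kappa0=8.0e10, Vf_frac=0.40)
    prefactor_mode: str = "off"
    vcn_water_volume: bool = False


class ProtocolSection(_Strict):
    T_start_C: float = -0.5
    T_end_C: float = -50.0
    rates_C_min: list[float] = Field(default_factory=lambda: [45.0, 60.0, 75.0, 100.0])
    grid_step_K: float = 0.05


class FittingSection(_Strict):
    n_starts: int = 20
    n_starts_volume: int = 3
    seed: int = 0
    weighting: str = "none"
    Omega0_bounds: list[float] = Field(default_factory=lambda: [1e5, 1e30])
    kappa0_bounds: list[float] = Field(default_factory=lambda: [1e8, 1e13])


class SyntheticSection(_Strict):
    seed: int = 0
    sigma_volume: float = 0.02
    cells_per_rate_volume: int = 30
    cells_per_rate_iif: int = 200
    rates_volume_C_min: list[float] = Field(
        default_factory=lambda: [5.0, 10.0, 15.0, 30.0, 60.0])
    rates_iif_C_min: list[float] = Field(
        default_factory=lambda: [45.0, 60.0, 75.0, 100.0])
    T_end_volume_C: float = -45.0
    T_end_iif_C: float = -50.0
    volume_grid_step_K: float = 2.0


class IOSection(_Strict):
    decimals: int = 6


class RunConfig(_Strict):
    """Schema-validated configuration; unknown keys are rejected."""

    constants: ConstantsSection = ConstantsSection()
    cell: CellSection = CellSection()
    free_volume: FreeVolumeSection = FreeVolumeSection()
    nucleation: NucleationSection = NucleationSection()
    protocol: ProtocolSection = ProtocolSection()
    fitting: FittingSection = FittingSection()
    synthetic: SyntheticSection = SyntheticSection()
    io: IOSection = IOSection()

    # -- builders -----------------------------------------------------------

    def physical_constants(self):
        from .constants import PhysicalConstants
        return PhysicalConstants(dHf=self.constants.dHf_kcal_mol,
                                 vw=self.constants.vw_cm3_mol * 1e12,
                                 T_gw=self.constants.T_gw_K)

    def free_volume_params(self):
        from .constants import FreeVolumeParams
        f = self.free_volume
        return FreeVolumeParams(eta_w0=f.eta_w0_mPas, Vhat_w=f.Vhat_w_cm3_g,
                                K11_over_lambda=f.K11_over_lambda_cm3_gK,
                                K21=f.K21_K)

    def cell_params(self):
        from .constants import CellParams
        from .physics import isotonic_salt_content
        c = self.cell
        if c.V0_um3 is not None:
            V0 = c.V0_um3
        elif c.radius_um is not None:
            V0 = 4.0 / 3.0 * np.pi * c.radius_um ** 3
        else:
            raise ValueError("cell section needs V0_um3 or radius_um")
        Vb = c.Vb_frac * V0
        T0 = celsius_to_kelvin(c.T0_isotonic_C)
        ns = isotonic_salt_content(V0, Vb, T0, c.phi_diss,
                                   self.physical_constants())
        return CellParams(V0=V0, Vb=Vb, Lpg=c.Lpg_um_min_atm,
                          ELp=c.ELp_kcal_mol, ns=ns, phi_diss=c.phi_diss,
                          vs=c.vs_cm3_mol * 1e12)

    def nucleation_params(self, model: str = "modified"):
        from .nucleation import NucleationParams
        V0 = self.cell_params().V0
        out = []
        for mech, sec in (("SCN", self.nucleation.scn), ("VCN", self.nucleation.vcn)):
            Vf = None
            if model == "modified" and sec.Vf_frac is not None:
                Vf = sec.Vf_frac * V0
            out.append(NucleationParams(mech, sec.Omega0, sec.kappa0, Vf=Vf))
        return tuple(out)

    def cooling_protocol(self, B: float):
        from .transport import CoolingProtocol
        return CoolingProtocol(B=B,
                               T_start=celsius_to_kelvin(self.protocol.T_start_C),
                               T_end=celsius_to_kelvin(self.protocol.T_end_C))

    def ground_truth(self):
        from .synthetic import GroundTruth
        s = self.synthetic
        scn, vcn = self.nucleation_params("modified")
        return GroundTruth(
            cell=self.cell_params(), scn=scn, vcn=vcn, seed=s.seed,
            rates_volume=tuple(s.rates_volume_C_min),
            rates_iif=tuple(s.rates_iif_C_min),
            sigma_volume=s.sigma_volume,
            cells_per_rate_volume=s.cells_per_rate_volume,
            cells_per_rate_iif=s.cells_per_rate_iif,
            T_start=celsius_to_kelvin(self.protocol.T_start_C),
            T_end_volume=celsius_to_kelvin(s.T_end_volume_C),
            T_end_iif=celsius_to_kelvin(s.T_end_iif_C),
            volume_grid_step=s.volume_grid_step_K)


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if overrides:
        for dotted, value in overrides.items():
            node = raw
            *parents, leaf = dotted.split(".")
            for p in parents:
                node = node.setdefault(p, {})
            node[leaf] = value
    return RunConfig.model_validate(raw)


def config_sha256(cfg: RunConfig) -> str:
    """Stable hash of the effective merged configuration."""
    payload = yaml.safe_dump(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
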