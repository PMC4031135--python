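"""Pooled nonlinear least-squares estimation of freezing-model parameters.

The estimation is two-stage, mirroring how freezing experiments are
analysed:

1. *Water transport.* One shared triple (L_pg, E_Lp, V_b) is fitted to
   normalized-volume observations pooled across all cooling rates
   simultaneously ("pooled fitting": a single parameter set, a single sum
   of squares over every (rate, temperature) record).
2. *Ice nucleation.* The stage-1 parameters are frozen; dehydration
   trajectories predicted from them provide A(T), V(T), T_f(T), η(T), and
   the nucleation parameters (Ω₀, κ₀ per mechanism, optionally critical
   volumes V_f) are fitted to cumulative PIF observations.  Ω₀ and κ₀ are
   searched in log10 space because their identifiable magnitudes span many
   decades; V_f is parametrized as a fraction of the isotonic volume.

Both stages use bounded trust-region least squares with a seeded
multistart over a Latin-hypercube design, so refitting the same data with
the same seed is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .constants import CONSTANTS, FREE_VOLUME, CellParams, FreeVolumeParams, PhysicalConstants
from .errors import DomainError, FitError
from .nucleation import NucleationParams, compute_pif_curve, pif_mechanism
from .physics import isotonic_salt_content
from .transport import CoolingProtocol, Trajectory, integrate_water_transport

__all__ = ["VolumeObservations", "IIFObservations", "FitResult", "FitOptions",
           "r_squared", "pooled_fit_water_transport", "fit_pif",
           "fit_pif_pooled"]


@dataclass
class VolumeObservations:
    """Normalized-volume records: one row per (cooling rate, temperature).

    ``data`` columns: ``rate`` (K·min⁻¹), ``T`` (K), ``mean`` (normalized
    volume), ``sem``, ``n`` (cells averaged).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"rate", "T", "mean", "sem", "n"}
        if not req.issubset(self.data.columns):
            raise ValueError(f"volume observations need columns {sorted(req)}")
        d = self.data
        if np.any((d["mean"] <= 0) | (d["mean"] > 1.2)):
            raise DomainError("normalized volume must lie in (0, 1.2]")
        if np.any(d["n"] < 1):
            raise DomainError("cell count n must be >= 1")

    @property
    def rates(self) -> np.ndarray:
        return np.sort(self.data["rate"].unique())


@dataclass
class IIFObservations:
    """Cumulative PIF records per (cooling rate, temperature).

    ``data`` columns: ``rate``, ``T`` (K), ``pif_darkening``,
    ``pif_twitching``, ``pif_both`` (each in [0, 1]), ``n`` (cells).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"rate", "T", "pif_darkening", "pif_twitching", "pif_both", "n"}
        if not req.issubset(self.data.columns):
            raise ValueError(f"IIF observations need columns {sorted(req)}")
        d = self.data
        for c in ("pif_darkening", "pif_twitching", "pif_both"):
            if np.any((d[c] < 0) | (d[c] > 1)):
                raise DomainError(f"{c} must lie in [0, 1]")
        if np.any(d["n"] < 1):
            raise DomainError("cell count n must be >= 1")
        for rate, grp in d.groupby("rate"):
            g = grp.sort_values("T", ascending=False)
            if np.any(np.diff(g["pif_both"].to_numpy()) < -1e-12):
                raise DomainError(
                    f"pif_both must be non-decreasing along cooling (rate {rate})")

    @property
    def rates(self) -> np.ndarray:
        return np.sort(self.data["rate"].unique())


@dataclass
class FitOptions:
    """Optimizer contract shared by both stages."""

    n_starts: int = 20
    seed: int = 0
    weighting: Literal["none", "sem"] = "none"
    max_nfev: int | None = None


@dataclass
class FitResult:
    """Parameter estimates plus goodness-of-fit and optimizer diagnostics."""

    params: dict[str, float]
    r_squared: float
    sse: float
    residuals: np.ndarray
    bounds: dict[str, tuple[float, float]]
    converged: bool
    n_starts: int
    seed: int
    start_objectives: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_obs: int = 0


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SSE/SST over pooled records."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 2:
        raise ValueError("observed and predicted must be equal-length vectors of size >= 2")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise DomainError("observed vector has zero variance")
    return 1.0 - float(np.sum((o - p) ** 2)) / sst


def _lhs_starts(lo: np.ndarray, hi: np.ndarray, n: int, seed: int,
                margin: float = 0.05) -> np.ndarray:
    """Seeded Latin-hypercube start design strictly inside the bounds."""
    sampler = qmc.LatinHypercube(d=lo.size, seed=seed)
    u = sampler.random(n)
    return lo + (margin + (1.0 - 2.0 * margin) * u) * (hi - lo)


def _multistart(residual_fn, starts: np.ndarray, lo: np.ndarray,
                hi: np.ndarray, max_nfev, diff_step=None) -> tuple:
    best = None
    objectives: list[float] = []
    for x0 in starts:
        try:
            sol = least_squares(residual_fn, x0, bounds=(lo, hi), method="trf",
                                max_nfev=max_nfev, diff_step=diff_step)
        except Exception:
            objectives.append(float("inf"))
            continue
        sse = float(2.0 * sol.cost)
        objectives.append(sse)
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise FitError("all multistart optimizations failed")
    return best[1], objectives


def pooled_fit_water_transport(obs: VolumeObservations, cell_template: CellParams,
                               T0_isotonic: float = 272.65,
                               bounds: dict[str, tuple[float, float]] | None = None,
                               options: FitOptions | None = None,
                               constants: PhysicalConstants = CONSTANTS,
                               fv: FreeVolumeParams = FREE_VOLUME) -> FitResult:
    """Fit (L_pg, E_Lp, V_b) to normalized-volume data pooled over rates.

    The search space is (log10 L_pg, E_Lp, V_b/V0); the intracellular
    salt content is re-derived from the isotonic condition for every V_b
    candidate so the model stays internally consistent.  R² uses a single
    SST over all pooled records.
    """
    options = options or FitOptions(n_starts=3)
    d = obs.data
    if len(obs.rates) < 2:
        raise FitError("pooled fitting requires observations at >= 2 cooling rates")
    if d["T"].nunique() < 2:
        raise FitError("degenerate data: a single temperature cannot constrain the model")

    b = {"Lpg": (1e-3, 10.0), "ELp": (1.0, 50.0), "Vb_frac": (0.05, 0.9)}
    if bounds:
        b.update(bounds)
    lo = np.array([np.log10(b["Lpg"][0]), b["ELp"][0], b["Vb_frac"][0]])
    hi = np.array([np.log10(b["Lpg"][1]), b["ELp"][1], b["Vb_frac"][1]])

    V0 = cell_template.V0
    by_rate = {rate: grp.sort_values("T", ascending=False)
               for rate, grp in d.groupby("rate")}
    w = {}
    for rate, grp in by_rate.items():
        if options.weighting == "sem":
            sem = np.clip(grp["sem"].to_numpy(float), 1e-4, None)
            w[rate] = 1.0 / sem
        else:
            w[rate] = np.ones(len(grp))

    def residual(x: np.ndarray) -> np.ndarray:
        Lpg, ELp, vb_frac = 10.0 ** x[0], x[1], x[2]
        Vb = vb_frac * V0
        ns = isotonic_salt_content(V0, Vb, T0_isotonic,
                                   cell_template.phi_diss, constants)
        cell = cell_template.replace(Lpg=Lpg, ELp=ELp, Vb=Vb, ns=ns)
        out = []
        for rate, grp in by_rate.items():
            T_obs = grp["T"].to_numpy(float)
            T_lo = min(T_obs.min(), T0_isotonic - 1.0)
            proto = CoolingProtocol(B=rate, T_start=T0_isotonic, T_end=T_lo - 0.5)
            t_eval = np.concatenate(([T0_isotonic], np.sort(T_obs)[::-1]))
            t_eval = np.unique(t_eval)[::-1]
            traj = integrate_water_transport(proto, cell, constants, fv,
                                             t_eval=t_eval, rtol=1e-7, atol=1e-9)
            model = traj.interp_norm_volume(T_obs)
            out.append((model - grp["mean"].to_numpy(float)) * w[rate])
        return np.concatenate(out)

    x_template = np.array([np.log10(cell_template.Lpg), cell_template.ELp,
                           cell_template.Vb / V0])
    starts = _lhs_starts(lo, hi, options.n_starts, options.seed)
    if np.all((x_template >= lo) & (x_template <= hi)):
        starts = np.vstack([x_template, starts[:-1]]) if options.n_starts > 1 \
            else np.array([x_template])

    try:
        sol, objectives = _multistart(residual, starts, lo, hi, options.max_nfev)
    except FitError:
        raise
    Lpg, ELp, vb_frac = 10.0 ** sol.x[0], float(sol.x[1]), float(sol.x[2])
    obs_all, pred_all = [], []
    res = residual(sol.x)
    # recover unweighted prediction for R²
    k = 0
    for rate, grp in by_rate.items():
        m = len(grp)
        obs_all.append(grp["mean"].to_numpy(float))
        pred_all.append(grp["mean"].to_numpy(float) + res[k:k + m] / w[rate])
        k += m
    r2 = r_squared(np.concatenate(obs_all), np.concatenate(pred_all))
    return FitResult(
        params={"Lpg": Lpg, "ELp": ELp, "Vb": vb_frac * V0, "Vb_frac": vb_frac},
        r_squared=r2, sse=float(2.0 * sol.cost), residuals=res,
        bounds=b, converged=bool(sol.success), n_starts=len(starts),
        seed=options.seed, start_objectives=objectives, n_obs=len(d))


# ---------------------------------------------------------------------------
# PIF fitting

_PIF_BOUNDS = {
    "Omega0": (1e5, 1e30),
    "kappa0": (1e8, 1e13),
}


def _pif_model_residual_factory(groups, model, cell, f_lo, weighting,
                                fv, constants):
    """groups: list of (trajectory, T_obs, pif_obs, weights).

    In the modified model the critical volumes are parametrized as
    f_scn = x[4] and f_vcn = f_lo + x[5]·(f_scn − f_lo) with x[5] ∈ [0, 1],
    which enforces V_f^SCN ≥ V_f^VCN structurally (the sequential
    surface-then-volume gating order) and removes the label-swap local
    optimum from the search space.
    """

    def unpack(x):
        if model == "modified":
            f_scn = x[4]
            f_vcn = f_lo + x[5] * (f_scn - f_lo)
            Vf_s, Vf_v = f_scn * cell.V0, f_vcn * cell.V0
        else:
            Vf_s = Vf_v = None
        scn = NucleationParams("SCN", 10.0 ** x[0], 10.0 ** x[1], Vf=Vf_s)
        vcn = NucleationParams("VCN", 10.0 ** x[2], 10.0 ** x[3], Vf=Vf_v)
        return scn, vcn

    def residual(x):
        scn, vcn = unpack(x)
        out = []
        for traj, T_obs, pif_obs, w in groups:
            curve = compute_pif_curve(traj, scn, vcn, fv, constants)
            model_pif = np.interp(T_obs, curve.T[::-1], curve.pif_total[::-1])
            out.append((model_pif - pif_obs) * w)
        return np.concatenate(out)

    return unpack, residual


def _fit_pif_groups(groups, model, cell, bounds, options, fv, constants) -> FitResult:
    b = dict(_PIF_BOUNDS)
    vb_frac = cell.Vb / cell.V0
    b["Vf_frac"] = (vb_frac + 1e-3, 1.0)
    if bounds:
        b.update(bounds)

    f_lo = b["Vf_frac"][0]
    lo = [np.log10(b["Omega0"][0]), np.log10(b["kappa0"][0])] * 2
    hi = [np.log10(b["Omega0"][1]), np.log10(b["kappa0"][1])] * 2
    if model == "modified":
        lo += [f_lo, 0.0]
        hi += [b["Vf_frac"][1], 1.0]
    elif model != "original":
        raise ValueError(f"unknown model {model!r}")
    lo, hi = np.array(lo), np.array(hi)

    unpack, residual = _pif_model_residual_factory(
        groups, model, cell, f_lo, options.weighting, fv, constants)
    starts = _lhs_starts(lo, hi, options.n_starts, options.seed)
    if model == "modified":
        # The gated objective is rugged and multimodal in the critical-
        # volume directions, and the kinetic parameters of each basin sit
        # on distinct (Omega0, kappa0) ridges; plain multistart stalls.
        # Global phase:
        #   1. fit the ungated model (one kinetics candidate);
        #   2. anchor SCN kinetics on the early rise — before any gate
        #      closes, the warm part of the curve is pure surface
        #      nucleation, so 2-parameter surface-only fits to the low-PIF
        #      points locate the admissible SCN ridges (there can be more
        #      than one; keep the distinct ones);
        #   3. from every kinetics candidate, run short full-space polishes
        #      over a dense grid of gate positions — the basin of a true
        #      gate is narrow (a few 0.01 V0), so the grid must resolve it;
        #   4. finish with unrestricted polish of the best candidates and
        #      the seeded LHS design.
        base = _fit_pif_groups(groups, "original", cell, bounds, options,
                               fv, constants)
        x_base = np.array([np.log10(base.params["Omega0_scn"]),
                           np.log10(base.params["kappa0_scn"]),
                           np.log10(base.params["Omega0_vcn"]),
                           np.log10(base.params["kappa0_vcn"])])
        pif_all = np.concatenate([g[2] for g in groups])
        early_cut = 0.5 * pif_all.max()

        def residual_scn_early(x2):
            scn = NucleationParams("SCN", 10.0 ** x2[0], 10.0 ** x2[1])
            out = []
            for traj, T_obs, pif_obs, w in groups:
                m = pif_obs <= early_cut
                if not m.any():
                    continue
                p = pif_mechanism(traj, scn, fv, constants)
                out.append(np.interp(T_obs[m], traj.T[::-1], p[::-1])
                           - pif_obs[m])
            return np.concatenate(out) if out else np.zeros(1)

        scn_ridges: list[np.ndarray] = []
        ridge_sses: list[float] = []
        for x2 in _lhs_starts(lo[:2], hi[:2], 10, options.seed + 1):
            try:
                sub2 = least_squares(residual_scn_early, x2,
                                     bounds=(lo[:2], hi[:2]), method="trf",
                                     max_nfev=200, diff_step=1e-3)
            except Exception:
                continue
            if any(np.max(np.abs(sub2.x - r_)) < 0.5 for r_ in scn_ridges):
                continue
            scn_ridges.append(sub2.x)
            ridge_sses.append(float(2 * sub2.cost))
        order = np.argsort(ridge_sses)
        best_sse = ridge_sses[order[0]] if len(order) else np.inf
        scn_ridges = [scn_ridges[i] for i in order
                      if ridge_sses[i] <= max(100.0 * best_sse, 1e-4)][:3]

        vcn_seeds = [x_base[2:],
                     np.array([0.5 * (lo[2] + hi[2]), 0.5 * (lo[3] + hi[3])])]
        kin_starts = [x_base] + [np.concatenate([s, v])
                                 for s in scn_ridges for v in vcn_seeds]

        f_grid = np.arange(f_lo + 5e-3, min(b["Vf_frac"][1], 0.93), 0.05)
        cand: list[tuple[float, np.ndarray]] = []
        for k in kin_starts:
            for fs in f_grid:
                for r in (0.3, 0.7):
                    x0 = np.concatenate([k, [float(fs), r]])
                    try:
                        short = least_squares(residual, x0, bounds=(lo, hi),
                                              method="trf", max_nfev=60,
                                              diff_step=1e-3)
                        cand.append((float(2 * short.cost), short.x))
                    except Exception:
                        continue
        cand.sort(key=lambda t: t[0])
        cont = [x for _, x in cand[:8]]
        cont.append(np.concatenate([x_base, [f_lo + 5e-3, 0.5]]))
        starts = np.vstack([np.asarray(cont), starts])
    sol, objectives = _multistart(residual, starts, lo, hi, options.max_nfev,
                                  diff_step=1e-3)

    warnings: list[str] = []
    params = {
        "Omega0_scn": 10.0 ** sol.x[0], "kappa0_scn": 10.0 ** sol.x[1],
        "Omega0_vcn": 10.0 ** sol.x[2], "kappa0_vcn": 10.0 ** sol.x[3],
    }
    if model == "modified":
        f_scn = float(sol.x[4])
        f_vcn = f_lo + float(sol.x[5]) * (f_scn - f_lo)
        params["Vf_frac_scn"] = f_scn
        params["Vf_frac_vcn"] = f_vcn
        for val, key in ((f_scn, "Vf_frac_scn"), (f_vcn, "Vf_frac_vcn")):
            if min(val - f_lo, b["Vf_frac"][1] - val) < 1e-6:
                warnings.append(f"{key} pinned at a search bound")

    sse = float(2.0 * sol.cost)
    # near-degenerate direction check: the VCN kinetic prefactor is the
    # classic sloppy direction of this model
    x_pert = sol.x.copy()
    x_pert[2] = min(x_pert[2] + 1.0, hi[2])
    sse_pert = float(np.sum(residual(x_pert) ** 2))
    if abs(sse_pert - sse) < 1e-3:
        warnings.append("objective insensitive to 10x Omega0_vcn perturbation "
                        "(near-degenerate parameter direction)")

    obs_all = np.concatenate([g[2] for g in groups])
    pred = obs_all + sol.fun / np.concatenate([g[3] for g in groups])
    r2 = r_squared(obs_all, pred)
    return FitResult(params=params, r_squared=r2, sse=sse, residuals=sol.fun,
                     bounds=b, converged=bool(sol.success), n_starts=len(starts),
                     seed=options.seed, start_objectives=objectives,
                     warnings=warnings, n_obs=obs_all.size)


def _obs_group(grp: pd.DataFrame, traj: Trajectory, weighting: str):
    g = grp.sort_values("T", ascending=False)
    T_obs = g["T"].to_numpy(float)
    pif_obs = g["pif_both"].to_numpy(float)
    if weighting == "sem":
        # binomial-ish weight: sqrt(n) de-emphasizes small samples
        w = np.sqrt(g["n"].to_numpy(float))
        w = w / w.mean()
    else:
        w = np.ones(T_obs.size)
    return traj, T_obs, pif_obs, w


def fit_pif(obs: IIFObservations, traj: Trajectory,
            model: Literal["original", "modified"] = "modified",
            bounds: dict | None = None, options: FitOptions | None = None,
            fv: FreeVolumeParams = FREE_VOLUME,
            constants: PhysicalConstants = CONSTANTS) -> FitResult:
    """Fit nucleation parameters to cumulative PIF data at one cooling rate.

    ``original`` fits 4 parameters (Ω₀, κ₀ per mechanism); ``modified``
    adds the two critical-volume fractions.  The objective is the SSE
    between modelled combined PIF and the observed 'both-event' PIF,
    pooling all temperature points of the rate.  The dehydration
    trajectory must come from stage-1 water-transport parameters and is
    held fixed.
    """
    options = options or FitOptions()
    rates = obs.rates
    if len(rates) != 1:
        raise FitError("fit_pif expects observations at exactly one cooling rate; "
                       "use fit_pif_pooled for shared-parameter multi-rate fits")
    if abs(float(rates[0]) - traj.protocol.B) > 1e-9:
        raise FitError("trajectory cooling rate does not match the observations")
    if len(obs.data) < 3:
        raise FitError("too few temperature points to fit nucleation parameters")
    groups = [_obs_group(obs.data, traj, options.weighting)]
    return _fit_pif_groups(groups, model, traj.cell, bounds, options, fv, constants)


def fit_pif_pooled(obs: IIFObservations, trajs: dict[float, Trajectory],
                   model: Literal["original", "modified"] = "modified",
                   bounds: dict | None = None, options: FitOptions | None = None,
                   fv: FreeVolumeParams = FREE_VOLUME,
                   constants: PhysicalConstants = CONSTANTS) -> FitResult:
    """Fit one shared nucleation parameter set to PIF data at several rates.

    The global variant of :func:`fit_pif`: a single (Ω₀, κ₀[, V_f]) pair
    per mechanism explains all cooling rates simultaneously, each through
    its own dehydration trajectory.
    """
    options = options or FitOptions()
    groups = []
    cell = None
    for rate, grp in obs.data.groupby("rate"):
        if rate not in trajs:
            raise FitError(f"no trajectory supplied for cooling rate {rate}")
        traj = trajs[rate]
        if abs(float(rate) - traj.protocol.B) > 1e-9:
            raise FitError(f"trajectory rate mismatch at {rate}")
        cell = traj.cell
        groups.append(_obs_group(grp, traj, options.weighting))
    if not groups:
        raise FitError("empty observation table")
    return _fit_pif_groups(groups, model, cell, bounds, options, fv, constants)
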