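"""Pooled least-squares estimation: metric, recovery, determinism."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import cryopif as cp
from cryopif.errors import DomainError, FitError
from cryopif.fitting import (FitOptions, IIFObservations, VolumeObservations,
                             fit_pif, fit_pif_pooled,
                             pooled_fit_water_transport, r_squared)
from cryopif.nucleation import NucleationParams, compute_pif_curve
from cryopif.synthetic import generate_volume_observations


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction(self):
        o = np.array([0.0, 1.0, 2.0])
        assert r_squared(o, np.full(3, o.mean())) == pytest.approx(0.0)

    def test_three_point_hand_case(self):
        assert r_squared([0.0, 1.0, 2.0], [0.0, 1.0, 1.0]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            r_squared([1.0, 1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def noiseless_volume_obs():
    gt = replace(cp.default_ground_truth(seed=2), sigma_volume=0.0,
                 rates_volume=(10.0, 30.0, 60.0), cells_per_rate_volume=5)
    return gt, generate_volume_observations(gt)


class TestWaterTransportFit:
    def test_noiseless_parameter_recovery(self, noiseless_volume_obs):
        """Noise-free multi-rate volume curves pin (L_pg, E_Lp) to <1%."""
        gt, obs = noiseless_volume_obs
        template = gt.cell.replace(Lpg=0.4, ELp=7.0, Vb=0.35 * gt.cell.V0)
        res = pooled_fit_water_transport(obs, template,
                                         options=FitOptions(n_starts=2, seed=0))
        assert res.params["Lpg"] == pytest.approx(gt.cell.Lpg, rel=0.01)
        assert res.params["ELp"] == pytest.approx(gt.cell.ELp, rel=0.01)
        assert res.r_squared >= 0.9999

    def test_single_rate_rejected(self, noiseless_volume_obs):
        _, obs = noiseless_volume_obs
        one = VolumeObservations(obs.data[obs.data["rate"] == 10.0].copy())
        with pytest.raises(FitError):
            pooled_fit_water_transport(one, cp.default_ground_truth(0).cell)

    def test_single_temperature_rejected(self):
        df = pd.DataFrame({"rate": [10.0, 30.0], "T": [263.15, 263.15],
                           "mean": [0.6, 0.8], "sem": [0.01, 0.01],
                           "n": [10, 10]})
        with pytest.raises(FitError):
            pooled_fit_water_transport(VolumeObservations(df),
                                       cp.default_ground_truth(0).cell)

    def test_seed_reproducibility(self, noiseless_volume_obs):
        gt, obs = noiseless_volume_obs
        template = gt.cell.replace(Lpg=0.4, ELp=7.0)
        opts = FitOptions(n_starts=2, seed=4)
        a = pooled_fit_water_transport(obs, template, options=opts)
        b = pooled_fit_water_transport(obs, template, options=opts)
        assert a.params == b.params
        assert a.sse == b.sse


@pytest.fixture(scope="module")
def analytic_pif_data(ground_truth, traj60):
    """Noise-free (n -> infinity) combined-PIF data from the gated model."""
    curve = compute_pif_curve(traj60, ground_truth.scn, ground_truth.vcn)
    grid = np.arange(270.65, 223.15 - 1e-9, -2.0)
    pif = np.interp(grid, curve.T[::-1], curve.pif_total[::-1])
    df = pd.DataFrame({"rate": 60.0, "T": grid, "pif_darkening": pif,
                       "pif_twitching": 0.0, "pif_both": pif, "n": 100000})
    return IIFObservations(df)


class TestPIFFit:
    def test_noiseless_critical_volume_recovery(self, ground_truth, traj60,
                                                analytic_pif_data):
        """The two critical-volume fractions are recovered within 0.02 V0
        from a noise-free single-rate curve."""
        res = fit_pif(analytic_pif_data, traj60, "modified",
                      options=FitOptions(n_starts=10, seed=1))
        V0 = ground_truth.cell.V0
        assert res.params["Vf_frac_scn"] == pytest.approx(
            ground_truth.scn.Vf / V0, abs=0.02)
        assert res.params["Vf_frac_vcn"] == pytest.approx(
            ground_truth.vcn.Vf / V0, abs=0.02)
        assert res.params["Vf_frac_scn"] >= res.params["Vf_frac_vcn"]

    def test_original_model_overshoots_plateau(self, traj60, analytic_pif_data):
        """On data that plateau below 1, the ungated fit overshoots the
        plateau tail while the gated fit tracks it (smaller tail SSE)."""
        opts = FitOptions(n_starts=10, seed=1)
        res_o = fit_pif(analytic_pif_data, traj60, "original", options=opts)
        res_m = fit_pif(analytic_pif_data, traj60, "modified", options=opts)
        d = analytic_pif_data.data.sort_values("T", ascending=False)
        tail = d["T"].to_numpy() < 243.15  # below -30 C: the plateau region
        sse_o = float(np.sum(res_o.residuals[tail] ** 2))
        sse_m = float(np.sum(res_m.residuals[tail] ** 2))
        assert sse_m < sse_o
        assert res_m.sse < res_o.sse

    def test_rate_mismatch_rejected(self, cell, analytic_pif_data):
        traj45 = cp.integrate_water_transport(
            cp.CoolingProtocol(B=45.0, T_end=223.15), cell, grid_step=0.5)
        with pytest.raises(FitError):
            fit_pif(analytic_pif_data, traj45)

    def test_multirate_requires_pooled_variant(self, traj60, analytic_pif_data):
        d2 = analytic_pif_data.data.copy()
        d2["rate"] = 45.0
        both = IIFObservations(pd.concat([analytic_pif_data.data, d2]))
        with pytest.raises(FitError):
            fit_pif(both, traj60)

    def test_degenerate_direction_flagged(self, traj60, ground_truth):
        """When the data carry no volume-catalyzed signal the VCN kinetic
        prefactor is unidentifiable and the fit must say so."""
        scn_only = compute_pif_curve(traj60, ground_truth.scn,
                                     NucleationParams("VCN", 0.0, 1e10))
        grid = np.arange(270.65, 223.15 - 1e-9, -2.0)
        pif = np.interp(grid, scn_only.T[::-1], scn_only.pif_total[::-1])
        obs = IIFObservations(pd.DataFrame(
            {"rate": 60.0, "T": grid, "pif_darkening": pif,
             "pif_twitching": 0.0, "pif_both": pif, "n": 1000}))
        # cap the kinetic prefactors at a level where the per-volume channel
        # cannot produce measurable hazard (<1e-6/K even barrier-free): the
        # fitted Omega0_vcn is then necessarily unidentifiable
        res = fit_pif(obs, traj60, "original", bounds={"Omega0": (1e5, 1e9)},
                      options=FitOptions(n_starts=8, seed=2))
        assert any("Omega0_vcn" in w for w in res.warnings)

    def test_best_of_k_objective_monotone(self, traj60, analytic_pif_data):
        res = fit_pif(analytic_pif_data, traj60, "original",
                      options=FitOptions(n_starts=8, seed=5))
        running = np.minimum.accumulate(res.start_objectives)
        assert np.all(np.diff(running) <= 0)
        assert res.sse == pytest.approx(min(res.start_objectives))

    def test_seed_reproducibility(self, traj60, analytic_pif_data):
        opts = FitOptions(n_starts=4, seed=9)
        a = fit_pif(analytic_pif_data, traj60, "modified", options=opts)
        b = fit_pif(analytic_pif_data, traj60, "modified", options=opts)
        assert a.params == b.params


def test_two_stage_freezes_stage_one(noiseless_volume_obs, ground_truth):
    """Stage-2 PIF fitting must not perturb the stage-1 water-transport
    estimates."""
    from cryopif.synthetic import empirical_pif, simulate_iif_events
    from cryopif.workflows import two_stage_fit

    gt, vol_obs = noiseless_volume_obs
    gt_iif = replace(gt, rates_iif=(60.0,), cells_per_rate_iif=150)
    ev = simulate_iif_events(gt_iif, 60.0)
    grid = np.arange(gt.T_start, gt.T_end_iif - 1e-9, -2.0)
    iif_obs = empirical_pif(ev, grid)
    template = gt.cell.replace(Lpg=0.4, ELp=7.0)
    s1, s2 = two_stage_fit(vol_obs, iif_obs, template, gt.T_start,
                           gt.T_end_iif, n_starts_volume=2, n_starts_pif=6,
                           fit_seed=3)
    direct = pooled_fit_water_transport(
        vol_obs, template, gt.T_start, options=FitOptions(n_starts=2, seed=3))
    assert s1.params == direct.params
    assert set(s2.params) >= {"Omega0_scn", "Vf_frac_scn", "Vf_frac_vcn"}
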