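"""Synthetic volume tables and stochastic ice-event generation."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import cryopif as cp
from cryopif.nucleation import compute_pif_curve
from cryopif.synthetic import (IIFEventTable, empirical_pif,
                               generate_volume_observations,
                               simulate_iif_events)


@pytest.fixture(scope="module")
def small_gt():
    gt = cp.default_ground_truth(seed=11)
    return replace(gt, rates_volume=(10.0, 60.0), cells_per_rate_volume=20,
                   cells_per_rate_iif=400, rates_iif=(60.0,))


class TestVolumeObservations:
    def test_noiseless_equals_model(self, small_gt):
        gt = replace(small_gt, sigma_volume=0.0)
        obs = generate_volume_observations(gt)
        traj = cp.integrate_water_transport(
            cp.CoolingProtocol(B=10.0, T_start=gt.T_start, T_end=gt.T_end_volume),
            gt.cell)
        grp = obs.data[obs.data["rate"] == 10.0]
        model = traj.interp_norm_volume(grp["T"].to_numpy())
        assert np.allclose(grp["mean"].to_numpy(), model, atol=1e-12)
        assert np.all(grp["sem"] < 1e-12)

    def test_sem_scales_inverse_sqrt_n(self):
        sems = []
        for n in (10, 40, 160):
            gt = replace(cp.default_ground_truth(seed=5),
                         rates_volume=(10.0,), cells_per_rate_volume=n)
            obs = generate_volume_observations(gt)
            sems.append(obs.data["sem"].mean())
        r1 = sems[0] / sems[1]
        r2 = sems[1] / sems[2]
        assert 1.5 < r1 < 2.7
        assert 1.5 < r2 < 2.7

    def test_seed_determinism(self, small_gt):
        a = generate_volume_observations(small_gt)
        b = generate_volume_observations(small_gt)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = generate_volume_observations(replace(small_gt, seed=99))
        assert not np.allclose(a.data["mean"], c.data["mean"])


class TestEventSimulation:
    def test_no_nucleation_all_censored(self, small_gt):
        gt = replace(small_gt,
                     scn=replace(small_gt.scn, Omega0=0.0),
                     vcn=replace(small_gt.vcn, Omega0=0.0))
        ev = simulate_iif_events(gt, 60.0)
        assert (ev.data["label"] == "none").all()
        assert ev.data["event_T"].isna().all()

    def test_empirical_matches_analytic_pif(self, small_gt):
        """Monte-Carlo PIF from a few hundred cells tracks the quadrature
        curve within binomial noise."""
        ev = simulate_iif_events(small_gt, 60.0)
        grid = np.arange(small_gt.T_start, small_gt.T_end_iif - 1e-9, -1.0)
        emp = empirical_pif(ev, grid)
        traj = cp.integrate_water_transport(
            cp.CoolingProtocol(B=60.0, T_start=small_gt.T_start,
                               T_end=small_gt.T_end_iif), small_gt.cell)
        curve = compute_pif_curve(traj, small_gt.scn, small_gt.vcn)
        ana = np.interp(emp.data["T"].to_numpy(), curve.T[::-1],
                        curve.pif_total[::-1])
        assert np.max(np.abs(emp.data["pif_both"].to_numpy() - ana)) < 0.06

    def test_no_events_below_gate_closing(self, small_gt):
        """With both critical volumes above the terminal volume, no cell
        ices after the later (VCN) gate has closed."""
        ev = simulate_iif_events(small_gt, 60.0)
        traj = cp.integrate_water_transport(
            cp.CoolingProtocol(B=60.0, T_start=small_gt.T_start,
                               T_end=small_gt.T_end_iif), small_gt.cell)
        assert traj.V[-1] < small_gt.vcn.Vf
        T_close = traj.T[np.argmax(traj.V < small_gt.vcn.Vf)]
        t_events = ev.data["event_T"].dropna()
        assert t_events.min() >= T_close - 0.1

    def test_mechanism_labels(self, small_gt):
        ev = simulate_iif_events(small_gt, 60.0)
        iced = ev.data.dropna(subset=["event_T"])
        assert set(iced["mechanism"]) <= {"SCN", "VCN"}
        assert (iced.loc[iced["mechanism"] == "SCN", "label"] == "darkening").all()
        assert (iced.loc[iced["mechanism"] == "VCN", "label"] == "twitching").all()

    def test_seed_determinism(self, small_gt):
        a = simulate_iif_events(small_gt, 60.0).data
        b = simulate_iif_events(small_gt, 60.0).data
        pd.testing.assert_frame_equal(a, b)


class TestEmpiricalPIF:
    def _toy_table(self):
        rows = [
            (60.0, 0, 263.15, "SCN", "darkening"),
            (60.0, 1, 258.15, "SCN", "darkening"),
            (60.0, 2, 248.15, "VCN", "twitching"),
            (60.0, 3, np.nan, "", "none"),
            (60.0, 4, np.nan, "", "none"),
        ]
        df = pd.DataFrame(rows, columns=["rate", "cell_id", "event_T",
                                         "mechanism", "label"])
        return IIFEventTable(df, T_start=272.65, T_end=223.15)

    def test_hand_count(self):
        """5-cell toy table: 2 darkening, 1 twitching, 2 censored."""
        obs = empirical_pif(self._toy_table(),
                            np.array([268.15, 260.15, 250.15, 240.15]))
        d = obs.data.set_index("T")
        assert d.loc[268.15, "pif_both"] == 0.0
        assert d.loc[260.15, "pif_both"] == pytest.approx(0.2)
        assert d.loc[250.15, "pif_both"] == pytest.approx(0.4)
        assert d.loc[240.15, "pif_both"] == pytest.approx(0.6)
        assert d.loc[240.15, "pif_darkening"] == pytest.approx(0.4)
        assert d.loc[240.15, "pif_twitching"] == pytest.approx(0.2)

    def test_step_when_all_cells_ice_together(self):
        df = pd.DataFrame({"rate": 10.0, "cell_id": range(4),
                           "event_T": 271.65, "mechanism": "SCN",
                           "label": "darkening"})
        obs = empirical_pif(IIFEventTable(df, T_start=272.65, T_end=223.15),
                            np.array([272.65, 271.66, 271.64]))
        vals = obs.data.sort_values("T", ascending=False)["pif_both"].to_numpy()
        assert list(vals) == [0.0, 0.0, 1.0]

    def test_all_censored_gives_zero(self):
        df = pd.DataFrame({"rate": 10.0, "cell_id": range(3),
                           "event_T": np.nan, "mechanism": "",
                           "label": "none"})
        obs = empirical_pif(IIFEventTable(df, T_start=272.65, T_end=223.15),
                            np.array([260.15, 250.15]))
        assert (obs.data["pif_both"] == 0.0).all()

    def test_empty_rejected(self):
        tbl = IIFEventTable(pd.DataFrame(columns=["rate", "cell_id", "event_T",
                                                  "mechanism", "label"]),
                            T_start=272.65, T_end=223.15)
        with pytest.raises(ValueError):
            empirical_pif(tbl, np.array([260.0]))


def test_convergence_rate_with_cells():
    """Empirical-vs-analytic PIF error shrinks roughly as n^-1/2."""
    errs = []
    for n in (100, 400, 1600):
        gt = replace(cp.default_ground_truth(seed=3), rates_iif=(60.0,),
                     cells_per_rate_iif=n)
        ev = simulate_iif_events(gt, 60.0)
        grid = np.arange(gt.T_start, gt.T_end_iif - 1e-9, -2.0)
        emp = empirical_pif(ev, grid)
        traj = cp.integrate_water_transport(
            cp.CoolingProtocol(B=60.0, T_start=gt.T_start, T_end=gt.T_end_iif),
            gt.cell)
        curve = compute_pif_curve(traj, gt.scn, gt.vcn)
        ana = np.interp(emp.data["T"].to_numpy(), curve.T[::-1],
                        curve.pif_total[::-1])
        errs.append(np.sqrt(np.mean((emp.data["pif_both"].to_numpy() - ana) ** 2)))
    assert errs[2] < errs[0]
    assert errs[2] < 0.025
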