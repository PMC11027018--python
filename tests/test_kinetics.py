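import numpy as np
import pytest
from dataclasses import replace

from etqsp import kinetics as kin
from etqsp.kinetics import (AntagonistSpec, ET1KineticParams, ET1KineticState,
                            baseline_occupancy, baseline_steady_state,
                            et1_derivatives, simulate_et1)
from etqsp.protocols import DoseEvent, Protocol, build_bohm_protocol


def small_params(**over):
    base = dict(
        bigET1_production_rate=1.0, k_ECE=0.2, k_tp=1.0, k_pt=2.0,
        V_tissue=10.0, V_plasma=3.0, kon_A=0.01, koff_A=0.5, kon_B=0.01,
        koff_B=0.5, k_int_A=0.2, k_int_B=1.0, R_A_tissue=5.0,
        R_B_tissue=50.0, R_A_plasma=5.0, R_B_plasma=10.0)
    base.update(over)
    return ET1KineticParams(**base)


class TestParamsInvariants:
    def test_kd_properties(self):
        p = small_params()
        assert p.Kd_A == pytest.approx(50.0)
        assert p.Kd_B == pytest.approx(50.0)

    def test_renal_etb_dominance_enforced(self):
        with pytest.raises(ValueError):
            small_params(R_B_tissue=4.0, R_A_tissue=5.0)

    def test_positive_rates_enforced(self):
        with pytest.raises(ValueError):
            small_params(kon_A=0.0)
        with pytest.raises(ValueError):
            small_params(bigET1_production_rate=-1.0)

    def test_antagonist_selectivity_checks(self):
        with pytest.raises(ValueError):
            AntagonistSpec("X", Kd_A=10.0, Kd_B=1.0, plasma_halflife=10.0,
                           eta_selective=True)
        with pytest.raises(ValueError):
            AntagonistSpec("X", Kd_A=1.0, Kd_B=10.0, plasma_halflife=10.0,
                           eta_selective=False)
        ok = AntagonistSpec("X", Kd_A=1.0, Kd_B=100.0, plasma_halflife=10.0,
                            eta_selective=True)
        assert ok.Kd_B / ok.Kd_A > 1


class TestDerivatives:
    def test_steady_state_derivatives_vanish(self):
        p = small_params()
        ss = baseline_steady_state(p)
        dy = et1_derivatives(ss, p)
        for name in ["bigET1_tissue", "ET1_tissue", "ET1_plasma",
                     "bound_A_tissue", "bound_B_tissue", "bound_A_plasma",
                     "bound_B_plasma"]:
            assert abs(getattr(dy, name)) < 1e-9

    def test_negative_state_rejected(self):
        p = small_params()
        with pytest.raises(ValueError, match="negative concentration"):
            et1_derivatives(ET1KineticState(ET1_plasma=-1.0), p)

    def test_unknown_agent_rejected(self):
        p = small_params()
        with pytest.raises(ValueError, match="unknown infused agent"):
            et1_derivatives(ET1KineticState(), p, {"bosentan": 1.0})
        with pytest.raises(ValueError, match="non-negative"):
            et1_derivatives(ET1KineticState(), p, {"ET1": -5.0})

    def test_irreversible_binding_rises_monotonically_to_capacity(self):
        """With koff_B -> 0 a plasma ET-1 step drives bound_B toward its
        receptor ceiling along the closed-form irreversible-binding curve."""
        p = small_params(koff_B=1e-9, k_int_B=0.05, k_pt=1e-9, k_tp=1e-9,
                         bigET1_production_rate=0.0, k_cl_plasma=0.0,
                         kon_A=1e-12)
        L0 = 1000.0  # large step, roughly constant free ligand early on
        y0 = ET1KineticState(ET1_plasma=L0)
        proto = Protocol(study="bohm", arm="x", t_pre=0.0, t_end=10.0)
        t = np.linspace(0, 10, 201)
        traj = simulate_et1(p, proto, t, y0=y0)
        b = traj["bound_B_plasma"]
        i_peak = int(np.argmax(b))
        assert np.all(np.diff(b[: i_peak + 1]) > -1e-9)
        assert b.max() <= p.R_B_plasma + 1e-6
        assert b[i_peak] == pytest.approx(p.R_B_plasma, rel=0.02)
        # closed form db/dt = kon*L*(R-b) - kint*b with L ~ constant early:
        # b(t) = R' (1 - exp(-(kon L + kint) t)), R' = kon L R/(kon L + kint)
        k = p.kon_B * L0 + p.k_int_B
        i_early = np.searchsorted(t, 0.2)
        expected = (p.kon_B * L0 * p.R_B_plasma / k) * (
            1 - np.exp(-k * t[i_early]))
        assert b[i_early] == pytest.approx(expected, rel=0.08)

    def test_etb_blockade_raises_steady_plasma_et1(self, model):
        """ET_B antagonism removes the dominant clearance route, so free
        plasma ET-1 settles strictly above baseline."""
        p = model.kinetics
        ss = baseline_steady_state(p)
        bq788 = model.antagonists["BQ788"]
        proto = Protocol(
            study="bohm", arm="x", t_pre=0.0, t_end=600.0,
            events=[DoseEvent("BQ788", 4.0, "nmol/kg/min", 0.0, 600.0)])
        t = np.linspace(0, 600, 601)
        traj = simulate_et1(p, proto, t, antagonists={"BQ788": bq788}, y0=ss)
        assert traj.ET1_plasma[-1] > 1.5 * ss.ET1_plasma


class TestBaselineOccupancy:
    def test_zero_production_gives_zero_occupancy(self):
        p = small_params(bigET1_production_rate=0.0)
        occ = baseline_occupancy(p)
        assert all(abs(v) < 1e-12 for v in occ.values())

    def test_equilibrium_with_internalization_balance(self, kin_params):
        """Occupancies satisfy kon*L*(R_tot - bound) = (koff + k_int)*bound."""
        p = kin_params
        ss = baseline_steady_state(p)
        checks = [
            (p.kon_A, p.koff_A, p.k_int_A, ss.ET1_tissue, p.R_A_tissue,
             ss.bound_A_tissue),
            (p.kon_B, p.koff_B, p.k_int_B, ss.ET1_tissue, p.R_B_tissue,
             ss.bound_B_tissue),
            (p.kon_A, p.koff_A, p.k_int_A, ss.ET1_plasma, p.R_A_plasma,
             ss.bound_A_plasma),
            (p.kon_B, p.koff_B, p.k_int_B, ss.ET1_plasma, p.R_B_plasma,
             ss.bound_B_plasma),
        ]
        for kon, koff, kint, L, R, b in checks:
            assert kon * L * (R - b) == pytest.approx((koff + kint) * b,
                                                      rel=1e-8)

    def test_tissue_etb_occupancy_exceeds_eta(self):
        # equal affinity, higher ET_B density => higher ET_B occupancy
        p = small_params()
        occ = baseline_occupancy(p)
        assert occ[("ET_B", "tissue")] > occ[("ET_A", "tissue")]


class TestSimulation:
    def test_empty_protocol_stays_flat_at_baseline(self, kin_params):
        proto = Protocol(study="rabelink", arm="x", t_pre=0.0, t_end=240.0)
        t = np.linspace(0, 240, 241)
        traj = simulate_et1(kin_params, proto, t)
        drift = np.abs(traj.ET1_plasma / traj.ET1_plasma[0] - 1.0)
        assert drift.max() < 1e-6

    def test_infusion_rises_then_decays_toward_baseline(self, kin_params):
        proto = Protocol(
            study="rabelink", arm="x", t_pre=0.0, t_end=240.0,
            events=[DoseEvent("ET1", 0.2, "pmol/kg/min", 0.0, 60.0)])
        t = np.linspace(0, 240, 481)
        traj = simulate_et1(kin_params, proto, t)
        base = traj.ET1_plasma[0]
        i_end = np.searchsorted(t, 60.0)
        assert traj.ET1_plasma[i_end] > 1.5 * base
        assert traj.ET1_plasma[-1] == pytest.approx(base, rel=0.02)
        assert traj.ET1_plasma[-1] < traj.ET1_plasma[i_end]

    def test_doubling_plasma_volume_halves_early_increment(self, kin_params):
        """Before binding saturates, the early concentration increment of an
        infusion scales as 1/V_plasma."""
        proto = Protocol(
            study="rabelink", arm="x", t_pre=0.0, t_end=1.0,
            events=[DoseEvent("ET1", 0.2, "pmol/kg/min", 0.0, 1.0)])
        t = np.linspace(0, 1.0, 51)  # early times only
        tr1 = simulate_et1(kin_params, proto, t)
        p2 = replace(kin_params, V_plasma=2 * kin_params.V_plasma)
        tr2 = simulate_et1(p2, proto, t, y0=baseline_steady_state(p2))
        inc1 = tr1.ET1_plasma[5] - tr1.ET1_plasma[0]
        inc2 = tr2.ET1_plasma[5] - tr2.ET1_plasma[0]
        assert inc1 / inc2 == pytest.approx(2.0, rel=0.05)

    def test_mass_balance_over_six_hours(self, model):
        """Cumulative internalization + pool change balances production +
        infusion to < 1e-6 relative."""
        proto = Protocol(
            study="rabelink", arm="x", t_pre=0.0, t_end=360.0,
            events=[DoseEvent("ET1", 0.4, "pmol/kg/min", 30.0, 90.0),
                    DoseEvent("ET1", 0.8, "pmol/kg/min", 120.0, 180.0)])
        t = np.linspace(0, 360, 721)
        traj = simulate_et1(model.kinetics, proto, t, rtol=1e-10,
                            atol=1e-12, method="bdf")
        assert traj.mass_balance_error() < 1e-6

    def test_trajectory_invariants_hold_pointwise(self, model):
        proto = build_bohm_protocol("BQ788")
        t = np.arange(proto.t_pre, proto.t_end + 0.25, 0.25)
        traj = simulate_et1(model.kinetics, proto, t,
                            antagonists=model.antagonists)
        assert traj.y[:, :13].min() >= 0.0
        p = model.kinetics
        assert np.all(traj["bound_A_tissue"] + traj["ant_bound_A_tissue"]
                      <= p.R_A_tissue * (1 + 1e-9))
        assert np.all(traj["bound_B_tissue"] + traj["ant_bound_B_tissue"]
                      <= p.R_B_tissue * (1 + 1e-9))

    def test_agreement_with_stiff_reference_solver(self, model):
        """LSODA production path matches an independent BDF solve at tight
        tolerance on a three-dose protocol (max relative difference < 1e-4)."""
        proto = Protocol(
            study="bohm", arm="x", t_pre=-10.0, t_end=120.0,
            events=[DoseEvent("BQ788", 4.0, "nmol/kg/min", 0.0, 15.0),
                    DoseEvent("ET1", 4.0, "pmol/kg/min", 30.0, 50.0),
                    DoseEvent("ET1", 1.0, "pmol/kg/min", 80.0, 100.0)])
        t = np.arange(-10.0, 120.5, 0.5)
        lsoda = simulate_et1(model.kinetics, proto, t,
                             antagonists=model.antagonists)
        bdf = simulate_et1(model.kinetics, proto, t,
                           antagonists=model.antagonists,
                           rtol=1e-10, atol=1e-12, method="bdf")
        scale = np.maximum(np.abs(bdf.y[:, :7]).max(axis=0), 1e-9)
        err = np.max(np.abs(lsoda.y[:, :7] - bdf.y[:, :7]) / scale)
        assert err < 1e-4

    def test_dose_outside_grid_rejected(self, kin_params):
        proto = Protocol(
            study="rabelink", arm="x", t_pre=0.0, t_end=240.0,
            events=[DoseEvent("ET1", 0.2, "pmol/kg/min", 0.0, 200.0)])
        with pytest.raises(ValueError, match="outside the time grid"):
            simulate_et1(kin_params, proto, np.linspace(0, 100, 11))

    def test_one_antagonist_per_protocol(self, model):
        proto = Protocol(
            study="bohm", arm="x", t_pre=0.0, t_end=60.0,
            events=[DoseEvent("BQ123", 5.0, "nmol/kg/min", 0.0, 30.0),
                    DoseEvent("BQ788", 4.0, "nmol/kg/min", 0.0, 15.0)])
        with pytest.raises(ValueError, match="one antagonist"):
            simulate_et1(model.kinetics, proto, np.linspace(0, 60, 61),
                         antagonists=model.antagonists)
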