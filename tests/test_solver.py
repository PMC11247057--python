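"""Flow-solver physics: discretization, conservation, verification problems."""

import numpy as np
import pytest
from scipy.optimize import root

from cowflow.boundary import InflowWaveform, WindkesselOutlet
from cowflow.constitutive import ParamRow, TubeLawParams, VesselParameterTable, wave_speed
from cowflow.mesh import discretize
from cowflow.network import assemble_network
from cowflow.reduction import reduce_centerline
from cowflow.solver import (BoundaryConditions, SimulationResult, SolverSettings,
                            TransientSolver, periodicity_metric, run_simulation)
from .conftest import constant_wave, single_vessel_setup, straight_centerline, y_network_setup


class TestDiscretize:
    @pytest.mark.parametrize("length,expected", [(0.25, 3), (0.1, 1), (0.05, 1), (1.0, 10)])
    def test_element_counts(self, length, expected):
        net = assemble_network(
            [reduce_centerline(straight_centerline("V", length, 0.1), 0.01)],
            {"V": ("a", "b")}, inlet_labels=["V"])
        params = VesselParameterTable([ParamRow("V", 0.01, 1e6, 1e5, 90.0, 1e4, 1e-7)])
        mesh = discretize(net, params, max_elem=0.1)
        assert mesh.n_elements == expected
        assert np.all(mesh.h <= 0.1 + 1e-12)

    def test_cohort_mean_basilar_element_count(self, mean_cow, params_table):
        mesh = discretize(mean_cow, params_table, max_elem=0.1)
        ba = mesh.elements_of("BA")
        assert ba.size == 31  # ceil(3.04 / 0.1)

    def test_nodal_reference_areas_follow_profile(self, mean_cow, params_table):
        mesh = discretize(mean_cow, params_table, max_elem=0.1)
        els = mesh.elements_of("BA")
        r_first = mean_cow.arteries["BA"].segments[0].r0
        assert mesh.a0_l[els[0]] == pytest.approx(np.pi * r_first**2, rel=1e-12)


class TestEquilibrium:
    def test_zero_inflow_equilibrium_is_a_fixed_point(self):
        net, params, _ = single_vessel_setup()
        wk = WindkesselOutlet.from_terminal(5000.0, 1e-7, Pv=10.0)
        bcs = BoundaryConditions({"V": constant_wave(0.0)}, {"V": wk})
        mesh = discretize(net, params, max_elem=0.1, pext_mmhg=0.0)
        solver = TransientSolver(mesh, bcs, SolverSettings(dt=1e-3, n_cycles=1,
                                                           analysis_cycles=1),
                                 initial_pressure_mmhg=10.0)
        u0 = solver.state.u.copy()
        for _ in range(5):
            solver.advance()
        assert np.allclose(solver.state.u, u0, atol=1e-8)


class TestSteadyVerification:
    def test_rigid_limit_poiseuille_pressure_drop(self):
        # beta scaled x1e4 makes the wall effectively rigid; a constant unit
        # inflow must then produce dP = 8 pi mu L Q / A^2 along the vessel
        L, A, Q, mu = 1.0, 0.1, 1.0, 0.04
        net, params, bcs = single_vessel_setup(length=L, area=A,
                                               beta_pa_cm=136122.4e4, q=Q)
        st = SolverSettings(dt=1e-3, n_cycles=2, analysis_cycles=1)
        mesh = discretize(net, params, max_elem=0.1)
        solver = TransientSolver(mesh, bcs, st)
        for _ in range(2000):
            solver.advance()
        p = solver.state.P
        nid_in = mesh.inlet_nodes[0][0]
        nid_out = mesh.outlet_nodes[0][0]
        dp = p[nid_in] - p[nid_out]
        expected = 8 * np.pi * mu * L * Q / A**2  # 100.53 dyn/cm^2
        assert dp == pytest.approx(expected, rel=0.01)

    def test_steady_state_matches_independent_root_finder(self):
        """Time marching and a brute-force root finder must land on the same
        solution of the steady nonlinear system (Y-bifurcation)."""
        net, params, bcs = y_network_setup(rt1=8000.0, rt2=12000.0)
        mesh = discretize(net, params, max_elem=0.25)
        solver = TransientSolver(mesh, bcs, SolverSettings(dt=1e-3, n_cycles=2,
                                                           analysis_cycles=1))
        for _ in range(2000):
            solver.advance()
        u_march = solver.state.u.copy()
        sol = root(solver.steady_residual, u_march * 1.01 + 1.0, method="hybr", tol=1e-13)
        assert sol.success
        rel = np.abs(sol.x - u_march) / np.maximum(np.abs(u_march), 1e-6)
        assert rel.max() < 1e-6

    def test_outlet_flows_sum_to_inlet_flow(self):
        net, params, bcs = y_network_setup(q=2.0)
        st = SolverSettings(dt=1e-3, n_cycles=4, analysis_cycles=2, newton_tol=1e-12)
        res = run_simulation(net, params=params, settings=st, bcs=bcs)
        total_out = sum(res.outlet_mean_flows().values())
        assert total_out == pytest.approx(2.0, rel=1e-8)

    def test_doubling_terminal_resistance_keeps_total_flow_raises_pressure(self):
        # inflow is prescribed, so total flow is invariant; mean pressures
        # must rise with the terminal resistance
        st = SolverSettings(dt=1e-3, n_cycles=4, analysis_cycles=2)
        net, params, bcs = y_network_setup()
        res1 = run_simulation(net, params=params, settings=st, bcs=bcs)
        net2, params2, bcs2 = y_network_setup(rt1=16000.0, rt2=16000.0)
        res2 = run_simulation(net2, params=params2, settings=st, bcs=bcs2)
        tot1 = sum(res1.outlet_mean_flows().values())
        tot2 = sum(res2.outlet_mean_flows().values())
        assert tot2 == pytest.approx(tot1, rel=1e-6)
        for v in ("P", "D1", "D2"):
            assert res2.mean_pressure(v) > res1.mean_pressure(v) + 1.0

    def test_symmetric_bifurcation_splits_evenly(self):
        net, params, bcs = y_network_setup(r_d1=0.15, r_d2=0.15)
        st = SolverSettings(dt=1e-3, n_cycles=4, analysis_cycles=2)
        res = run_simulation(net, params=params, settings=st, bcs=bcs)
        out = res.outlet_mean_flows()
        assert out["D1"] == pytest.approx(out["D2"], rel=1e-9)


class TestWavePropagation:
    def test_small_pulse_speed_matches_linear_theory(self):
        L, r0 = 16.0, 0.2
        A0 = np.pi * r0**2
        beta = 1e4  # Pa.cm
        c = wave_speed(TubeLawParams(beta=beta, A0=A0), rho=1.04)
        zc = 1.04 * c / A0 / 10.0  # characteristic impedance, Pa.s/cm^3
        net = assemble_network(
            [reduce_centerline(straight_centerline("V", L, r0), 0.01)],
            {"V": ("n0", "n1")}, inlet_labels=["V"])
        params = VesselParameterTable([ParamRow("V", 0.01, 1e6, beta, 0.0, zc, 1e-6)])
        T = 0.4

        def sig(t):
            t = np.asarray(t, float)
            return 0.2 * np.exp(-(((np.mod(t, T)) - 0.06) / 0.008) ** 2)

        wave = InflowWaveform(period=T, mean=0.02, peak=0.2, signal=sig)
        wk = WindkesselOutlet(R1=zc, R2=zc, C=1e-6, Pv=0.0)  # near-matched outlet
        bcs = BoundaryConditions({"V": wave}, {"V": wk})
        res = run_simulation(net, params=params, settings=SolverSettings(
            dt=2e-4, n_cycles=1, analysis_cycles=1), bcs=bcs, pext_mmhg=0.0,
            probes={"p1": ("V", 0.2), "p2": ("V", 0.7)}, initial_pressure_mmhg=0.0)

        def peak_time(rec):
            q = rec["Q"]
            i = int(np.argmax(q))
            y0, y1, y2 = q[i - 1], q[i], q[i + 1]
            dd = y0 - 2 * y1 + y2
            return rec["t"][i] + (0.5 * (y0 - y2) / dd if dd else 0.0) * 2e-4

        dt_travel = peak_time(res.probes["p2"]) - peak_time(res.probes["p1"])
        measured = 0.5 * L / dt_travel
        assert measured == pytest.approx(c, rel=0.05)


class TestTemporalOrder:
    def test_bdf2_observed_order_at_least_1_8(self):
        L, r0 = 2.0, 0.15
        net = assemble_network(
            [reduce_centerline(straight_centerline("V", L, r0), 0.01)],
            {"V": ("n0", "n1")}, inlet_labels=["V"])
        params = VesselParameterTable([ParamRow("V", 0.01, 1e6, 2e4, 10.0, 2000.0, 1e-6)])
        T, qm = 0.05, 1.0

        def sig(t):
            t = np.asarray(t, float)
            return qm * 0.5 * (1 - np.cos(2 * np.pi * t / T))

        wave = InflowWaveform(period=T, mean=qm * 0.5, peak=qm, signal=sig)

        def final_state(dt):
            wk = WindkesselOutlet(R1=400.0, R2=1600.0, C=1e-6, Pv=10.0)
            bcs = BoundaryConditions({"V": wave}, {"V": wk})
            mesh = discretize(net, params, max_elem=0.1, pext_mmhg=0.0)
            s = TransientSolver(mesh, bcs, SolverSettings(dt=dt, n_cycles=1,
                                                          analysis_cycles=1,
                                                          newton_tol=1e-12),
                                initial_pressure_mmhg=10.0)
            for _ in range(int(round(T / dt))):
                s.advance()
            return s.state.u.copy()

        ref = final_state(T / 1600)
        e1 = np.linalg.norm(final_state(T / 100) - ref)
        e2 = np.linalg.norm(final_state(T / 200) - ref)
        assert np.log2(e1 / e2) >= 1.8


class TestPeriodicityMetric:
    def _result_with_cycles(self, c1, c2):
        snaps = np.vstack([c1, c2])
        n = c1.shape[0]
        return SimulationResult(
            time=np.arange(2 * n, dtype=float), vessel_labels=["V"],
            vessel_Q=np.zeros((2 * n, 1)), vessel_P=np.zeros((2 * n, 1)),
            vessel_A=np.ones((2 * n, 1)), inlet_labels=["V"],
            inlet_Q=np.ones((2 * n, 1)), outlet_labels=["V"],
            outlet_Q=np.ones((2 * n, 1)), steps_per_cycle=n, analysis_cycles=2,
            decimation=1, snapshots_Q=snaps, max_junction_mass_residual=0.0)

    def test_identical_cycles_give_zero(self):
        c = np.random.default_rng(0).normal(size=(50, 7))
        assert periodicity_metric(self._result_with_cycles(c, c.copy())) == 0.0

    def test_uniform_one_percent_growth_gives_0_01(self):
        c = np.random.default_rng(1).normal(size=(50, 7))
        assert periodicity_metric(self._result_with_cycles(c, 1.01 * c)) == \
            pytest.approx(0.01, rel=1e-12)

    def test_decreasing_while_converging(self):
        # successive cycle pairs of a converging pulsatile run shrink the metric
        net, params, _ = y_network_setup()
        T = 0.25

        def sig(t):
            u = np.mod(np.asarray(t, float) / T, 1.0)
            return 1.0 + 0.8 * np.sin(2 * np.pi * u)

        wave = InflowWaveform(period=T, mean=1.0, peak=1.8, signal=sig)
        bcs = BoundaryConditions({"P": wave},
                                 {"D1": WindkesselOutlet.from_terminal(8000.0, 1e-5),
                                  "D2": WindkesselOutlet.from_terminal(8000.0, 1e-5)})
        st = SolverSettings(dt=1e-3, n_cycles=5, analysis_cycles=5)
        res = run_simulation(net, params=params, settings=st, bcs=bcs)
        per = res.steps_per_cycle // res.decimation
        snaps = res.snapshots_Q
        metrics = []
        for k in range(4):
            a = snaps[k * per:(k + 1) * per]
            b = snaps[(k + 1) * per:(k + 2) * per]
            metrics.append(np.linalg.norm(b - a) / np.linalg.norm(a))
        assert metrics == sorted(metrics, reverse=True)


class TestJunctionConservation:
    def test_mass_balance_at_junction_every_snapshot(self):
        net, params, bcs = y_network_setup()
        st = SolverSettings(dt=1e-3, n_cycles=3, analysis_cycles=2)
        res = run_simulation(net, params=params, settings=st, bcs=bcs)
        assert res.max_junction_mass_residual <= 1e-8

    def test_intersegment_pressure_continuity_is_structural(self, mean_cow, params_table):
        # segments of one artery share nodes, so P and Q are continuous by
        # construction; verify the mesh wiring reflects that
        mesh = discretize(mean_cow, params_table)
        for lbl in ("BA", "R ICA G1"):
            els = mesh.elements_of(lbl)
            assert np.array_equal(mesh.node_r[els[:-1]], mesh.node_l[els[1:]])
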