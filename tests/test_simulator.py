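"""Ventilated-shell simulator: waveform, solver physics, signals, clouds."""

import numpy as np
import pytest

from pulmoflow.simulator import (
    BASELINE_PARAMETERS,
    CMH2O_TO_KPA,
    EstimationError,
    LungSignals,
    ParameterVector,
    ShellGeometry,
    ShellMesh,
    VentilatorWaveform,
    airway_pressure,
    compute_signals,
    estimate_lung_mechanics,
    project_to_cloud,
    run_simulation,
    scatter_observation_nodes,
)


class TestWaveform:
    def test_plateau_value_in_kpa(self):
        w = VentilatorWaveform(pip=6.0)
        assert airway_pressure(w.t_insp, w) == pytest.approx(0.588399, abs=1e-9)

    def test_zero_during_expiration_and_at_onset(self):
        w = VentilatorWaveform(pip=6.0)
        assert airway_pressure(0.0, w) == 0.0
        for t in (1.5, 2.0, 2.99, 4.2, 5.95):
            assert airway_pressure(t, w) == 0.0

    def test_linear_ramp_midpoint(self):
        w = VentilatorWaveform(pip=8.0, t_ramp=0.4)
        assert airway_pressure(0.2, w) == pytest.approx(
            0.5 * 8.0 * CMH2O_TO_KPA, rel=1e-12
        )

    def test_periodicity(self):
        w = VentilatorWaveform(pip=5.0)
        t = np.linspace(0, w.period, 61)
        np.testing.assert_allclose(
            airway_pressure(t, w), airway_pressure(t + w.period, w), atol=1e-12
        )

    def test_bounds_and_errors(self):
        w = VentilatorWaveform(pip=9.0)
        vals = airway_pressure(w.times, w)
        assert np.all(vals >= 0) and np.all(vals <= 9.0 * CMH2O_TO_KPA + 1e-12)
        with pytest.raises(ValueError):
            airway_pressure(-0.1, w)
        with pytest.raises(ValueError):
            VentilatorWaveform(pip=5.0, t_ramp=0.0)
        with pytest.raises(ValueError):
            VentilatorWaveform(pip=5.0, n_steps=121)

    def test_peak_index_is_last_cycle_end_inspiration(self):
        w = VentilatorWaveform(pip=6.0)
        assert w.times[w.peak_index] == pytest.approx(4.0)
        assert airway_pressure(w.times[w.peak_index], w) == pytest.approx(
            6.0 * CMH2O_TO_KPA
        )


class TestSolverPhysics:
    def test_zero_pip_keeps_reference_state(self):
        xi = ParameterVector(0.0, 0.3567, 1.075, 0.2782, 5766.0, 1e4, 0.08)
        sol, resp = run_simulation(
            xi, "L", waveform=VentilatorWaveform(pip=0.0, n_steps=24, n_cycles=1)
        )
        assert np.all(sol.displacement == 0.0)
        assert np.all(sol.p_alv == 0.0)
        for q in ("ux", "uy", "uz", "palv"):
            assert np.all(resp.field(q) == 0.0)

    def test_plateau_steady_state_is_uniform_pressure(self):
        # hold the plateau for a long inspiration: Darcy flow equilibrates
        # and the pore pressure becomes spatially uniform at the plateau
        w = VentilatorWaveform(pip=6.0, t_insp=4.0, t_exp=2.0, n_cycles=1, n_steps=60)
        sol, _ = run_simulation(BASELINE_PARAMETERS, "L", waveform=w)
        k = int(round(4.0 / w.dt)) - 1  # end of the long inspiration
        plateau = 6.0 * CMH2O_TO_KPA
        np.testing.assert_allclose(sol.p_alv[k], plateau, rtol=1e-5)
        # zero Darcy flux everywhere: inlet influx ~ 0
        assert abs(sol.influx_ml_s[k]) < 1e-5 * np.abs(sol.influx_ml_s).max()

    @pytest.mark.parametrize("fixture", ["baseline_lf", "baseline_hf"])
    def test_discrete_mass_conservation(self, fixture, request):
        sol, _ = request.getfixturevalue(fixture)
        dt = sol.waveform.dt
        dv = np.diff(sol.volume_ml) / dt
        err = np.abs(dv - sol.influx_ml_s[1:]).max()
        assert err <= 1e-6 * np.abs(sol.influx_ml_s).max()

    def test_state_invariants(self, baseline_hf):
        sol, _ = baseline_hf
        assert np.all(np.diff(sol.phi, axis=1) > 0)  # no interpenetration
        plateau = 6.0 * CMH2O_TO_KPA
        prescribed = airway_pressure(sol.times, sol.waveform)
        np.testing.assert_allclose(sol.p_alv[:, 0], prescribed, atol=1e-8 * plateau)
        assert np.all(sol.phi[0] == sol.mesh.nodes)

    def test_determinism_bit_identical(self):
        xi = BASELINE_PARAMETERS
        sol1, resp1 = run_simulation(xi, "L", cloud_seed=5)
        sol2, resp2 = run_simulation(xi, "L", cloud_seed=5)
        assert np.array_equal(sol1.phi, sol2.phi)
        assert np.array_equal(sol1.p_alv, sol2.p_alv)
        for q in ("ux", "uy", "uz", "palv"):
            assert np.array_equal(resp1.field(q), resp2.field(q))

    def test_grid_convergence_is_monotone(self):
        # discretization error against a 128-element reference decreases
        # monotonically with refinement: the LF -> HF gap is real
        geometry = ShellGeometry()
        w = VentilatorWaveform(pip=6.0, n_steps=30, n_cycles=1)
        sols = {}
        for n_el in (8, 16, 32, 64, 128):
            mesh = ShellMesh(geometry=geometry, n_el=n_el)
            sol, _ = run_simulation(
                BASELINE_PARAMETERS, "L", mesh=mesh, cloud_size=10, waveform=w
            )
            sols[n_el] = sol
        k = w.peak_index
        r_probe = np.linspace(geometry.r_inner, geometry.r_outer, 200)
        ref = np.interp(r_probe, sols[128].mesh.nodes, sols[128].displacement[k])
        errs = []
        for n_el in (8, 16, 32, 64):
            u = np.interp(r_probe, sols[n_el].mesh.nodes, sols[n_el].displacement[k])
            errs.append(np.linalg.norm(u - ref))
        assert all(a > b for a, b in zip(errs, errs[1:]))
        assert errs[0] > 0

    def test_fidelity_levels_strongly_correlated(self, table1_box_draws):
        # across the sampled box, LF and HF tidal volumes track each other:
        # the premise the multi-fidelity architecture exploits
        vol_l, vol_h = [], []
        for row in table1_box_draws[:20]:
            xi = ParameterVector.from_array(row)
            w = VentilatorWaveform(pip=xi.p_pip, n_steps=60, n_cycles=1)
            sol_l, _ = run_simulation(xi, "L", cloud_size=5, waveform=w)
            sol_h, _ = run_simulation(xi, "H", cloud_size=5, waveform=w)
            vol_l.append(sol_l.volume_ml.max())
            vol_h.append(sol_h.volume_ml.max())
        r = np.corrcoef(vol_l, vol_h)[0, 1]
        assert r > 0.9


class TestObservationCloud:
    def test_bounds_and_determinism(self):
        pts = scatter_observation_nodes(500, 5.0, 50.0, seed=4)
        radii = np.linalg.norm(pts, axis=1)
        assert np.all(radii >= 5.0) and np.all(radii <= 50.0)
        assert np.array_equal(pts, scatter_observation_nodes(500, 5.0, 50.0, seed=4))
        single = scatter_observation_nodes(1, 5.0, 50.0, seed=4)
        assert single.shape == (1, 3)

    def test_radial_distribution_follows_volume_law(self):
        from scipy.stats import kstest

        pts = scatter_observation_nodes(10_000, 5.0, 50.0, seed=1)
        radii = np.linalg.norm(pts, axis=1)

        def cdf(r):
            return (r**3 - 5.0**3) / (50.0**3 - 5.0**3)

        assert kstest(radii, cdf).pvalue > 0.01

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            scatter_observation_nodes(0, 5.0, 50.0, seed=1)
        with pytest.raises(ValueError):
            scatter_observation_nodes(10, 50.0, 5.0, seed=1)


class TestProjection:
    def test_axis_node_is_purely_radial(self, baseline_lf):
        sol, _ = baseline_lf
        cloud = np.array([[20.0, 0.0, 0.0], [0.0, -30.0, 0.0]])
        resp = project_to_cloud(sol, cloud)
        assert np.all(resp.uy[0] == 0.0) and np.all(resp.uz[0] == 0.0)
        assert np.all(resp.ux[1] == 0.0) and np.all(resp.uz[1] == 0.0)
        k = sol.waveform.peak_index
        ur = np.interp(20.0, sol.mesh.nodes, sol.displacement[k])
        assert resp.ux[0, k] == pytest.approx(ur, rel=1e-12)

    def test_displacement_magnitude_equals_radial(self, baseline_lf):
        sol, resp = baseline_lf
        radii = np.linalg.norm(resp.cloud, axis=1)
        k = sol.waveform.peak_index
        mag = np.sqrt(resp.ux[:, k] ** 2 + resp.uy[:, k] ** 2 + resp.uz[:, k] ** 2)
        ur = np.interp(radii, sol.mesh.nodes, sol.displacement[k])
        np.testing.assert_allclose(mag, np.abs(ur), rtol=1e-10, atol=1e-14)

    def test_fields_zero_at_t0_and_knot_exactness(self, baseline_lf):
        sol, resp = baseline_lf
        for q in ("ux", "uy", "uz", "palv"):
            assert np.all(resp.field(q)[:, 0] == 0.0)
        node_cloud = np.column_stack(
            [sol.mesh.nodes, np.zeros_like(sol.mesh.nodes), np.zeros_like(sol.mesh.nodes)]
        )
        resp_nodes = project_to_cloud(sol, node_cloud)
        np.testing.assert_array_equal(resp_nodes.palv, sol.p_alv.T)

    def test_extrapolation_refused(self, baseline_lf):
        sol, _ = baseline_lf
        with pytest.raises(ValueError):
            project_to_cloud(sol, np.array([[60.0, 0.0, 0.0]]))


class TestSignalsAndMechanics:
    def test_volume_starts_at_zero_and_flow_closes_cycle(self, baseline_hf):
        sol, _ = baseline_hf
        sig = compute_signals(sol)
        assert sig.volume_ml[0] == 0.0
        assert sig.v0_ml == pytest.approx(4 * np.pi / 3 * (50**3 - 5**3) / 1000.0)
        np.testing.assert_allclose(sig.paw_cmh2o, sol.waveform.pressure_cmh2o(sol.times))
        # net flow over the second (steady) cycle nearly cancels; flow is
        # dV/dt, so its exact cycle integral is the volume difference
        w = sol.waveform
        start = int(w.period / w.dt)
        net = sig.volume_ml[-1] - sig.volume_ml[start]
        assert abs(net) < 0.005 * sig.volume_ml.max()

    def test_parameter_recovery_oracle(self):
        # signals generated exactly from the equation of motion are inverted
        t = np.linspace(0, 6, 121)
        v = 300 * np.sin(np.pi * t / 3) ** 2
        vdot = np.gradient(v, t)
        crs_true, r_true = 50.0, 0.01
        paw = v / crs_true + r_true * vdot
        sig = LungSignals(times=t, paw_cmh2o=paw, volume_ml=v, flow_ml_s=vdot, v0_ml=500.0)
        crs, r = estimate_lung_mechanics(sig)
        assert crs == pytest.approx(crs_true, rel=1e-6)
        assert r == pytest.approx(r_true, rel=1e-6)

    def test_intercept_shift_leaves_estimates_unchanged(self):
        t = np.linspace(0, 6, 121)
        v = 300 * np.sin(np.pi * t / 3) ** 2
        vdot = np.gradient(v, t)
        paw = v / 50.0 + 0.01 * vdot
        sig0 = LungSignals(t, paw, v, vdot, 500.0)
        sig1 = LungSignals(t, paw + 3.5, v, vdot, 500.0)
        assert estimate_lung_mechanics(sig0) == pytest.approx(
            estimate_lung_mechanics(sig1), rel=1e-9
        )

    def test_scale_equivariance(self):
        t = np.linspace(0, 6, 121)
        v = 300 * np.sin(np.pi * t / 3) ** 2
        vdot = np.gradient(v, t)
        paw = v / 50.0 + 0.01 * vdot
        crs1, r1 = estimate_lung_mechanics(LungSignals(t, paw, v, vdot, 500.0))
        crs2, r2 = estimate_lung_mechanics(LungSignals(t, paw, 2 * v, 2 * vdot, 500.0))
        assert crs2 == pytest.approx(2 * crs1, rel=1e-9)
        assert r2 == pytest.approx(r1 / 2, rel=1e-9)

    def test_rank_deficient_signals_rejected(self):
        t = np.linspace(0, 6, 121)
        zeros = np.zeros_like(t)
        with pytest.raises(EstimationError):
            estimate_lung_mechanics(LungSignals(t, zeros, zeros, zeros, 500.0))

    def test_physiological_plausibility_of_baseline(self, baseline_hf):
        sol, _ = baseline_hf
        crs, r = estimate_lung_mechanics(compute_signals(sol))
        assert crs > 0 and r >= 0
        assert 1.0 < crs < 100.0  # mL/cmH2O, loosely physiological


class TestParameterVector:
    def test_array_round_trip(self):
        arr = BASELINE_PARAMETERS.as_array()
        assert ParameterVector.from_array(arr) == BASELINE_PARAMETERS

    def test_validation(self):
        with pytest.raises(ValueError):
            ParameterVector(-1.0, 0.3, 1.0, 0.2, 5000.0, 1e4, 0.08)
        with pytest.raises(ValueError):
            ParameterVector(6.0, 0.3, 1.0, 0.2, 5000.0, -1e4, 0.08)
        with pytest.raises(ValueError):
            ParameterVector.from_array(np.ones(6))
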