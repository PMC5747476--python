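import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trunkflow import geometry, hydraulics, units
from trunkflow.geometry import TrunkTopology, VesselKind, VesselSpec
from trunkflow.hydraulics import (
    NetworkSolver,
    OcclusionParams,
    ResistanceModel,
    flow_diagnostics,
    network_dissipation,
    occluded_resistance,
    poiseuille_resistance,
    solve_flows,
)


class TestResistanceLaws:
    def test_poiseuille_formula(self):
        assert poiseuille_resistance(1, 1, 1e-6) == pytest.approx(8e-6 / np.pi)

    def test_fourth_power_of_radius(self):
        assert poiseuille_resistance(10, 2, 1e-6) == pytest.approx(
            poiseuille_resistance(10, 1, 1e-6) / 16
        )

    def test_printed_ladder_conductances(self, printed_kappas):
        """The default DA/Se geometries reproduce the measured conductances."""
        k1, k2 = printed_kappas
        assert k1 == pytest.approx(9.4e5, rel=0.05)
        assert k2 == pytest.approx(3.9e4, rel=0.05)

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, -1, 1), (1, 1, 0)])
    def test_poiseuille_rejects_nonpositive(self, args):
        with pytest.raises(ValueError):
            poiseuille_resistance(*args)

    def test_occlusion_is_linear_in_cell_count(self):
        assert occluded_resistance(1e-5, 0, 1e-6) == 1e-5
        assert occluded_resistance(1e-5, 2, 1.01e-6) == pytest.approx(1.202e-5)

    def test_occlusion_rejects_negative_count(self):
        with pytest.raises(ValueError):
            occluded_resistance(1e-5, -1, 1e-6)

    def test_continuum_occupancy_matches_hematocrit_form(self, trunk12):
        """Continuum mode adds alpha * Hct * V / V_c = alpha * rho * V per vessel."""
        params = OcclusionParams.uniform(trunk12, 1e-6, rho=0.003)
        model = ResistanceModel(trunk12, params)
        se = trunk12.se_vessels[0]
        k = trunk12.vessels.index(se)
        hct = units.hematocrit_from_rho(params.rho, params.cell_volume)
        expected = 1e-6 * hct * se.volume / params.cell_volume
        assert model.total()[k] - model.bare[k] == pytest.approx(expected, rel=1e-12)


def _single_vessel():
    return TrunkTopology(
        vessels=(VesselSpec(1, VesselKind.SE, 1, 2, 100.0, 3.0),),
        n_se=1,
        inflow_vertex=1,
        zero_pressure_vertices=frozenset({2}),
    )


def _ladder_oracle(r_da, r_se, F):
    """Series-parallel reduction of the canonical ladder, tail-first.

    D_i is the resistance from DA vertex i to ground; the last DA segment
    runs straight to the grounded tail junction.
    """
    n = len(r_se)
    D = 0.0
    for i in range(n - 1, -1, -1):
        chain = r_da[i] + D
        D = 1.0 / (1.0 / r_se[i] + 1.0 / chain)
    pressures = []
    p = F * D
    flows_da, flows_se = [], []
    D_down = [None] * (n + 1)
    D_down[n] = 0.0
    for i in range(n - 1, -1, -1):
        chain = r_da[i] + D_down[i + 1]
        D_down[i] = 1.0 / (1.0 / r_se[i] + 1.0 / chain)
    for i in range(n):
        pressures.append(p)
        q_se = p / r_se[i]
        q_da = p / (r_da[i] + D_down[i + 1])
        flows_se.append(q_se)
        flows_da.append(q_da)
        p = p - r_da[i] * q_da
    return np.array(pressures), np.array(flows_da), np.array(flows_se)


class TestKirchhoffSolve:
    def test_single_vessel(self):
        t = _single_vessel()
        R = np.array([2.5e-5])
        state = solve_flows(t, R, 1.0)
        assert state.flows[0] == pytest.approx(1.0)
        assert state.pressure(1) == pytest.approx(2.5e-5)

    def test_two_rung_ladder_against_hand_solution(self):
        """Mesh analysis of the n=2 uniform ladder, solved by hand.

        With DA conductance g and Se conductance h the junction equations
        are F = g(p1-p2) + h p1 and g(p1-p2) = (g+h) p2, giving
        p1 = (2g+h)/g * p2 and p2 = F / ((2g+h)(g+h)/g - g).
        """
        t = geometry.build_trunk(2, geometry.default_geometry_table(2, uniform=True))
        R = ResistanceModel(t, OcclusionParams(), "continuum_whole_blood").total(
            np.zeros(4)
        )
        g, h = 1 / R[0], 1 / R[2]
        p2 = 1.0 / ((2 * g + h) * (g + h) / g - g)
        p1 = (2 * g + h) / g * p2
        state = solve_flows(t, R, 1.0)
        assert state.pressure(1) == pytest.approx(p1, rel=1e-12)
        assert state.pressure(2) == pytest.approx(p2, rel=1e-12)

    @pytest.mark.parametrize("n_se", [1, 2, 3])
    def test_matches_dense_and_series_parallel_oracles(self, n_se):
        rng = np.random.default_rng(n_se)
        t = geometry.build_trunk(n_se)
        r_all = 10.0 ** rng.uniform(-6, -4, 2 * n_se)
        state = solve_flows(t, r_all, 1.0)
        # dense oracle: assemble the Laplacian explicitly and invert
        g = 1 / r_all
        A = np.zeros((n_se, n_se))
        b = np.zeros(n_se)
        b[0] = 1.0
        for k, v in enumerate(t.vessels):
            for vert in (v.head_vertex, v.tail_vertex):
                if vert <= n_se:
                    A[vert - 1, vert - 1] += g[k]
            if v.head_vertex <= n_se and v.tail_vertex <= n_se:
                A[v.head_vertex - 1, v.tail_vertex - 1] -= g[k]
                A[v.tail_vertex - 1, v.head_vertex - 1] -= g[k]
        p_dense = np.linalg.inv(A) @ b
        for i in range(n_se):
            assert state.pressure(i + 1) == pytest.approx(p_dense[i], rel=1e-12)
        # series-parallel oracle
        p_sp, q_da, q_se = _ladder_oracle(r_all[:n_se], r_all[n_se:], 1.0)
        np.testing.assert_allclose(
            [state.pressure(i + 1) for i in range(n_se)], p_sp, rtol=1e-12
        )
        np.testing.assert_allclose(state.flows[:n_se], q_da, rtol=1e-12)
        np.testing.assert_allclose(state.flows[n_se:], q_se, rtol=1e-12)

    def test_eleven_fold_short_circuit(self, trunk12, whole_blood_solve):
        """Without occlusion the first Se carries ~11x the last Se's flow."""
        _, state = whole_blood_solve
        q = state.flows[[trunk12.vessels.index(v) for v in trunk12.se_vessels]]
        assert q[0] / q[-1] == pytest.approx(11.0, rel=0.20)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_flux_conservation_random_resistances(self, seed):
        rng = np.random.default_rng(seed)
        t = geometry.build_trunk(12)
        r = 10.0 ** rng.uniform(-7, -3, 24)
        state = solve_flows(t, r, 1.0)
        net = {i: 0.0 for i in range(1, 13)}
        for q, v in zip(state.flows, t.vessels):
            if v.head_vertex in net:
                net[v.head_vertex] -= q
            if v.tail_vertex in net:
                net[v.tail_vertex] += q
        assert abs(net[1] + 1.0) < 1e-10  # inflow enters vertex 1
        for i in range(2, 13):
            assert abs(net[i]) < 1e-10

    def test_monotonicity_in_se_resistance(self, trunk12):
        """Raising one Se's resistance lowers its flow, raises every other Se's."""
        model = ResistanceModel(trunk12, OcclusionParams(), "continuum_whole_blood")
        r = model.total(np.zeros(24))
        base = solve_flows(trunk12, r, 1.0)
        se_idx = [trunk12.vessels.index(v) for v in trunk12.se_vessels]
        bumped = r.copy()
        bumped[se_idx[5]] *= 2.0
        new = solve_flows(trunk12, bumped, 1.0)
        assert new.flows[se_idx[5]] < base.flows[se_idx[5]]
        for k in se_idx:
            if k != se_idx[5]:
                assert new.flows[k] >= base.flows[k]

    def test_unreachable_ground_rejected(self):
        t = _single_vessel()
        with pytest.raises(ValueError):
            solve_flows(t, np.array([-1.0]), 1.0)

    def test_solver_reuse_matches_one_shot(self, trunk12):
        model = ResistanceModel(trunk12, OcclusionParams(), "continuum_whole_blood")
        r = model.total(np.zeros(24))
        solver = NetworkSolver(trunk12)
        a = solver.solve(r, 2.0)
        b = solve_flows(trunk12, r, 2.0)
        np.testing.assert_array_equal(a.flows, b.flows)


class TestDissipation:
    def test_energy_identity(self, trunk12, whole_blood_solve):
        """Total viscous loss equals inflow times inlet pressure."""
        model, state = whole_blood_solve
        _, _, total = network_dissipation(state, model, np.zeros(24))
        assert total == pytest.approx(state.inflow * state.pressure(1), rel=1e-10)

    def test_decomposition_sums_to_r_q_squared(self, trunk12):
        params = OcclusionParams.uniform(trunk12, 1e-6, rho=0.003)
        model = ResistanceModel(trunk12, params)
        counts = np.zeros(24)
        counts[12:] = 2.0
        r = model.total(counts)
        state = solve_flows(trunk12, r, 1.0)
        plasma, cell, total = network_dissipation(state, model, counts)
        assert total == pytest.approx(float(np.sum(r * state.flows**2)), rel=1e-12)
        assert cell > 0
        assert plasma == pytest.approx(
            float(np.sum(model.bare * state.flows**2)), rel=1e-12
        )

    def test_quadratic_scaling_and_zero(self, trunk12, whole_blood_solve):
        model, state = whole_blood_solve
        _, _, total = network_dissipation(state, model, np.zeros(24))
        doubled = hydraulics.HydraulicState(
            pressures=state.pressures,
            resistances=state.resistances,
            flows=2 * state.flows,
            inflow=2 * state.inflow,
        )
        _, _, total2 = network_dissipation(doubled, model, np.zeros(24))
        assert total2 == pytest.approx(4 * total, rel=1e-12)
        zero = hydraulics.HydraulicState(
            pressures={}, resistances=state.resistances,
            flows=0 * state.flows, inflow=0.0,
        )
        assert network_dissipation(zero, model, np.zeros(24)) == (0.0, 0.0, 0.0)


class TestFlowDiagnostics:
    def test_trunk_womersley_number(self):
        d = flow_diagnostics(d=12.0, nu=5e-6, f=2.0, U=3e-3)
        assert d.womersley == pytest.approx(1.9e-2, rel=0.05)
        assert d.womersley < 1  # quasi-steady regime

    def test_zero_frequency(self):
        assert flow_diagnostics(12.0, 5e-6, 0.0, 3e-3).womersley == 0.0

    def test_entry_length_scale(self):
        # bare U d^2 / nu scale; the flow is fully developed over any vessel
        d = flow_diagnostics(d=12.0, nu=5e-6, f=2.0, U=3e-3)
        assert d.entry_length == pytest.approx(0.0864, rel=1e-6)
        assert d.entry_length < 0.3

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError):
            flow_diagnostics(12.0, 0.0, 2.0, 3e-3)


class TestViscosityModes:
    def test_continuum_mode_has_no_occlusion(self, trunk12):
        params = OcclusionParams.uniform(trunk12, 1e-5)
        model = ResistanceModel(trunk12, params, "continuum_whole_blood")
        assert np.all(model.alpha == 0)
        np.testing.assert_allclose(model.total(np.full(24, 5.0)), model.bare)

    def test_plasma_mode_occludes_only_se(self, trunk12):
        params = OcclusionParams.uniform(trunk12, 1e-5)
        model = ResistanceModel(trunk12, params, "plasma_cells")
        is_se = np.array([v.kind == VesselKind.SE for v in trunk12.vessels])
        assert np.all(model.alpha[~is_se] == 0)
        assert np.all(model.alpha[is_se] == 1e-5)

    def test_unknown_mode_rejected(self, trunk12):
        with pytest.raises(ValueError):
            ResistanceModel(trunk12, OcclusionParams(), "nonsense")

    def test_param_invariants(self):
        with pytest.raises(ValueError):
            OcclusionParams(mu_pl=6e-6)  # above whole blood
        with pytest.raises(ValueError):
            OcclusionParams(alpha_c={1: -1e-7})
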