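"""Viscosity law, linear flow solve and the coupled iteration."""

import math

import numpy as np
import pytest

from hemonet.network import BoundaryConditions, Node, VesselNetwork, VesselSegment
from hemonet.rheology import (
    SolverSettings,
    ViscosityModel,
    coupled_solve,
    relative_viscosity,
    segment_conductance,
    solve_flow,
)
from hemonet.synthetic import TreeSpec, build_symmetric_tree

from conftest import rbc_flux_residuals


class TestViscosityLaw:
    def test_large_diameter_anchor_at_reference_hematocrit(self):
        """Independent evaluation of the in-vivo law at d = 1000 um, H = 0.45."""
        # recomputed from the published constants with 40-digit arithmetic
        assert relative_viscosity(1000.0, 0.45) == pytest.approx(
            3.1979224062202887, rel=1e-12
        )

    @pytest.mark.parametrize("d", [5.0, 10.0, 30.0, 100.0, 1000.0])
    def test_monotone_in_hematocrit(self, d):
        values = [relative_viscosity(d, h) for h in np.linspace(0.0, 0.8, 17)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_plasma_viscosity_is_multiplicative(self):
        base = ViscosityModel(plasma_viscosity=1.2e-3)
        double = ViscosityModel(plasma_viscosity=2.4e-3)
        for d, h in [(8.0, 0.1), (30.0, 0.45), (200.0, 0.6)]:
            assert double.apparent_viscosity(d, h) == pytest.approx(
                2.0 * base.apparent_viscosity(d, h), rel=1e-14
            )

    def test_hematocrit_domain_error(self):
        with pytest.raises(ValueError):
            relative_viscosity(30.0, 1.0)

    def test_constant_law_stub(self):
        model = ViscosityModel(law="constant")
        assert relative_viscosity(8.0, 0.6, model) == 1.0


class TestLinearFlow:
    def test_single_segment_poiseuille_closed_form(self, minimal_network):
        bc = BoundaryConditions(inlet_hematocrit=0.0, pressures={"a": 100.0, "b": 0.0})
        model = ViscosityModel(law="constant", plasma_viscosity=1.2e-3)
        _, flows = solve_flow(minimal_network, bc, model=model)
        expected = math.pi * 25.0**4 * 100.0 / (128.0 * 1.2e-3 * 100.0)
        assert flows["s1"] == pytest.approx(expected, rel=1e-12)

    def test_symmetric_tree_splits_evenly(self, small_tree, tree_bc):
        _, flows = solve_flow(small_tree, tree_bc)
        assert flows["gen1_0"] == pytest.approx(flows["gen1_1"], rel=1e-12)
        assert flows["gen1_0"] + flows["gen1_1"] == pytest.approx(
            flows["gen0"], rel=1e-12
        )

    def test_interior_mass_balance(self, small_tree, tree_bc):
        _, flows = solve_flow(small_tree, tree_bc)
        qmax = max(abs(q) for q in flows.values())
        for nid in small_tree.nodes:
            if small_tree.node_role(nid) != "junction":
                continue
            net_q = sum(flows[s.id] for s in small_tree.in_segments(nid)) - sum(
                flows[s.id] for s in small_tree.out_segments(nid)
            )
            assert abs(net_q) / qmax < 1e-10

    def test_pressure_scaling_linearity(self, small_tree):
        """With fixed (stub) viscosity, scaling Dp scales all flows."""
        model = ViscosityModel(law="constant")
        bc1 = BoundaryConditions(inlet_hematocrit=0.2, pressures={"inlet": 500.0, "outlet": 0.0})
        bc3 = BoundaryConditions(inlet_hematocrit=0.2, pressures={"inlet": 1500.0, "outlet": 0.0})
        _, f1 = solve_flow(small_tree, bc1, model=model)
        _, f3 = solve_flow(small_tree, bc3, model=model)
        for sid in f1:
            assert f3[sid] == pytest.approx(3.0 * f1[sid], rel=1e-10)

    def test_flow_boundary_conditions(self):
        """Prescribed inflow emerges exactly at the pressure outlet."""
        net = VesselNetwork(
            nodes=[Node("a"), Node("b"), Node("c")],
            segments=[
                VesselSegment("s1", "a", "b", 100.0, 20.0),
                VesselSegment("s2", "b", "c", 50.0, 20.0),
            ],
        )
        bc = BoundaryConditions(
            inlet_hematocrit=0.1, pressures={"c": 0.0}, flows={"a": 1234.5}
        )
        _, flows = solve_flow(net, bc)
        assert flows["s1"] == pytest.approx(1234.5, rel=1e-12)
        assert flows["s2"] == pytest.approx(1234.5, rel=1e-12)


class TestCoupledSolve:
    def test_symmetric_tree_no_memory_converges_in_one_iteration(self, small_tree, tree_bc):
        """Decoupled limit: the first propagated field reproduces the input."""
        state = coupled_solve(small_tree, tree_bc, hs_rule="pries",
                              model=ViscosityModel(law="constant"))
        assert state.iterations == 1
        assert state.converged

    def test_decoupled_asymmetric_takes_at_most_two_iterations(self):
        """Stub viscosity with uneven splits: one solve plus one verification."""
        net = VesselNetwork(
            nodes=[Node("a"), Node("b"), Node("c1"), Node("c2")],
            segments=[
                VesselSegment("p", "a", "b", 100.0, 30.0,
                              meta={"turn": "straight", "cfl_thin_side": "none"}),
                VesselSegment("u", "b", "c1", 100.0, 23.8),
                VesselSegment("v", "b", "c2", 200.0, 23.8),
            ],
        )
        bc = BoundaryConditions(inlet_hematocrit=0.3, pressures={"a": 100.0, "c1": 0.0, "c2": 0.0})
        state = coupled_solve(net, bc, hs_rule="pries", model=ViscosityModel(law="constant"))
        assert state.iterations <= 2

    def test_global_conservation(self, small_tree, tree_bc):
        state = coupled_solve(small_tree, tree_bc, hs_rule="memory")
        inflow = state.flows["gen0"]
        outflow = state.flows["cgen0"]
        assert inflow == pytest.approx(outflow, rel=1e-10)

    def test_fixed_point_property(self, small_tree, tree_bc):
        """Re-running from a converged hematocrit field changes nothing."""
        first = coupled_solve(small_tree, tree_bc, hs_rule="memory")
        settings = SolverSettings()
        again = coupled_solve(small_tree, tree_bc, hs_rule="memory", settings=settings)
        for sid in first.hematocrit:
            assert again.hematocrit[sid] == pytest.approx(
                first.hematocrit[sid], abs=10 * settings.tolerance
            )
        assert again.iterations <= first.iterations

    def test_rbc_conservation_at_convergence(self, tree_bc):
        tree = build_symmetric_tree(TreeSpec(lmbda=4.0, generations=4))
        state = coupled_solve(tree, tree_bc, hs_rule="memory")
        assert rbc_flux_residuals(tree, state.flows, state.hematocrit) < 1e-12

    def test_rerouting_away_from_hemoconcentrated_child(self, tree_bc):
        """Higher hematocrit raises resistance: the enriched child of an
        interior bifurcation receives less than half the parent flow."""
        tree = build_symmetric_tree(TreeSpec(lmbda=4.0, generations=4))
        state = coupled_solve(tree, tree_bc, hs_rule="memory")
        checked = 0
        for g in range(2, 5):
            for pair in range(2 ** (g - 1)):
                a, b = f"gen{g}_{2 * pair}", f"gen{g}_{2 * pair + 1}"
                ha, hb = state.hematocrit[a], state.hematocrit[b]
                qa, qb = abs(state.flows[a]), abs(state.flows[b])
                if abs(ha - hb) > 1e-9:
                    rich_q = qa if ha > hb else qb
                    assert rich_q / (qa + qb) < 0.5
                    checked += 1
        assert checked > 0

    def test_nonconvergence_raises_with_diagnostics(self, small_tree, tree_bc):
        from hemonet.rheology import ConvergenceError

        with pytest.raises(ConvergenceError):
            coupled_solve(
                small_tree, tree_bc, hs_rule="memory",
                settings=SolverSettings(tolerance=1e-16, max_iterations=3),
            )
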