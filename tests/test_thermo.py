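"""Loop detection and detailed-balance constraint machinery."""

import numpy as np
import pytest

import textode as tx
from textode.compiler import compile_model
from textode.dsl import parse_model
from textode.simulate import SimulationCondition, integrate
from textode.thermo import (
    ThermoError,
    apply_constraints,
    assign_constraints,
    build_reversible_graph,
    constraint_report,
    cycle_basis,
    detect_and_constrain,
)

DIAMOND = tx.fixtures.make_diamond_model()


def _diamond():
    return compile_model(parse_model(DIAMOND))


def _set(model, params, **kw):
    for name, v in kw.items():
        params[model.parameter_index(name)] = v
    return params


class TestGraphAndCycles:
    def test_diamond_composition_graph(self):
        g = build_reversible_graph(_diamond())
        # compositions: {A,B},{AB},{AB,C},{ABC},{A,C},{AC},{AC,B}
        assert g.n_nodes == 7
        assert g.n_edges == 4

    def test_diamond_has_exactly_one_loop_with_alternating_signs(self):
        m = _diamond()
        cycles = cycle_basis(build_reversible_graph(m))
        assert len(cycles) == 1
        assert cycles[0].edges == ((0, 1), (1, 1), (2, -1), (3, -1))

    def test_irreversible_only_model_gives_empty_graph(self):
        m = compile_model(parse_model("A is degraded\nE phosphorylates S --> pS\n"))
        g = build_reversible_graph(m)
        assert g.n_edges == 0
        assert cycle_basis(g) == []

    def test_single_bind_has_no_cycle(self):
        m = compile_model(parse_model("A binds B --> AB\n"))
        assert cycle_basis(build_reversible_graph(m)) == []

    def test_tree_shaped_cascade_is_acyclic(self):
        m = compile_model(parse_model(
            "A binds B --> AB\nAB binds C --> ABC\nABC binds D --> ABCD\n"
        ))
        assert cycle_basis(build_reversible_graph(m)) == []

    def test_two_disjoint_diamonds_give_two_loops(self):
        text = DIAMOND.replace("@init A = 1\n@init B = 1\n@init C = 1\n", "")
        second = text.replace("A", "X").replace("B", "Y").replace("C", "Z")
        m = compile_model(parse_model(text + second))
        assert len(cycle_basis(build_reversible_graph(m))) == 2


class TestAssignment:
    def test_highest_indexed_reaction_loses_its_reverse_constant(self):
        m = _diamond()
        constraints = assign_constraints(m, cycle_basis(build_reversible_graph(m)))
        assert len(constraints) == 1
        derived = m.parameters[constraints[0].derived_parameter_index]
        assert derived.name == "kr_r4"
        assert derived.status == "derived"

    def test_free_count_drops_by_number_of_cycles(self):
        m = _diamond()
        before = len(m.free_parameter_indices())
        cycles = cycle_basis(build_reversible_graph(m))
        assign_constraints(m, cycles)
        after = len(m.free_parameter_indices())
        assert before - after == len(cycles) == 1
        assert (before, after) == (8, 7)

    def test_no_cycles_changes_nothing(self):
        m = compile_model(parse_model("A binds B --> AB\n"))
        before = len(m.free_parameter_indices())
        assign_constraints(m, cycle_basis(build_reversible_graph(m)))
        assert len(m.free_parameter_indices()) == before

    def test_over_constrained_cycle_is_an_error(self):
        m = _diamond()
        cycles = cycle_basis(build_reversible_graph(m))
        assign_constraints(m, cycles)
        with pytest.raises(ThermoError, match="over-constrained"):
            # every reaction in this loop would need a second derived constant
            assign_constraints(m, cycles * 4)


class TestApplication:
    def test_worked_equilibrium_constant_example(self):
        # traversal signs (+,+,-,-): Keq1·Keq2/(Keq3·Keq4) = 1
        m = _diamond()
        constraints = assign_constraints(m, cycle_basis(build_reversible_graph(m)))
        p = _set(m, m.parameter_values(), kf_r1=2, kr_r1=1, kf_r2=3, kr_r2=1,
                 kf_r3=4, kr_r3=1, kf_r4=1)
        p2 = apply_constraints(p, constraints)
        keq4 = p2[m.parameter_index("kf_r4")] / p2[m.parameter_index("kr_r4")]
        assert keq4 == pytest.approx(2 * 3 / 4)
        assert constraints[0].cycle_product(p2) == pytest.approx(1.0, abs=1e-12)

    def test_identity_case_all_keq_one(self):
        m = _diamond()
        constraints = assign_constraints(m, cycle_basis(build_reversible_graph(m)))
        p2 = apply_constraints(m.parameter_values(), constraints)
        assert p2[m.parameter_index("kr_r4")] == pytest.approx(1.0)

    def test_idempotent_and_stable_under_free_perturbation(self):
        m = _diamond()
        constraints = assign_constraints(m, cycle_basis(build_reversible_graph(m)))
        p = apply_constraints(m.parameter_values(), constraints)
        assert np.array_equal(apply_constraints(p, constraints), p)
        p[m.parameter_index("kf_r1")] *= 7.3
        p2 = apply_constraints(p, constraints)
        assert constraints[0].cycle_product(p2) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_rate_constant_rejected(self):
        m = _diamond()
        constraints = assign_constraints(m, cycle_basis(build_reversible_graph(m)))
        p = m.parameter_values()
        p[m.parameter_index("kf_r1")] = 0.0
        with pytest.raises(ThermoError, match="positive"):
            apply_constraints(p, constraints)


INIT_FREE = {"A": 1.0, "B": 1.0, "C": 1.0, "AB": 0.0, "AC": 0.0, "ABC": 0.0}
INIT_PATH1 = {"A": 0.0, "B": 0.0, "C": 1.0, "AB": 1.0, "AC": 0.0, "ABC": 0.0}
INIT_PATH2 = {"A": 0.0, "B": 1.0, "C": 0.0, "AB": 0.0, "AC": 1.0, "ABC": 0.0}


def _steady(model, params, overrides, duration=10000.0):
    cond = SimulationCondition("eq", overrides, duration, 11)
    return integrate(model, params, cond).states[-1]


class TestPathIndependence:
    """Detailed balance makes the two assembly paths thermodynamically
    equivalent; a loop product ≠ 1 breaks that equivalence."""

    def test_constrained_diamond_equilibrium(self):
        m = _diamond()
        constraints = detect_and_constrain(m)
        p = _set(m, m.parameter_values(), kf_r1=2, kf_r2=2, kf_r3=2, kf_r4=1)
        p = apply_constraints(p, constraints)
        eq_states = [_steady(m, p, ov) for ov in (INIT_FREE, INIT_PATH1, INIT_PATH2)]
        for s in eq_states[1:]:
            assert np.allclose(s, eq_states[0], rtol=1e-6, atol=1e-9)
        # every reaction individually balanced: true equilibrium, no loop flux
        assert np.abs(m.rates(eq_states[0], p)).max() < 1e-8
        # measured ratios match the Keq prediction of *both* paths
        names = m.species_names
        s = dict(zip(names, eq_states[0]))
        keq = lambda kf, kr: p[m.parameter_index(kf)] / p[m.parameter_index(kr)]
        path1 = keq("kf_r1", "kr_r1") * keq("kf_r2", "kr_r2")
        path2 = keq("kf_r3", "kr_r3") * keq("kf_r4", "kr_r4")
        measured = s["ABC"] / (s["A"] * s["B"] * s["C"])
        assert measured == pytest.approx(path1, rel=1e-6)
        assert measured == pytest.approx(path2, rel=1e-6)

    def test_unconstrained_loop_product_two_violates_path_equivalence(self):
        m = _diamond()  # no constraints applied
        p = _set(m, m.parameter_values(), kf_r1=2, kf_r2=2, kf_r3=2, kf_r4=1)
        cycles = cycle_basis(build_reversible_graph(m))
        assert cycles[0].cycle_product(p) == pytest.approx(2.0)
        s_vec = _steady(m, p, INIT_FREE)
        # steady state sustains a perpetual flux around the loop
        assert np.abs(m.rates(s_vec, p)).max() > 1e-3
        # the two paths now predict different overall equilibrium constants
        # and the realized steady state matches neither
        s = dict(zip(m.species_names, s_vec))
        keq = lambda kf, kr: p[m.parameter_index(kf)] / p[m.parameter_index(kr)]
        path1 = keq("kf_r1", "kr_r1") * keq("kf_r2", "kr_r2")
        path2 = keq("kf_r3", "kr_r3") * keq("kf_r4", "kr_r4")
        measured = s["ABC"] / (s["A"] * s["B"] * s["C"])
        assert path1 / path2 == pytest.approx(2.0)
        assert abs(measured - path1) / path1 > 0.05
        assert abs(measured - path2) / path2 > 0.05


def test_constraint_report_names_loop_and_formula():
    m = _diamond()
    constraints = detect_and_constrain(m)
    rep = constraint_report(m, constraints)
    assert "kr_r4" in rep and "loop 1" in rep
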