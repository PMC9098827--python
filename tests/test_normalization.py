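"""Normalization: scale parameters, elasticities, symbolic Jacobian,
constraint propagation, and the finite-difference master oracle."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from genmod import (
    ConstraintError,
    ConstraintSpec,
    GeneralizedModel,
    NamingError,
    StructuralError,
    apply_constraints,
    build_jacobian,
    derive_scale_parameters,
    elasticity_numeric,
    elasticity_symbolic,
    fixture,
    normalize_timescale,
    realize_power_law,
)
from conftest import draw_admissible

S = sympy.symbols


class TestElasticityCalculus:
    """Exponent parameters are logarithmic derivatives at the steady state."""

    @pytest.mark.parametrize(
        "fn, expected",
        [
            (lambda x: 3.0 * x, 1.0),          # linear
            (lambda x: 0.7 * x**2, 2.0),       # quadratic
            (lambda x: 5.0 * np.sqrt(x), 0.5), # square root
            (lambda x: 2.0 / x, -1.0),         # reciprocal
        ],
    )
    def test_numeric_path(self, fn, expected):
        assert elasticity_numeric(fn, 1.7) == pytest.approx(expected, abs=1e-8)

    @given(
        a=st.floats(0.1, 10), p=st.floats(-3, 3), xstar=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_power_law_elasticity_is_exponent_regardless_of_scale(self, a, p, xstar):
        x = sympy.Symbol("x")
        sym = elasticity_symbolic(a * x**p, x, xstar)
        assert float(sym) == pytest.approx(p, abs=1e-9)
        num = elasticity_numeric(lambda v: a * v**p, xstar)
        assert num == pytest.approx(p, abs=1e-5 * max(1, abs(p)))

    def test_symbolic_and_numeric_paths_agree_for_saturating_form(self):
        x = sympy.Symbol("x")
        expr = 2 * x / (1 + x)
        sym = float(elasticity_symbolic(expr, x, 1))
        num = elasticity_numeric(lambda v: 2 * v / (1 + v), 1.0)
        assert sym == pytest.approx(0.5, abs=1e-12)
        assert num == pytest.approx(sym, abs=1e-8)


class TestScaleParameters:
    def test_one_d_single_turnover_no_branching(self):
        scales = derive_scale_parameters(fixture("one_d_gain_loss"))
        assert scales.turnover["X"] == sympy.Symbol("alpha_x")
        assert scales.branching_groups == ()

    def test_predator_prey_loss_branching_sums_to_one(self):
        scales = derive_scale_parameters(fixture("predator_prey"))
        pairs = dict(scales.weights[("X", "loss")])
        assert sympy.simplify(pairs["F"] + pairs["L"] - 1) == 0
        assert isinstance(pairs["F"], sympy.Symbol)  # rho, the predation share

    def test_z_equation_two_three_way_groups(self):
        scales = derive_scale_parameters(fixture("z_branching"))
        gains = dict(scales.weights[("Z", "gain")])
        losses = dict(scales.weights[("Z", "loss")])
        assert sympy.simplify(sum(gains.values()) - 1) == 0
        assert sympy.simplify(sum(losses.values()) - 1) == 0
        # k-way group -> k-1 free symbols each
        assert len([g for g in scales.branching_groups if len(g) == 2]) == 2

    def test_unvalidated_model_rejected(self):
        m = GeneralizedModel().add_variable("X").add_process("G", [("X", "gain")], ["X"])
        with pytest.raises(StructuralError):
            derive_scale_parameters(m)

    def test_timescale_normalization_sets_reference_to_one_and_is_idempotent(self):
        scales = derive_scale_parameters(fixture("predator_prey"))
        once = normalize_timescale(scales, "X")
        assert once.turnover["X"] == 1
        assert once.turnover["Y"] == sympy.Symbol("alpha_y")
        assert normalize_timescale(once, "X") == once

    def test_unknown_reference_rejected(self):
        scales = derive_scale_parameters(fixture("one_d_gain_loss"))
        with pytest.raises(NamingError):
            normalize_timescale(scales, "W")


class TestSymbolicJacobian:
    def test_one_d_jacobian(self):
        jac = build_jacobian(fixture("one_d_gain_loss"))
        a, g, l = S("alpha_x g_x l_x")
        assert sympy.expand(jac.matrix[0, 0] - a * (g - l)) == 0

    def test_predator_prey_matches_closed_form(self, predator_prey_jac):
        s_x, f_x, f_y, l_x, g_x, g_y, m_y = S("s_x f_x f_y l_x g_x g_y m_y")
        alpha, rho = S("alpha_y sigma_f")
        expected = sympy.Matrix(
            [
                [s_x - rho * f_x - (1 - rho) * l_x, -rho * f_y],
                [alpha * g_x, alpha * (g_y - m_y)],
            ]
        )
        assert sympy.expand(predator_prey_jac.matrix - expected) == sympy.zeros(2, 2)

    def test_z_row_branching_entry(self):
        jac = build_jacobian(fixture("z_branching"))
        a_z, b_a, s_q, s_r, a_x, s_x = S("alpha_z beta_a sigma_q sigma_r a_x s_x")
        sigma_s = 1 - s_q - s_r
        expected = a_z * (b_a * a_x - sigma_s * s_x)
        assert sympy.expand(jac.matrix[2, 0] - expected) == 0

    def test_structural_zeros_follow_dependencies(self):
        from genmod import generate_food_chain

        jac = build_jacobian(generate_food_chain(4), timescale_reference="X1")
        for i in range(4):
            for j in range(4):
                if abs(i - j) > 1:
                    assert jac.matrix[i, j] == 0
                else:
                    assert jac.matrix[i, j] != 0

    def test_entries_linear_in_each_elasticity(self, predator_prey_jac):
        for sym in predator_prey_jac.exponents.values():
            assert sympy.diff(predator_prey_jac.matrix, sym, 2) == sympy.zeros(2, 2)


class TestConstraints:
    def test_simple_composition_chain_rule(self):
        # G = H(F): g_v -> h_f * f_v
        m = fixture("predator_prey").add_constraint(
            ConstraintSpec("function_composition", {"outer": "G", "function": "H", "args": ["F"]})
        )
        jac = build_jacobian(m, timescale_reference="X")
        h_f, f_x, f_y, alpha = S("h_f f_x f_y alpha_y")
        assert sympy.expand(jac.matrix[1, 0] - alpha * h_f * f_x) == 0

    def test_identity_composition_with_linear_outer(self):
        m = fixture("predator_prey").add_constraint(
            ConstraintSpec(
                "function_composition",
                {"outer": "G", "function": "H", "args": ["F"], "fixed": {"h_f": 1}},
            )
        )
        jac = build_jacobian(m, timescale_reference="X")
        f_x, alpha = S("f_x alpha_y")
        assert sympy.expand(jac.matrix[1, 0] - alpha * f_x) == 0

    def test_per_capita_conversion_constraint(self):
        # G = H(F, C), C = F/Y, h_f = 1:
        #   g_x -> (1 + h_c) f_x,   g_y -> f_y + h_c (f_y - 1)
        jac = build_jacobian(fixture("predator_prey_conversion"), timescale_reference="X")
        f_x, f_y, h_c, m_y, alpha = S("f_x f_y h_c m_y alpha_y")
        assert sympy.expand(jac.matrix[1, 0] - alpha * (1 + h_c) * f_x) == 0
        assert sympy.expand(jac.matrix[1, 1] - alpha * (f_y + h_c * (f_y - 1) - m_y)) == 0

    def test_explicit_inner_log_differentiation(self):
        # C = F/Y has c_f = 1, c_y = -1 in closed form.
        from genmod.jacobian import _inner_elasticities

        spec = ConstraintSpec("explicit_inner", {"name": "C", "expr": "F / Y"})
        els = _inner_elasticities(spec, fixture("predator_prey"))
        assert els == {"F": 1, "Y": -1}

    @given(p=st.floats(-3, 3).filter(lambda p: abs(p) > 1e-3), a=st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_explicit_inner_power_law_yields_exponent(self, p, a):
        from genmod.jacobian import _inner_elasticities

        spec = ConstraintSpec("explicit_inner", {"name": "C", "expr": f"{a} * F**{p}"})
        els = _inner_elasticities(spec, fixture("predator_prey"))
        assert float(els["F"]) == pytest.approx(p, abs=1e-9)

    def test_derivative_condition_pins_elasticity_to_zero(self):
        m = fixture("one_d_gain_loss").add_constraint(
            ConstraintSpec("derivative_condition", {"process": "G", "variable": "X"})
        )
        jac = build_jacobian(m, timescale_reference="X")
        assert sympy.expand(jac.matrix[0, 0] + sympy.Symbol("l_x")) == 0

    def test_composition_cycle_rejected(self):
        m = fixture("predator_prey")
        m = m.add_constraint(
            ConstraintSpec("function_composition", {"outer": "G", "function": "H", "args": ["F"]})
        )
        m = m.add_constraint(
            ConstraintSpec("function_composition", {"outer": "F", "function": "K", "args": ["G"]})
        )
        with pytest.raises(ConstraintError):
            build_jacobian(m, timescale_reference="X")

    def test_constraints_preserve_structural_zeros(self):
        jac = build_jacobian(fixture("predator_prey_conversion"), timescale_reference="X")
        base = build_jacobian(fixture("predator_prey"), timescale_reference="X")
        for i in range(2):
            for j in range(2):
                if base.matrix[i, j] == 0:
                    assert jac.matrix[i, j] == 0

    def test_conservation_law_records_flux_matching(self):
        m = GeneralizedModel()
        for v in ("A", "B"):
            m = m.add_variable(v)
        m = m.add_process("IN", [("A", "gain")], ["A"])
        m = m.add_process("T", [("A", "loss"), ("B", "gain")], ["A"])
        m = m.add_process("OUT", [("B", "loss")], ["B"])
        m = m.add_constraint(
            ConstraintSpec("conservation_law", {"coefficients": {"A": 1, "B": 1}})
        )
        jac = build_jacobian(m)
        assert jac.matrix.shape == (2, 2)  # full size retained
        extra = [c for c in jac.scales.constraints if "chi" in str(c)]
        assert len(extra) == 1
        assert sympy.Symbol("alpha_a") in extra[0].free_symbols


class TestMasterOracle:
    """Symbolic Jacobian == finite-difference Jacobian of the power-law
    realization at its (all-ones) steady state."""

    @pytest.mark.parametrize(
        "name, ref",
        [
            ("one_d_gain_loss", "X"),
            ("predator_prey", "X"),
            ("predator_prey_conversion", "X"),
            ("z_branching", None),
        ],
    )
    def test_fixture_agreement(self, name, ref):
        model = fixture(name)
        jac = build_jacobian(model, timescale_reference=ref)
        for params in draw_admissible(jac, 50, seed=7):
            realized = realize_power_law(model, params, jac=jac)
            fd = realized.finite_difference_jacobian()
            sym = jac.evaluate(params)
            scale = max(1.0, np.abs(sym).max())
            assert np.abs(fd - sym).max() / scale < 1e-6
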