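"""Worked generalized models and parameterized generators.

The catalog ships the small systems used throughout the documentation
and tests, so every analysis runs without external input:

``one_d_gain_loss``
    A single positive quantity with one gain and one loss process;
    Jacobian ``[alpha*(g_x - l_x)]``, stable iff the loss elasticity
    exceeds the gain elasticity.
``predator_prey``
    Prey X with reproduction S(X), predation loss F(X, Y) and other
    mortality L(X); predator Y with predation gain G(X, Y) and mortality
    M(Y).  Time is measured in prey turnover units, so one turnover
    ratio ``alpha_y`` remains.
``predator_prey_conversion``
    Same structure with predator gain tied to prey loss through a
    conversion efficiency that depends on per-capita consumption:
    G = H(F, C), C = F/Y, with the direct dependence on total
    consumption fixed to linear (h_f = 1), leaving the elasticity of
    conversion efficiency ``h_c`` free.
``z_branching``
    A three-variable system whose Z equation has three gains (branching
    weights beta) and three losses (weights sigma), exercising multi-way
    branching groups.

``generate_food_chain(n)`` builds chains of n trophic levels with
linear conversion efficiency on every predation link.
"""

from __future__ import annotations

from .errors import NamingError, RangeError
from .model import ConstraintSpec, GeneralizedModel

__all__ = ["fixture", "fixture_names", "generate_food_chain", "default_ranges"]

FIXTURE_NAMES = (
    "one_d_gain_loss",
    "predator_prey",
    "predator_prey_conversion",
    "z_branching",
)


def fixture_names() -> tuple[str, ...]:
    return FIXTURE_NAMES


def _one_d() -> GeneralizedModel:
    m = GeneralizedModel().add_variable("X", "a positive stock subject to gain and loss")
    m = m.add_process("G", [("X", "gain")], ["X"])
    m = m.add_process("L", [("X", "loss")], ["X"])
    return m


def _predator_prey() -> GeneralizedModel:
    m = GeneralizedModel()
    m = m.add_variable("X", "prey")
    m = m.add_variable("Y", "predator")
    # Prey reproduction is independent of the predator by assumption.
    m = m.add_process("S", [("X", "gain")], ["X"])
    m = m.add_process("F", [("X", "loss")], ["X", "Y"])
    m = m.add_process("L", [("X", "loss")], ["X"])
    m = m.add_process("G", [("Y", "gain")], ["X", "Y"])
    m = m.add_process("M", [("Y", "loss")], ["Y"])
    return m


def _predator_prey_conversion() -> GeneralizedModel:
    m = _predator_prey()
    m = m.add_constraint(
        ConstraintSpec("explicit_inner", {"name": "C", "expr": "F / Y"})
    )
    m = m.add_constraint(
        ConstraintSpec(
            "function_composition",
            {"outer": "G", "function": "H", "args": ["F", "C"], "fixed": {"h_f": 1}},
        )
    )
    return m


def _z_branching() -> GeneralizedModel:
    m = GeneralizedModel()
    for v in ("X", "Y", "Z"):
        m = m.add_variable(v)
    # Simple gain/loss pairs keep the X and Y equations well-formed.
    m = m.add_process("PX", [("X", "gain")], ["X"])
    m = m.add_process("DX", [("X", "loss")], ["X"])
    m = m.add_process("PY", [("Y", "gain")], ["Y"])
    m = m.add_process("DY", [("Y", "loss")], ["Y"])
    # The Z equation branches three gains and three losses.
    m = m.add_process("A", [("Z", "gain")], ["X"])
    m = m.add_process("B", [("Z", "gain")], ["Y"])
    m = m.add_process("C", [("Z", "gain")], ["Z"])
    m = m.add_process("Q", [("Z", "loss")], ["Z"])
    m = m.add_process("R", [("Z", "loss")], ["Z", "Y"])
    m = m.add_process("S", [("Z", "loss")], ["Z", "Y", "X"])
    return m


def fixture(name: str) -> GeneralizedModel:
    """Return a fully declared model from the catalog by name."""
    try:
        return {
            "one_d_gain_loss": _one_d,
            "predator_prey": _predator_prey,
            "predator_prey_conversion": _predator_prey_conversion,
            "z_branching": _z_branching,
        }[name]()
    except KeyError:
        raise NamingError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None


def generate_food_chain(n: int) -> GeneralizedModel:
    """A food chain of ``n`` trophic levels.

    Level 1 has a primary-production gain; level k > 1 gains by predation
    on level k-1 (conversion tied to the corresponding predation loss
    with linear efficiency, h_f = 1); every level has a mortality loss,
    and every level but the top additionally loses to predation.  The
    resulting Jacobian has tridiagonal sparsity.
    """
    if n < 1:
        raise RangeError("a food chain needs at least one trophic level")
    m = GeneralizedModel()
    for k in range(1, n + 1):
        m = m.add_variable(f"X{k}", f"trophic level {k}")
    m = m.add_process("P1", [("X1", "gain")], ["X1"])
    for k in range(2, n + 1):
        below, here = f"X{k-1}", f"X{k}"
        m = m.add_process(f"F{k}", [(below, "loss")], [below, here])
        m = m.add_process(f"G{k}", [(here, "gain")], [below, here])
        m = m.add_constraint(
            ConstraintSpec(
                "function_composition",
                {
                    "outer": f"G{k}",
                    "function": f"H{k}",
                    "args": [f"F{k}"],
                    "fixed": {f"h{k}_f{k}": 1},
                },
            )
        )
    for k in range(1, n + 1):
        m = m.add_process(f"D{k}", [(f"X{k}", "loss")], [f"X{k}"])
    return m


def default_ranges(jac_symbols: tuple[str, ...] | None = None) -> dict[str, tuple[float, float]]:
    """Illustrative default sampling ranges by parameter family.

    Elasticities cover [0, 2] -- the span from constant to quadratic
    response, matching what a Holling type-III functional response can
    produce; turnovers/turnover ratios cover [0.1, 10] (allometric
    spread); auxiliary outer elasticities (conversion nonlinearity)
    cover [-1, 1].  All user-overridable.
    """
    out: dict[str, tuple[float, float]] = {}
    for name in jac_symbols or ():
        if name.startswith("alpha_"):
            out[name] = (0.1, 10.0)
        elif name.startswith(("beta_", "sigma_")):
            continue  # simplex-sampled
        elif name.startswith("h") and "_" in name:
            out[name] = (-1.0, 1.0)
        else:
            out[name] = (0.0, 2.0)
    return out
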