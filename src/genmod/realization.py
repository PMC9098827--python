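"""Construct conventional ODE models that realize a generalized parameter set.

Any point of the generalized parameter space corresponds to a realizable
steady state of an explicit model: replace each unknown normalized
process by a specific function that (a) equals its turnover weight at
the all-ones point (normalization condition ``F(1) = alpha``) and (b)
has the requested elasticities there.  The simplest such family is the
power laws ``F(x) = prod_v x_v**theta_v``, whose elasticity w.r.t.
``x_v`` is exactly ``theta_v`` everywhere; saturating (Holling-type)
templates ``G(x) = (1+K) x / (K + x)`` cover elasticities in [0, 1).

The constructed system has its steady state at the all-ones point by
construction, so no steady-state computation is ever needed, and its
Jacobian there reproduces the generalized Jacobian -- this round trip is
the toolkit's master consistency oracle.

Power-law realizations are flagged with a degeneracy caveat: with every
process a pure power law, certain bifurcations become degenerate, which
can distort bifurcation studies (simulation studies are unaffected);
mixing in saturating templates avoids this.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import scipy.optimize
import sympy

from .errors import IntegrityError, NumericError, RangeError, StructuralError
from .jacobian import SymbolicJacobian, build_jacobian, elasticity_numeric
from .model import GeneralizedModel

__all__ = [
    "FunctionTemplate",
    "RealizedModel",
    "realize_power_law",
    "solve_template",
    "verify_roundtrip",
    "saturating_template",
]


@dataclass(frozen=True)
class FunctionTemplate:
    """A parameterized functional form for one process.

    ``expr`` is a sympy expression in the normalized variable ``x`` (and
    the template's constants before they are solved).  The solved
    template is positive on the positive axis, equals 1 at ``x = 1`` and
    has a prescribed elasticity there.
    """

    family: str  # "power_law" | "saturating" | "custom"
    expr: sympy.Expr
    constants: Mapping[str, float] = field(default_factory=dict)

    def __call__(self, x: float) -> float:
        sub = {sympy.Symbol(k): v for k, v in self.constants.items()}
        return float(self.expr.subs(sub).subs(sympy.Symbol("x"), x))


def saturating_template() -> FunctionTemplate:
    """Holling-type saturating response ``A x / (x + K)`` with ``A = 1 + K``
    enforced so the normalized value at 1 is exactly 1."""
    x, k = sympy.symbols("x K")
    return FunctionTemplate(family="saturating", expr=(1 + k) * x / (x + k))


def solve_template(
    template: FunctionTemplate,
    target_elasticity: float,
    turnover_weight: float = 1.0,
) -> FunctionTemplate:
    """Fix a template's shape constant so its elasticity at 1 matches.

    For the saturating family the elasticity at the normalized point is
    ``K/(K+1)``, giving the closed form ``K = p/(1-p)`` for target ``p``
    in [0, 1); a target of 0 degenerates to the constant response and a
    target >= 1 is unachievable.  Custom one-constant templates are
    solved by bracketed root finding on [1e-6, 1e6].  The returned
    template is scaled by ``turnover_weight``.
    """
    if template.family == "saturating":
        p = float(target_elasticity)
        if not 0 <= p < 1:
            raise RangeError(
                f"saturating family achieves elasticities in [0, 1); got {p}"
            )
        k = p / (1.0 - p)
        expr = turnover_weight * template.expr
        return replace(template, expr=expr, constants={"K": k})
    if template.family == "custom":
        free = sorted(
            (s for s in template.expr.free_symbols if s.name != "x"),
            key=lambda s: s.name,
        )
        if len(free) != 1:
            raise StructuralError("custom templates must have exactly one shape constant")
        k = free[0]
        x = sympy.Symbol("x")
        el = sympy.diff(template.expr, x) * x / template.expr
        el_at_one = sympy.lambdify(k, el.subs(x, 1))
        value_at_one = sympy.lambdify(k, template.expr.subs(x, 1))

        def residual(kv: float) -> float:
            return float(el_at_one(kv)) - float(target_elasticity)

        lo, hi = 1e-6, 1e6
        flo, fhi = residual(lo), residual(hi)
        if not np.isfinite(flo) or not np.isfinite(fhi) or flo * fhi > 0:
            raise RangeError(
                f"target elasticity {target_elasticity} outside the achievable "
                "range of this template on [1e-6, 1e6]"
            )
        kv = scipy.optimize.brentq(residual, lo, hi, xtol=1e-14, rtol=1e-14)
        scale = turnover_weight / float(value_at_one(kv))
        return replace(template, expr=scale * template.expr, constants={k.name: kv})
    raise StructuralError(f"cannot solve template family {template.family!r}")


@dataclass(frozen=True)
class RealizedModel:
    """Explicit ODE system realizing a generalized parameter set.

    Steady state at the all-ones point of the normalized variables.
    ``terms[i]`` lists ``(sign, process, expr)`` for equation i, where
    ``expr`` is a sympy expression in the normalized variables whose
    value at the all-ones point equals ``turnover_i * weight``.
    """

    variables: tuple[str, ...]
    terms: tuple[tuple[tuple[int, str, sympy.Expr], ...], ...]
    parameters: Mapping[str, float]
    degenerate_bifurcations: bool = False

    @property
    def rhs_exprs(self) -> tuple[sympy.Expr, ...]:
        return tuple(
            sympy.expand(sum(s * e for s, _, e in eq)) for eq in self.terms
        )

    def rhs(self) -> Callable[[np.ndarray], np.ndarray]:
        syms = [sympy.Symbol(v.lower()) for v in self.variables]
        fns = [sympy.lambdify(syms, e, "numpy") for e in self.rhs_exprs]
        return lambda x: np.array([f(*x) for f in fns], dtype=float)

    def finite_difference_jacobian(self, x: np.ndarray | None = None, step: float = 1e-6) -> np.ndarray:
        """Central-difference Jacobian, by default at the all-ones steady state."""
        f = self.rhs()
        x0 = np.ones(len(self.variables)) if x is None else np.asarray(x, dtype=float)
        n = len(x0)
        jac = np.empty((n, n))
        for j in range(n):
            up, dn = x0.copy(), x0.copy()
            up[j] += step
            dn[j] -= step
            jac[:, j] = (f(up) - f(dn)) / (2 * step)
        return jac

    def to_text(self) -> str:
        lines = []
        for v, e in zip(self.variables, self.rhs_exprs):
            lines.append(f"d{v.lower()}/dt = {e}")
        return "\n".join(lines)

    def integrate(self, x0: np.ndarray, t_end: float, dt: float = 1e-3) -> np.ndarray:
        """Fixed-step RK4 time series for smoke tests; rows are time points."""
        f = self.rhs()
        steps = int(np.ceil(t_end / dt))
        out = np.empty((steps + 1, len(x0)))
        x = np.asarray(x0, dtype=float)
        out[0] = x
        for i in range(steps):
            k1 = f(x)
            k2 = f(x + 0.5 * dt * k1)
            k3 = f(x + 0.5 * dt * k2)
            k4 = f(x + dt * k3)
            x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            out[i + 1] = x
        return out


def realize_power_law(
    model: GeneralizedModel,
    parameters: Mapping[str, float],
    jac: SymbolicJacobian | None = None,
    templates: Mapping[str, FunctionTemplate] | None = None,
) -> RealizedModel:
    """Realize a numeric generalized parameter set as an explicit model.

    Every process becomes ``weight * prod_v x_v**theta_v`` (power law) by
    default; ``templates`` may substitute a solved saturating/custom
    template for single-dependency processes.  ``parameters`` maps the
    symbol names of the model's Jacobian (turnovers, branching weights,
    elasticities) to numbers; elasticity values are read from the
    *post-constraint* Jacobian parameterization, so constrained models
    realize their effective elasticities.
    """
    if jac is None:
        jac = build_jacobian(model)
    params = {str(k): float(v) for k, v in parameters.items()}
    scales = jac.scales
    if scales is None:
        raise StructuralError("realization needs a Jacobian with scale parameters")

    def num(expr: sympy.Expr) -> float:
        val = sympy.sympify(expr).subs({sympy.Symbol(k): v for k, v in params.items()})
        if val.free_symbols:
            raise NumericError(f"unresolved parameter(s) in {expr}: {val.free_symbols}")
        return float(val)

    var_syms = {v: sympy.Symbol(v.lower()) for v in jac.variables}
    substitution = dict(jac.substitutions)
    templates = dict(templates or {})

    terms: list[tuple[tuple[int, str, sympy.Expr], ...]] = []
    used_template = False
    for vi in jac.variables:
        alpha = num(scales.turnover[vi])
        eq_terms: list[tuple[int, str, sympy.Expr]] = []
        for sign_name, s in (("gain", 1), ("loss", -1)):
            for pname, w in scales.weights.get((vi, sign_name), ()):
                weight = num(w)
                proc = model.process(pname)
                if pname in templates:
                    if len(proc.dependencies) != 1:
                        raise StructuralError(
                            f"template substitution needs a single dependency ({pname!r})"
                        )
                    tpl = templates[pname]
                    dep = proc.dependencies[0]
                    sub = {sympy.Symbol(k): v for k, v in tpl.constants.items()}
                    expr = tpl.expr.subs(sub).subs(sympy.Symbol("x"), var_syms[dep])
                    used_template = True
                else:
                    expr = sympy.Integer(1)
                    for dep in proc.dependencies:
                        theta_sym = sympy.Symbol(f"{pname.lower()}_{dep.lower()}")
                        theta_expr = substitution.get(theta_sym, theta_sym)
                        expr *= var_syms[dep] ** num(theta_expr)
                eq_terms.append((s, pname, alpha * weight * expr))
        terms.append(tuple(eq_terms))

    realized = RealizedModel(
        variables=jac.variables,
        terms=tuple(terms),
        parameters=params,
        degenerate_bifurcations=not used_template,
    )
    residual = np.max(np.abs(realized.rhs()(np.ones(len(jac.variables)))))
    if residual > 1e-10:
        raise IntegrityError(
            f"realized model violates stationarity at the all-ones point "
            f"(residual {residual:.2e}); check branching sums"
        )
    return realized


def verify_roundtrip(
    realized: RealizedModel, step: float = 1e-6
) -> tuple[dict[str, float], float]:
    """Recover generalized parameters from a realized model numerically.

    Turnovers are re-read as total gain rates at the all-ones point,
    branching weights as term shares, and elasticities as central-
    difference log-derivatives.  Returns the recovered parameter dict and
    the maximum absolute deviation from the requested set.  Raises when
    the model is not actually stationary at the all-ones point.
    """
    ones = np.ones(len(realized.variables))
    residual = np.max(np.abs(realized.rhs()(ones)))
    if residual > 1e-8:
        raise IntegrityError(
            f"steady-state residual {residual:.2e} exceeds 1e-8; "
            "model does not realize the normalized steady state"
        )
    var_syms = [sympy.Symbol(v.lower()) for v in realized.variables]
    recovered: dict[str, float] = {}
    for vi, eq in zip(realized.variables, realized.terms):
        gain_total = 0.0
        values: dict[str, float] = {}
        for s, pname, expr in eq:
            f = sympy.lambdify(var_syms, expr, "numpy")
            val = float(f(*ones))
            values[pname] = val
            if s > 0:
                gain_total += val
        recovered[f"alpha_{vi.lower()}"] = gain_total
        for s, pname, expr in eq:
            key = ("beta" if s > 0 else "sigma") + f"_{pname.lower()}"
            recovered.setdefault(key, values[pname] / gain_total)
        for s, pname, expr in eq:
            f = sympy.lambdify(var_syms, expr, "numpy")
            for j, vj in enumerate(realized.variables):
                def g(xj: float, _f=f, _j=j) -> float:
                    x = ones.copy()
                    x[_j] = xj
                    return float(_f(*x))

                el = elasticity_numeric(g, 1.0, step=step)
                if abs(el) > 1e-9:
                    recovered[f"{pname.lower()}_{vj.lower()}"] = el
    max_dev = 0.0
    for name, req in realized.parameters.items():
        if name in recovered:
            max_dev = max(max_dev, abs(recovered[name] - float(req)))
    return recovered, max_dev
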