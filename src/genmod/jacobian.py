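"""Normalization of a generalized model and its symbolic Jacobian.

The normalization rewrites every variable as ``x = X/X*`` and every
process as ``p = P/P*`` so that the (unknown) steady state moves to the
all-ones point, where every normalized process runs at rate 1.  The
prefactors that appear are captured in interpretable *scale parameters*:

* one **turnover** ``alpha_v`` per variable -- the per-unit total gain
  (= total loss, by stationarity) rate in the steady state, units 1/time;
* **branching weights** per (variable, sign) group -- the fraction of the
  turnover carried by each process; each group sums to one, so a group of
  k processes contributes k-1 free weights and the last is one minus
  their sum.

The unknown derivatives of the normalized processes at the steady state
become **exponent parameters** (elasticities): logarithmic derivatives
that equal 1 for a linear process, p for any power law ``a*X**p``, and
lie in (0, 1) for saturating kinetics.

The Jacobian entry for row i (variable ``v_i``) and column j is::

    J_ij = alpha_i * sum over processes P in equation i of
           sign(P, i) * weight(P, i) * theta[P, v_j]

with ``theta[P, v] = 0`` when P does not declare a dependency on v
(structural zero).  Entries are linear in every elasticity symbol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy

from .errors import ConstraintError, NamingError, NumericError, StructuralError
from .model import ConstraintSpec, GeneralizedModel, Process

__all__ = [
    "ScaleParameters",
    "SymbolicJacobian",
    "derive_scale_parameters",
    "normalize_timescale",
    "build_jacobian",
    "apply_constraints",
    "elasticity_numeric",
    "elasticity_symbolic",
]


# ---------------------------------------------------------------------------
# Elasticity calculus for explicit functions
# ---------------------------------------------------------------------------

def elasticity_numeric(
    fn: Callable[[float], float], steady_state: float, step: float = 1e-6
) -> float:
    """Exponent parameter of an explicit one-argument process at ``X*``.

    Normalizes ``p(x) = P(x X*)/P(X*)`` and returns the central finite
    difference of ``p`` at the normalized point 1 with relative step
    ``step``; equals d ln P / d ln X at the steady state.
    """
    p_star = fn(steady_state)
    if not math.isfinite(p_star) or p_star <= 0:
        raise NumericError("process rate must be positive at the steady state")
    up = fn((1.0 + step) * steady_state)
    dn = fn((1.0 - step) * steady_state)
    return (up - dn) / (2.0 * step * p_star)


def elasticity_symbolic(
    expr: sympy.Expr, var: sympy.Symbol, steady_state: float | sympy.Expr = 1
) -> sympy.Expr:
    """Symbolic logarithmic derivative ``(X/P) dP/dX`` evaluated at ``X*``.

    For any power law ``a*X**p`` the result is exactly ``p``, independent
    of the prefactor and of the steady-state location.
    """
    el = sympy.simplify(sympy.diff(expr, var) * var / expr)
    return sympy.simplify(el.subs(var, steady_state))


# ---------------------------------------------------------------------------
# Scale parameters
# ---------------------------------------------------------------------------

def _weight_symbol(proc: Process, variable: str, sign: str, shared: bool) -> sympy.Symbol:
    prefix = "beta" if sign == "gain" else "sigma"
    name = f"{prefix}_{proc.name.lower()}"
    if shared:
        name += f"_{variable.lower()}"
    return sympy.Symbol(name)


@dataclass(frozen=True)
class ScaleParameters:
    """Symbolic skeleton of the scale parameters of a model.

    ``turnover`` maps each variable to its turnover expression (a symbol,
    or 1 / a ratio symbol after timescale normalization).  ``weights``
    maps ``(variable, sign)`` to the ordered list of ``(process, weight
    expression)`` pairs of that branching group; in a group of k > 1
    processes the first k-1 weights are free symbols and the last is one
    minus their sum.  ``constraints`` records sum-to-one and flux-matching
    relations as sympy equalities.
    """

    turnover: Mapping[str, sympy.Expr]
    weights: Mapping[tuple[str, str], tuple[tuple[str, sympy.Expr], ...]]
    constraints: tuple[sympy.Equality, ...] = ()
    reference: str | None = None

    @property
    def branching_groups(self) -> tuple[tuple[sympy.Symbol, ...], ...]:
        """Free-symbol tuples, one per k>1 branching group (k-1 symbols each)."""
        groups = []
        for (_, _), pairs in self.weights.items():
            free = tuple(w for _, w in pairs if isinstance(w, sympy.Symbol))
            if len(pairs) > 1 and free:
                groups.append(free)
        return tuple(groups)

    def weight_of(self, process: str, variable: str) -> sympy.Expr:
        for (var, _), pairs in self.weights.items():
            if var != variable:
                continue
            for pname, w in pairs:
                if pname == process:
                    return w
        raise NamingError(f"no weight for process {process!r} in equation {variable!r}")


def derive_scale_parameters(model: GeneralizedModel) -> ScaleParameters:
    """Introduce turnover and branching symbols for a validated model.

    Stationarity (total gain = total loss per variable) is honored by
    construction: the gain and loss groups of a variable share one
    turnover symbol, so steady states that cannot exist are simply not
    representable.
    """
    report = model.validate()
    if report:
        raise StructuralError("model fails validation: " + "; ".join(report))

    shared_count: dict[tuple[str, str], int] = {}
    for p in model.processes:
        for _, sign in p.contributions:
            shared_count[(p.name, sign)] = shared_count.get((p.name, sign), 0) + 1

    turnover = {
        v: sympy.Symbol(f"alpha_{v.lower()}")
        for v in model.variable_names
    }
    weights: dict[tuple[str, str], tuple[tuple[str, sympy.Expr], ...]] = {}
    constraints: list[sympy.Equality] = []
    for var in model.variable_names:
        for sign in ("gain", "loss"):
            procs = model.processes_for(var, sign)
            if not procs:
                continue
            if len(procs) == 1:
                weights[(var, sign)] = ((procs[0].name, sympy.Integer(1)),)
                continue
            syms = [
                _weight_symbol(p, var, sign, shared_count[(p.name, sign)] > 1)
                for p in procs[:-1]
            ]
            last = sympy.Integer(1) - sum(syms)
            pairs = tuple(
                [(p.name, s) for p, s in zip(procs[:-1], syms)]
                + [(procs[-1].name, last)]
            )
            weights[(var, sign)] = pairs
            constraints.append(sympy.Eq(sum(w for _, w in pairs), 1))
    return ScaleParameters(turnover=turnover, weights=weights, constraints=tuple(constraints))


def normalize_timescale(scales: ScaleParameters, reference: str) -> ScaleParameters:
    """Measure time in units of the reference variable's turnover time.

    The reference turnover becomes 1 and every other turnover symbol is
    reinterpreted as a ratio (e.g. predator-to-prey turnover ratio).
    Idempotent for a fixed reference.
    """
    if reference not in scales.turnover:
        raise NamingError(f"unknown reference variable {reference!r}")
    new_turnover = {
        v: (sympy.Integer(1) if v == reference else sympy.Symbol(f"alpha_{v.lower()}"))
        for v in scales.turnover
    }
    return replace(scales, turnover=new_turnover, reference=reference)


# ---------------------------------------------------------------------------
# Symbolic Jacobian
# ---------------------------------------------------------------------------

def elasticity_symbol(process: str, variable: str) -> sympy.Symbol:
    """Canonical symbol for the elasticity of *process* w.r.t. *variable*."""
    return sympy.Symbol(f"{process.lower()}_{variable.lower()}")


@dataclass(frozen=True)
class SymbolicJacobian:
    """N x N generalized Jacobian in scale and exponent parameters.

    Row/column order follows variable declaration order.  Entry (i, j) is
    identically zero when no process in equation i depends on variable j.
    """

    matrix: sympy.Matrix
    variables: tuple[str, ...]
    scales: ScaleParameters | None = None
    exponents: Mapping[tuple[str, str], sympy.Symbol] = field(default_factory=dict)
    substitutions: Mapping[sympy.Symbol, sympy.Expr] = field(default_factory=dict)

    @classmethod
    def from_matrix(
        cls, matrix: sympy.Matrix | Sequence[Sequence[object]],
        variables: Sequence[str] | None = None,
    ) -> "SymbolicJacobian":
        m = sympy.Matrix(matrix)
        if m.rows != m.cols:
            raise NumericError("Jacobian must be square")
        names = tuple(variables) if variables else tuple(f"x{i+1}" for i in range(m.rows))
        return cls(matrix=m, variables=names)

    @property
    def n(self) -> int:
        return self.matrix.rows

    @property
    def free_symbols(self) -> tuple[sympy.Symbol, ...]:
        """All free parameter symbols, sorted by name (deterministic)."""
        return tuple(sorted(self.matrix.free_symbols, key=lambda s: s.name))

    @property
    def branching_groups(self) -> tuple[tuple[sympy.Symbol, ...], ...]:
        if self.scales is None:
            return ()
        present = set(self.matrix.free_symbols)
        groups = []
        for grp in self.scales.branching_groups:
            kept = tuple(s for s in grp if s in present)
            if kept:
                groups.append(kept)
        return tuple(groups)

    def subs(self, mapping: Mapping[object, object]) -> "SymbolicJacobian":
        smap = {sympy.Symbol(k) if isinstance(k, str) else k: v for k, v in mapping.items()}
        return replace(
            self,
            matrix=sympy.expand(self.matrix.subs(smap)),
            substitutions={**dict(self.substitutions), **smap},
        )

    # -- numeric evaluation ------------------------------------------------
    def _entry_functions(self):
        cached = getattr(self, "_entry_fn_cache", None)
        if cached is not None:
            return cached
        syms = self.free_symbols
        fns = []
        for i in range(self.n):
            row = []
            for j in range(self.n):
                row.append(sympy.lambdify(syms, self.matrix[i, j], "numpy"))
            fns.append(row)
        object.__setattr__(self, "_entry_fn_cache", (syms, fns))
        return syms, fns

    def evaluate(self, params: Mapping[str, float]) -> np.ndarray:
        """Numeric Jacobian for a single parameter set (dict by symbol name)."""
        return self.evaluate_many({k: np.asarray([v]) for k, v in params.items()})[0]

    def evaluate_many(self, params: Mapping[str, np.ndarray]) -> np.ndarray:
        """Vectorized evaluation: arrays of length M -> stack of shape (M, N, N)."""
        syms, fns = self._entry_functions()
        missing = [s.name for s in syms if s.name not in params]
        if missing:
            raise NamingError(f"missing parameter values for {missing}")
        cols = [np.asarray(params[s.name], dtype=float) for s in syms]
        m = len(cols[0]) if cols else 1
        out = np.empty((m, self.n, self.n), dtype=float)
        for i in range(self.n):
            for j in range(self.n):
                val = fns[i][j](*cols)
                out[:, i, j] = np.broadcast_to(np.asarray(val, dtype=float), (m,))
        if not np.all(np.isfinite(out)):
            raise NumericError("non-finite Jacobian entries")
        return out

    # -- export ------------------------------------------------------------
    def to_text(self) -> str:
        rows = []
        for i in range(self.n):
            rows.append("[" + ", ".join(str(self.matrix[i, j]) for j in range(self.n)) + "]")
        return "\n".join(rows)

    def to_json(self) -> str:
        payload = {
            "variables": list(self.variables),
            "entries": [
                [str(self.matrix[i, j]) for j in range(self.n)] for i in range(self.n)
            ],
            "parameters": [s.name for s in self.free_symbols],
            "branching_groups": [[s.name for s in g] for g in self.branching_groups],
        }
        return json.dumps(payload, indent=2)


def build_jacobian(
    model: GeneralizedModel,
    scales: ScaleParameters | None = None,
    timescale_reference: str | None = None,
    constraints: bool = True,
) -> SymbolicJacobian:
    """Assemble the generalized Jacobian of a validated model.

    ``timescale_reference`` rescales time so that the reference variable's
    turnover equals 1 (ratios remain for the others).  With
    ``constraints=True`` (default) the model's attached constraints are
    propagated through :func:`apply_constraints`.
    """
    if scales is None:
        scales = derive_scale_parameters(model)
    if timescale_reference is not None:
        scales = normalize_timescale(scales, timescale_reference)
    names = model.variable_names
    exponents = {
        (p.name, v): elasticity_symbol(p.name, v)
        for p in model.processes
        for v in p.dependencies
    }
    n = len(names)
    mat = sympy.zeros(n, n)
    for i, vi in enumerate(names):
        alpha = scales.turnover[vi]
        for sign, s in (("gain", 1), ("loss", -1)):
            for pname, w in scales.weights.get((vi, sign), ()):
                proc = model.process(pname)
                for j, vj in enumerate(names):
                    theta = exponents.get((pname, vj))
                    if theta is not None:
                        mat[i, j] += s * alpha * w * theta
    jac = SymbolicJacobian(
        matrix=sympy.expand(mat),
        variables=names,
        scales=scales,
        exponents=exponents,
    )
    if constraints and model.constraints:
        jac = apply_constraints(model, jac)
    return jac


# ---------------------------------------------------------------------------
# Constraint propagation
# ---------------------------------------------------------------------------

def _inner_elasticities(
    spec: ConstraintSpec, model: GeneralizedModel
) -> dict[str, sympy.Expr]:
    """Closed-form elasticities of an explicit auxiliary w.r.t. its direct
    arguments, by symbolic log-differentiation at the normalized point
    (all variables and process rates equal 1)."""
    expr = sympy.sympify(str(spec.payload["expr"]))
    args = sorted(expr.free_symbols, key=lambda s: s.name)
    at_one = {s: 1 for s in args}
    out: dict[str, sympy.Expr] = {}
    for a in args:
        el = sympy.simplify(sympy.diff(expr, a) * a / expr)
        el = sympy.simplify(el.subs(at_one))
        if el.free_symbols:
            raise NumericError(
                f"inner form {spec.payload['expr']!r} is not log-differentiable "
                f"to a number at the normalized point (w.r.t. {a.name})"
            )
        if not el.is_finite:
            raise NumericError(
                f"inner form {spec.payload['expr']!r} has a non-finite elasticity"
            )
        out[a.name] = el
    return out


def apply_constraints(
    model: GeneralizedModel, jac: SymbolicJacobian
) -> SymbolicJacobian:
    """Propagate the model's constraints into the Jacobian.

    Order of application: explicit-inner auxiliaries are resolved first
    (their elasticities are closed-form numbers), then function
    compositions innermost-to-outermost via the chain rule (introducing
    outer elasticity symbols like ``h_f``, ``h_c``), then derivative
    conditions (elasticities pinned to zero).  Conservation laws keep the
    Jacobian at full size and record flux-matching relations on the scale
    parameters.  Composition cycles are rejected.
    """
    variables = jac.variables
    inner: dict[str, dict[str, sympy.Expr]] = {}
    compositions: list[ConstraintSpec] = []
    deriv_zero: list[tuple[str, str]] = []
    scale_constraints: list[sympy.Equality] = []

    for c in model.constraints:
        if c.kind == "explicit_inner":
            inner[str(c.payload["name"])] = _inner_elasticities(c, model)
        elif c.kind == "function_composition":
            compositions.append(c)
        elif c.kind == "derivative_condition":
            deriv_zero.append((str(c.payload["process"]), str(c.payload["variable"])))
        elif c.kind == "conservation_law":
            scale_constraints.extend(
                _conservation_constraints(c, model, jac)
            )

    # Topological order: an outer process may consume another composition's
    # outer process as an inner argument; resolve the consumed one first.
    outer_names = [str(c.payload["outer"]) for c in compositions]
    if len(set(outer_names)) != len(outer_names):
        raise ConstraintError("multiple compositions constrain the same process")
    order: list[ConstraintSpec] = []
    placed: set[str] = set()
    pending = list(compositions)
    while pending:
        progressed = False
        for c in list(pending):
            args = [str(a) for a in c.payload["args"]]
            if all(a not in outer_names or a in placed for a in args):
                order.append(c)
                placed.add(str(c.payload["outer"]))
                pending.remove(c)
                progressed = True
        if not progressed:
            raise ConstraintError("cycle among function-composition constraints")

    # el(node, v): elasticity of a process/auxiliary w.r.t. variable v,
    # with already-resolved outer processes substituted.
    resolved: dict[str, dict[str, sympy.Expr]] = {}

    def el(node: str, v: str) -> sympy.Expr:
        if node == v:
            return sympy.Integer(1)
        if node in variables:
            return sympy.Integer(0)
        if node in resolved:
            return resolved[node].get(v, sympy.Integer(0))
        if node in inner:
            total = sympy.Integer(0)
            for arg, coeff in inner[node].items():
                total += coeff * el(arg, v)
            return total
        proc = model.process(node)  # raises NamingError for unknown nodes
        if v in proc.dependencies:
            return elasticity_symbol(node, v)
        return sympy.Integer(0)

    substitution: dict[sympy.Symbol, sympy.Expr] = {}
    for c in order:
        outer = str(c.payload["outer"])
        func = str(c.payload.get("function", "h"))
        args = [str(a) for a in c.payload["args"]]
        fixed = {str(k): v for k, v in dict(c.payload.get("fixed", {})).items()}
        outer_syms = {
            a: sympy.Symbol(f"{func.lower()}_{a.lower()}") for a in args
        }
        proc = model.process(outer)
        exprs: dict[str, sympy.Expr] = {}
        for v in variables:
            total = sympy.Integer(0)
            for a in args:
                total += outer_syms[a] * el(a, v)
            total = sympy.expand(
                total.subs({sympy.Symbol(k): val for k, val in fixed.items()})
            )
            if v not in proc.dependencies:
                if sympy.simplify(total) != 0:
                    raise ConstraintError(
                        f"composition for {outer!r} implies a dependency on {v!r} "
                        "that the process does not declare"
                    )
                continue
            exprs[v] = total
            substitution[elasticity_symbol(outer, v)] = total
        resolved[outer] = {v: e for v, e in exprs.items()}

    for pname, vname in deriv_zero:
        substitution[elasticity_symbol(pname, vname)] = sympy.Integer(0)

    new = jac.subs(substitution)
    if scale_constraints and new.scales is not None:
        new = replace(
            new,
            scales=replace(
                new.scales,
                constraints=new.scales.constraints + tuple(scale_constraints),
            ),
        )
    return new


def _conservation_constraints(
    spec: ConstraintSpec, model: GeneralizedModel, jac: SymbolicJacobian
) -> list[sympy.Equality]:
    """Flux-matching relations implied by a conservation law.

    For every shared process moving conserved quantity from variable i
    (loss) to variable j (gain), the absolute steady-state fluxes agree:
    ``c_i * w(P,i) * alpha_i * X*_i = c_j * w(P,j) * alpha_j * X*_j``.
    Unknown abundance ratios ``X*_j / X*_i`` are represented by symbols
    ``chi_<j>_<i>``; the Jacobian itself keeps its full size.
    """
    coeffs = {str(k): sympy.nsimplify(v) for k, v in dict(spec.payload["coefficients"]).items()}
    if jac.scales is None:
        return []
    out: list[sympy.Equality] = []
    for p in model.processes:
        losses = [v for v, s in p.contributions if s == "loss" and v in coeffs]
        gains = [v for v, s in p.contributions if s == "gain" and v in coeffs]
        for vi in losses:
            for vj in gains:
                chi = sympy.Symbol(f"chi_{vj.lower()}_{vi.lower()}")
                lhs = coeffs[vi] * jac.scales.weight_of(p.name, vi) * jac.scales.turnover[vi]
                rhs = coeffs[vj] * jac.scales.weight_of(p.name, vj) * jac.scales.turnover[vj] * chi
                out.append(sympy.Eq(lhs, rhs))
    return out
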