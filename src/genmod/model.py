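"""Structural skeleton of a generalized model.

A generalized model (GM) declares *structure* rather than equations:
state variables, the signed processes (gains and losses) acting on them,
the dependency set of each process, and optional algebraic constraints.
All quantitative detail -- kinetic laws, rate constants, the location of
the steady state -- is deliberately left unspecified; it is later captured
by interpretable scale and exponent parameters during normalization.

Every variable and every process rate is assumed strictly positive.
Processes that could run in both directions are not representable; declare
two antagonistic one-way processes instead (e.g. forward and reverse
reaction, emigration and immigration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

from .errors import NamingError, StructuralError

Sign = Literal["gain", "loss"]

_VALID_KINDS = (
    "function_composition",
    "explicit_inner",
    "derivative_condition",
    "conservation_law",
)


@dataclass(frozen=True)
class Variable:
    """A state variable; semantically a strictly positive quantity."""

    name: str
    description: str = ""


@dataclass(frozen=True)
class Process:
    """A one-way process contributing gains and/or losses to equations.

    Parameters
    ----------
    name:
        Identifier, unique within a model.
    contributions:
        ``(variable, sign)`` pairs; a *shared* process may contribute to
        several equations (e.g. a transfer that is a loss to one variable
        and a gain to another), but with at most one sign per equation.
    dependencies:
        Ordered tuple of variable names the process may depend on.  An
        exponent parameter (elasticity) exists only for declared pairs;
        undeclared dependencies are structural zeros in the Jacobian.
    """

    name: str
    contributions: tuple[tuple[str, Sign], ...]
    dependencies: tuple[str, ...] = ()

    def sign_for(self, variable: str) -> Sign | None:
        for var, sign in self.contributions:
            if var == variable:
                return sign
        return None


@dataclass(frozen=True)
class ConstraintSpec:
    """An algebraic constraint attached to a model.

    Kinds
    -----
    ``function_composition``
        An outer process is an unspecified function of inner arguments,
        e.g. predator gain as a function of prey loss, ``G = H(F, C)``.
        Payload keys: ``outer`` (process name), ``function`` (name of the
        unspecified outer function, e.g. ``"H"``), ``args`` (inner
        argument names: processes or explicit-inner auxiliaries),
        optional ``fixed`` mapping outer-elasticity symbol names to
        numbers (e.g. ``{"h_f": 1}`` for constant conversion efficiency).
    ``explicit_inner``
        A closed-form auxiliary quantity, e.g. per-capita consumption
        ``C = F/Y``.  Payload keys: ``name``, ``expr`` (expression string
        in declared variables and processes).
    ``derivative_condition``
        The derivative of a process w.r.t. a variable vanishes at the
        steady state, fixing the corresponding elasticity to zero.
        Payload keys: ``process``, ``variable``.
    ``conservation_law``
        A weighted sum of variables is conserved.  Payload key:
        ``coefficients`` mapping variable names to weights.
    """

    kind: str
    payload: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise StructuralError(f"unknown constraint kind {self.kind!r}")


@dataclass(frozen=True)
class GeneralizedModel:
    """Declared structure of a generalized model."""

    variables: tuple[Variable, ...] = ()
    processes: tuple[Process, ...] = ()
    constraints: tuple[ConstraintSpec, ...] = ()

    # -- accessors ---------------------------------------------------------
    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def process(self, name: str) -> Process:
        for p in self.processes:
            if p.name == name:
                return p
        raise NamingError(f"unknown process {name!r}")

    def processes_for(self, variable: str, sign: Sign) -> tuple[Process, ...]:
        """Processes contributing to *variable*'s equation with *sign*,
        in declaration order."""
        return tuple(
            p for p in self.processes if p.sign_for(variable) == sign
        )

    # -- construction ------------------------------------------------------
    def add_variable(self, name: str, description: str = "") -> "GeneralizedModel":
        if name in self.variable_names:
            raise NamingError(f"variable {name!r} already declared")
        return replace(self, variables=self.variables + (Variable(name, description),))

    def add_process(
        self,
        name: str,
        contributions: Sequence[tuple[str, Sign]],
        dependencies: Sequence[str] = (),
    ) -> "GeneralizedModel":
        if any(p.name == name for p in self.processes):
            raise NamingError(f"process {name!r} already declared")
        contribs = tuple((str(v), s) for v, s in contributions)
        if not contribs:
            raise StructuralError(f"process {name!r} has no contributions")
        known = set(self.variable_names)
        for var, sign in contribs:
            if var not in known:
                raise StructuralError(
                    f"process {name!r} contributes to undeclared variable {var!r}"
                )
            if sign not in ("gain", "loss"):
                raise StructuralError(f"invalid sign {sign!r} for process {name!r}")
        seen: dict[str, str] = {}
        for var, sign in contribs:
            if var in seen and seen[var] != sign:
                raise StructuralError(
                    f"process {name!r} contributes with both signs to {var!r};"
                    " declare two antagonistic processes instead"
                )
            seen[var] = sign
        for dep in dependencies:
            if dep not in known:
                raise StructuralError(
                    f"process {name!r} depends on undeclared variable {dep!r}"
                )
        proc = Process(name, contribs, tuple(dict.fromkeys(dependencies)))
        return replace(self, processes=self.processes + (proc,))

    def add_constraint(self, constraint: ConstraintSpec) -> "GeneralizedModel":
        return replace(self, constraints=self.constraints + (constraint,))

    # -- validation --------------------------------------------------------
    def validate(self) -> list[str]:
        """Return a list of structural violations; empty iff well-formed.

        Every state variable needs at least one gain and at least one loss
        process, and all constraint references must resolve.
        """
        report: list[str] = []
        names = self.variable_names
        if len(set(names)) != len(names):
            report.append("duplicate variable names")
        pnames = [p.name for p in self.processes]
        if len(set(pnames)) != len(pnames):
            report.append("duplicate process names")
        for var in names:
            if not self.processes_for(var, "gain"):
                report.append(f"variable {var!r}: missing gain process")
            if not self.processes_for(var, "loss"):
                report.append(f"variable {var!r}: missing loss process")
        known = set(names) | set(pnames)
        inner_names = {
            str(c.payload["name"])
            for c in self.constraints
            if c.kind == "explicit_inner"
        }
        known |= inner_names
        for c in self.constraints:
            for ref in _constraint_references(c):
                if ref not in known:
                    report.append(
                        f"constraint {c.kind}: unknown reference {ref!r}"
                    )
        return report


def _constraint_references(c: ConstraintSpec) -> list[str]:
    if c.kind == "function_composition":
        return [str(c.payload["outer"]), *map(str, c.payload["args"])]
    if c.kind == "explicit_inner":
        import sympy

        expr = sympy.sympify(str(c.payload["expr"]))
        return sorted(str(s) for s in expr.free_symbols)
    if c.kind == "derivative_condition":
        return [str(c.payload["process"]), str(c.payload["variable"])]
    if c.kind == "conservation_law":
        return sorted(map(str, dict(c.payload["coefficients"])))
    return []


# Functional aliases matching the operation-style interface -----------------

def add_variable(model: GeneralizedModel, name: str, description: str = "") -> GeneralizedModel:
    """Return *model* with a new variable appended."""
    return model.add_variable(name, description)


def add_process(
    model: GeneralizedModel,
    name: str,
    contributions: Sequence[tuple[str, Sign]],
    dependencies: Sequence[str] = (),
) -> GeneralizedModel:
    """Return *model* with a new signed process appended."""
    return model.add_process(name, contributions, dependencies)


def validate_structure(model: GeneralizedModel) -> list[str]:
    """Structural validation report; empty iff the model is well-formed."""
    return model.validate()
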