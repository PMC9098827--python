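"""YAML model configurations, result serialization and run manifests.

The configuration format declares the same information as the Python
API: variables, signed processes with dependency sets, constraints,
optional explicit parameter values and sampling ranges, and an optional
timescale reference.  Round-tripping a model through the format is
lossless.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError, StructuralError
from .fixtures import FIXTURE_NAMES, default_ranges, fixture
from .jacobian import build_jacobian
from .model import ConstraintSpec, GeneralizedModel
from .sampling import ParameterRanges

__all__ = [
    "load_model_config",
    "save_model_config",
    "model_to_dict",
    "model_from_dict",
    "resolve_model",
    "model_hash",
    "write_manifest",
]


def model_to_dict(
    model: GeneralizedModel,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    parameters: Mapping[str, float] | None = None,
    timescale_reference: str | None = None,
) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "variables": [
            {"name": v.name, **({"description": v.description} if v.description else {})}
            for v in model.variables
        ],
        "processes": [
            {
                "name": p.name,
                "contributions": [
                    {"variable": v, "sign": s} for v, s in p.contributions
                ],
                "dependencies": list(p.dependencies),
            }
            for p in model.processes
        ],
    }
    if model.constraints:
        doc["constraints"] = [
            {"kind": c.kind, **_jsonable(dict(c.payload))} for c in model.constraints
        ]
    if parameters:
        doc["parameters"] = {k: float(v) for k, v in parameters.items()}
    if ranges:
        doc["ranges"] = {k: [float(lo), float(hi)] for k, (lo, hi) in ranges.items()}
    if timescale_reference:
        doc["timescale_reference"] = timescale_reference
    return doc


def _jsonable(payload: dict[str, Any]) -> dict[str, Any]:
    out = {}
    for k, v in payload.items():
        if isinstance(v, Mapping):
            out[k] = {str(kk): (float(vv) if isinstance(vv, (int, float)) else str(vv)) for kk, vv in v.items()}
        elif isinstance(v, (list, tuple)):
            out[k] = [str(x) for x in v]
        else:
            out[k] = v if isinstance(v, (int, float)) else str(v)
    return out


def model_from_dict(doc: Mapping[str, Any]) -> tuple[GeneralizedModel, dict[str, Any]]:
    """Build a model from a parsed configuration document.

    Returns the model and a dict of extras (``parameters``, ``ranges``,
    ``timescale_reference``).  Raises :class:`ConfigurationError` with a
    located message on schema violations and :class:`StructuralError` on
    validation failures.
    """
    if not isinstance(doc, Mapping):
        raise ConfigurationError("configuration root must be a mapping")
    m = GeneralizedModel()
    for i, v in enumerate(doc.get("variables", [])):
        if isinstance(v, str):
            m = m.add_variable(v)
        elif isinstance(v, Mapping) and "name" in v:
            m = m.add_variable(str(v["name"]), str(v.get("description", "")))
        else:
            raise ConfigurationError(f"variables[{i}]: expected a name or mapping with 'name'")
    for i, p in enumerate(doc.get("processes", [])):
        if not isinstance(p, Mapping) or "name" not in p:
            raise ConfigurationError(f"processes[{i}]: expected a mapping with 'name'")
        contribs = []
        for j, c in enumerate(p.get("contributions", [])):
            if not isinstance(c, Mapping) or "variable" not in c or "sign" not in c:
                raise ConfigurationError(
                    f"processes[{i}].contributions[{j}]: need 'variable' and 'sign'"
                )
            contribs.append((str(c["variable"]), str(c["sign"])))
        m = m.add_process(str(p["name"]), contribs, [str(d) for d in p.get("dependencies", [])])
    for i, c in enumerate(doc.get("constraints", [])):
        if not isinstance(c, Mapping) or "kind" not in c:
            raise ConfigurationError(f"constraints[{i}]: expected a mapping with 'kind'")
        payload = {k: v for k, v in c.items() if k != "kind"}
        m = m.add_constraint(ConstraintSpec(str(c["kind"]), payload))
    report = m.validate()
    if report:
        raise StructuralError("model fails validation: " + "; ".join(report))
    extras = {
        "parameters": {str(k): float(v) for k, v in dict(doc.get("parameters", {})).items()},
        "ranges": {
            str(k): (float(v[0]), float(v[1]))
            for k, v in dict(doc.get("ranges", {})).items()
        },
        "timescale_reference": doc.get("timescale_reference"),
    }
    _check_branching_sums(m, extras["parameters"])
    return m, extras


def _check_branching_sums(model: GeneralizedModel, parameters: Mapping[str, float]) -> None:
    """Explicitly given weights of a branching group must sum to one."""
    from .jacobian import _weight_symbol

    for var in model.variable_names:
        for sign in ("gain", "loss"):
            procs = model.processes_for(var, sign)
            if len(procs) < 2:
                continue
            names = [
                _weight_symbol(
                    p, var, sign,
                    sum(1 for _, s in p.contributions if s == sign) > 1,
                ).name
                for p in procs
            ]
            given = [parameters[n] for n in names if n in parameters]
            if len(given) == len(names) and abs(sum(given) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"branching group ({var}, {sign}) weights {names} sum to "
                    f"{sum(given):.6g}, expected 1"
                )


def load_model_config(path: str | Path) -> tuple[GeneralizedModel, dict[str, Any]]:
    """Load and validate a model configuration file."""
    p = Path(path)
    try:
        text = p.read_text()
    except OSError as exc:
        raise ConfigurationError(f"cannot read {p}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{p}: YAML parse error: {exc}") from exc
    return model_from_dict(doc or {})


def save_model_config(
    model: GeneralizedModel,
    path: str | Path,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    parameters: Mapping[str, float] | None = None,
    timescale_reference: str | None = None,
) -> None:
    doc = model_to_dict(model, ranges=ranges, parameters=parameters,
                        timescale_reference=timescale_reference)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def resolve_model(source: str) -> tuple[GeneralizedModel, dict[str, Any]]:
    """Resolve a model source: a fixture name or a configuration path."""
    if source in FIXTURE_NAMES:
        model = fixture(source)
        ref = "X" if "X" in model.variable_names else None
        jac = build_jacobian(model, timescale_reference=ref)
        extras = {
            "parameters": {},
            "ranges": default_ranges(tuple(s.name for s in jac.free_symbols)),
            "timescale_reference": ref,
        }
        return model, extras
    return load_model_config(source)


def model_hash(model: GeneralizedModel) -> str:
    canonical = json.dumps(model_to_dict(model), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    analysis: str,
    model: GeneralizedModel,
    seed: int | None,
    tolerances: Mapping[str, float] | None = None,
    outputs: list[str] | None = None,
) -> Path:
    """Record everything needed to reproduce a run."""
    from . import __version__

    manifest = {
        "analysis": analysis,
        "model_hash": model_hash(model),
        "seed": seed,
        "tool_version": __version__,
        "tolerances": dict(tolerances or {}),
        "outputs": outputs or [],
        "conventions": {
            "branching_sampling": "uniform on the simplex (flat Dirichlet)",
            "boundary_classification": "Re(lead) = 0 counts as unstable",
            "eigenvalue_backend": "dense up to 200 variables, iterative above",
        },
    }
    p = Path(out_dir) / f"{analysis}_manifest.json"
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(manifest, indent=2))
    return p
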