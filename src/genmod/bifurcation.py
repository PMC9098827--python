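"""Bifurcation detection along parameter paths and diagram grids.

Steady states of a generalized model lose stability in only two generic
ways: a single real eigenvalue crosses zero (saddle-node-type
bifurcation; the number of steady states changes) or a complex-conjugate
pair crosses the imaginary axis (Hopf; onset of oscillations).  The
zero-eigenvalue case is located through the determinant -- the Jacobian
has a zero eigenvalue iff det J = 0, and determinants remain cheap at
any system size.  Hopf points are located by tracking the largest real
part among non-real eigenvalues and bisecting its sign changes; an
optional algebraic cross-check via the bialternate product (whose
determinant vanishes when two eigenvalues sum to zero) is provided for
small systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import ConfigurationError, NumericError, StructuralError
from .jacobian import SymbolicJacobian
from .sampling import ParameterRanges, _draw_samples, _pick_leading

__all__ = [
    "ParameterPath",
    "BifurcationHit",
    "DiagramGrid",
    "scan_zero_eigenvalue",
    "scan_hopf",
    "classify_grid",
    "bialternate_determinant",
]

#: Default number of initial bracketing points along a path.
BRACKET_POINTS = 200


@dataclass(frozen=True)
class ParameterPath:
    """A 1-parameter path through generalized parameter space.

    Either ``vary=(symbol_name, (lo, hi))`` on top of a ``base`` set, or an
    explicit ``waypoints`` list of full parameter dicts that is
    piecewise-linearly interpolated.
    """

    base: Mapping[str, float] = field(default_factory=dict)
    vary: tuple[str, tuple[float, float]] | None = None
    waypoints: Sequence[Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if (self.vary is None) == (self.waypoints is None):
            raise ConfigurationError("specify exactly one of vary= or waypoints=")
        if self.waypoints is not None and len(self.waypoints) < 2:
            raise ConfigurationError("waypoint path needs at least two points")

    def at(self, t: float) -> dict[str, float]:
        """Parameter set at path coordinate t in [0, 1]."""
        if self.vary is not None:
            name, (lo, hi) = self.vary
            return {**dict(self.base), name: lo + t * (hi - lo)}
        pts = [dict(w) for w in self.waypoints]  # type: ignore[union-attr]
        pos = t * (len(pts) - 1)
        k = min(int(pos), len(pts) - 2)
        frac = pos - k
        return {
            key: (1 - frac) * pts[k][key] + frac * pts[k + 1][key]
            for key in pts[0]
        }

    def coordinate_label(self) -> str:
        return self.vary[0] if self.vary is not None else "t"

    def coordinate(self, t: float) -> float:
        """Human-readable location: the varied parameter's value, else t."""
        if self.vary is not None:
            lo, hi = self.vary[1]
            return lo + t * (hi - lo)
        return t


@dataclass(frozen=True)
class BifurcationHit:
    """A located bifurcation on a parameter path."""

    type: str  # "zero_eigenvalue" | "hopf"
    location: float  # value of the varied parameter (or path coordinate t)
    parameters: Mapping[str, float]
    eigenvalues: tuple[complex, ...]  # critical eigenvalue(s)
    residual: float  # |det J| for zero-eigenvalue hits, |Re lambda_pair| for Hopf


@dataclass(frozen=True)
class DiagramGrid:
    """Stability classes on a 2- or 3-parameter grid (one row per cell)."""

    table: pd.DataFrame
    axes: tuple[str, ...]
    seed: int | None = None


def _matrix_fn(
    jac: SymbolicJacobian, path: ParameterPath
) -> Callable[[float], np.ndarray]:
    def fn(t: float) -> np.ndarray:
        return jac.evaluate(path.at(t))

    return fn


def scan_zero_eigenvalue(
    jac: SymbolicJacobian,
    path: ParameterPath,
    tolerance: float = 1e-8,
    bracket_points: int = BRACKET_POINTS,
) -> list[BifurcationHit]:
    """Locate zero-eigenvalue (saddle-node-type) bifurcations on a path.

    The determinant of the Jacobian is evaluated on an initial bracketing
    grid; every sign change is refined by bisection (Brent) until the
    path coordinate is resolved to ``tolerance``.  Hits are returned in
    path order.
    """
    mfn = _matrix_fn(jac, path)

    def det(t: float) -> float:
        d = float(np.linalg.det(mfn(t)))
        if not np.isfinite(d):
            raise NumericError(f"non-finite determinant at path coordinate {t}")
        return d

    ts = np.linspace(0.0, 1.0, bracket_points)
    vals = np.array([det(t) for t in ts])
    hits: list[BifurcationHit] = []
    for a, b, fa, fb in zip(ts[:-1], ts[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            root = a
        elif fa * fb < 0:
            root = scipy.optimize.brentq(det, a, b, xtol=tolerance)
        else:
            continue
        m = mfn(root)
        eig = np.linalg.eigvals(m)
        crit = eig[np.argmin(np.abs(eig))]
        hits.append(
            BifurcationHit(
                type="zero_eigenvalue",
                location=path.coordinate(root),
                parameters=path.at(root),
                eigenvalues=(complex(crit),),
                residual=abs(float(np.linalg.det(m))),
            )
        )
    return hits


def _hopf_margin(m: np.ndarray, im_floor: float) -> float:
    """Largest real part among genuinely non-real eigenvalues; NaN if the
    spectrum is entirely (numerically) real."""
    eig = np.linalg.eigvals(m)
    complex_mask = np.abs(eig.imag) > im_floor
    if not np.any(complex_mask):
        return np.nan
    return float(np.max(eig.real[complex_mask]))


def scan_hopf(
    jac: SymbolicJacobian,
    path: ParameterPath,
    tolerance: float = 1e-8,
    bracket_points: int = BRACKET_POINTS,
) -> list[BifurcationHit]:
    """Locate Hopf bifurcations (complex pair crossing the axis) on a path.

    Eigenvalues are tracked along the path; sign changes of the largest
    real part among non-real eigenvalues are bisected.  A candidate is
    accepted only if the pair is genuinely non-real and the determinant
    stays away from zero (excluding zero-eigenvalue hits).
    """
    if jac.n < 2:
        raise StructuralError("no Hopf bifurcation in a one-dimensional system")
    mfn = _matrix_fn(jac, path)
    im_floor = tolerance

    def margin(t: float) -> float:
        return _hopf_margin(mfn(t), im_floor)

    ts = np.linspace(0.0, 1.0, bracket_points)
    vals = np.array([margin(t) for t in ts])
    hits: list[BifurcationHit] = []
    for a, b, fa, fb in zip(ts[:-1], ts[1:], vals[:-1], vals[1:]):
        if np.isnan(fa) or np.isnan(fb) or not fa * fb < 0:
            continue
        lo, hi = a, b
        while hi - lo > tolerance:
            mid = 0.5 * (lo + hi)
            fm = margin(mid)
            if np.isnan(fm):
                break
            if fa * fm <= 0:
                hi = mid
            else:
                lo, fa = mid, fm
        root = 0.5 * (lo + hi)
        m = mfn(root)
        eig = np.linalg.eigvals(m)
        complex_mask = np.abs(eig.imag) > im_floor
        if not np.any(complex_mask):
            continue
        pair_idx = np.argmin(np.abs(eig.real[complex_mask]))
        lam = eig[complex_mask][pair_idx]
        if lam.imag < 0:
            lam = lam.conjugate()
        det = abs(float(np.linalg.det(m)))
        if det <= tolerance:
            continue  # zero-eigenvalue point, not a Hopf
        hits.append(
            BifurcationHit(
                type="hopf",
                location=path.coordinate(root),
                parameters=path.at(root),
                eigenvalues=(complex(lam), complex(lam.conjugate())),
                residual=abs(lam.real),
            )
        )
    return hits


def bialternate_determinant(m: np.ndarray) -> float:
    """Determinant of the bialternate product ``2 M (.) I``.

    This algebraic quantity vanishes whenever two eigenvalues of ``M``
    sum to zero -- in particular on a Hopf locus, where the pair is
    ``+/- i omega``.  Useful as a cross-check for small systems; the
    expressions degrade beyond roughly ten variables.
    """
    a = np.asarray(m, dtype=float)
    n = a.shape[0]
    pairs = [(p, q) for p in range(1, n) for q in range(p)]
    size = len(pairs)
    out = np.zeros((size, size))
    for row, (p, q) in enumerate(pairs):
        for col, (r, s) in enumerate(pairs):
            if r == p and s == q:
                out[row, col] = a[p, p] + a[q, q]
            elif r == q:
                out[row, col] = -a[p, s]
            elif r != p and s == q:
                out[row, col] = a[p, r]
            elif r == p and s != q:
                out[row, col] = a[q, s]
            elif s == p:
                out[row, col] = -a[q, r]
    return float(np.linalg.det(out))


def classify_grid(
    jac: SymbolicJacobian,
    axes: Mapping[str, Sequence[float]],
    remainder: Mapping[str, float] | None = None,
    ranges: ParameterRanges | None = None,
    m_per_cell: int = 1,
    seed: int | None = None,
) -> DiagramGrid:
    """Classify stability on a 2- or 3-parameter grid.

    Per cell the axis parameters are clamped; the remaining parameters
    are either fixed (``remainder``, deterministic diagrams) or sampled
    from ``ranges`` (PSW-style coloring, ``m_per_cell`` draws).  Classes:
    ``stable`` (leading real part negative), ``unstable_oscillatory``
    (unstable with a non-real leading eigenvalue -- the Hopf side) and
    ``unstable_real`` (unstable through a real eigenvalue -- the
    saddle-node side).
    """
    if not 2 <= len(axes) <= 3:
        raise ConfigurationError("classify_grid supports two or three axes")
    names = {s.name for s in jac.free_symbols}
    for ax in axes:
        if ax not in names:
            raise ConfigurationError(f"axis parameter {ax!r} not in the Jacobian")
        if not len(axes[ax]):
            raise ConfigurationError(f"empty grid for axis {ax!r}")
    axis_names = list(axes)
    mesh = np.meshgrid(*[np.asarray(axes[a], dtype=float) for a in axis_names], indexing="ij")
    cells = np.stack([g.ravel() for g in mesh], axis=-1)
    rows = []
    if remainder is None and ranges is None:
        remainder = {}
    rng = np.random.default_rng(seed)
    for cell in cells:
        point = {a: float(v) for a, v in zip(axis_names, cell)}
        if ranges is not None:
            draws = _draw_samples(jac, ranges, m_per_cell, rng, clamp=point)
            stacked = jac.evaluate_many({c: draws[c].to_numpy() for c in draws.columns})
            leads = [_pick_leading(np.linalg.eigvals(mm)) for mm in stacked]
            frac = np.mean([l.real < 0 for l in leads])
            lead = leads[0]
            cls = _classify(lead) if m_per_cell == 1 else ("stable" if frac >= 0.5 else "unstable")
            rows.append({**point, "class": cls, "psw": float(frac)})
        else:
            full = {**dict(remainder), **point}
            missing = [n for n in names if n not in full]
            if missing:
                raise ConfigurationError(f"no value for parameters {missing}")
            lead = _pick_leading(np.linalg.eigvals(jac.evaluate(full)))
            rows.append(
                {**point, "class": _classify(lead), "lead_re": lead.real, "lead_im": lead.imag}
            )
    return DiagramGrid(table=pd.DataFrame(rows), axes=tuple(axis_names), seed=seed)


def _classify(lead: complex, im_floor: float = 1e-12) -> str:
    if lead.real < 0:
        return "stable"
    return "unstable_oscillatory" if abs(lead.imag) > im_floor else "unstable_real"
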