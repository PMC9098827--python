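"""Ensemble exploration of generalized parameter space.

Given a symbolic Jacobian whose free parameters are interpretable scale
and exponent parameters, this module draws random parameter ensembles,
classifies the stability of each sampled steady state by the leading
eigenvalue, correlates individual parameters with stability, and sweeps
parameters to estimate the proportion of stable webs (PSW).

Sampling conventions
--------------------
Scalar parameters are drawn uniformly from their declared ranges.  The
free weights of a k-way branching group are drawn uniformly on the
(k-1)-simplex (flat Dirichlet over the k weights, keeping the first k-1;
the last weight is one minus their sum by construction), so all
admissible branchings are equally likely.  A steady state on the
stability boundary (leading real part exactly zero) counts as unstable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse.linalg

from .errors import ConfigurationError, NumericError
from .jacobian import SymbolicJacobian

__all__ = [
    "ParameterRanges",
    "EnsembleResult",
    "SweepResult",
    "leading_eigenvalue",
    "stability_indicator",
    "sample_ensemble",
    "stability_correlation",
    "proportion_stable_sweep",
]

#: Dimension above which the iterative largest-real-part eigensolver is tried
#: before falling back to the dense solver.
DENSE_LIMIT = 200


@dataclass(frozen=True)
class ParameterRanges:
    """Uniform sampling ranges per free scalar parameter.

    ``bounds`` maps parameter names to ``(low, high)``; branching-group
    weights are sampled on the simplex and need no entry.  Degenerate
    ranges (low == high) clamp the parameter.
    """

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not (lo <= hi):
                raise ConfigurationError(f"range for {name!r} has lower > upper")

    def with_overrides(self, **bounds: tuple[float, float]) -> "ParameterRanges":
        return ParameterRanges({**dict(self.bounds), **bounds})


@dataclass(frozen=True)
class EnsembleResult:
    """Sampled parameter sets with stability labels.

    ``samples`` has one column per parameter (symbol-name headers), one
    row per draw; ``lead`` holds the leading eigenvalue per draw and
    ``stable`` the 0/1 stability indicator.
    """

    samples: pd.DataFrame
    lead: np.ndarray
    stable: np.ndarray
    seed: int

    @property
    def psw(self) -> float:
        """Fraction of stable samples (proportion of stable webs)."""
        return float(np.mean(self.stable))

    def to_frame(self) -> pd.DataFrame:
        df = self.samples.copy()
        df["lead_re"] = self.lead.real
        df["lead_im"] = self.lead.imag
        df["stable"] = self.stable
        return df


@dataclass(frozen=True)
class SweepResult:
    """PSW on a 1- or 2-parameter grid; ``table`` has one row per cell."""

    table: pd.DataFrame
    swept: tuple[str, ...]
    seed: int


# ---------------------------------------------------------------------------
# Eigenvalues and stability
# ---------------------------------------------------------------------------

def leading_eigenvalue(j_num: np.ndarray) -> complex:
    """Eigenvalue of maximal real part.

    Ties on the real part are broken by larger imaginary modulus; of a
    conjugate pair the member with nonnegative imaginary part is
    returned.  Dense solve for dimensions up to ``DENSE_LIMIT``; above
    that an iterative largest-real-part solver is tried with a dense
    fallback on non-convergence (both agree wherever both run).
    """
    a = np.asarray(j_num)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise NumericError("leading_eigenvalue requires a square matrix")
    if not np.all(np.isfinite(a)):
        raise NumericError("non-finite matrix entries")
    n = a.shape[0]
    if n > DENSE_LIMIT:
        try:
            vals = scipy.sparse.linalg.eigs(
                a.astype(float), k=min(6, n - 2), which="LR",
                return_eigenvectors=False,
            )
            return _pick_leading(vals)
        except Exception:  # pragma: no cover - fallback path
            pass
    vals = np.linalg.eigvals(a)
    return _pick_leading(vals)


def _pick_leading(vals: np.ndarray) -> complex:
    order = sorted(
        vals, key=lambda z: (round(z.real, 14), abs(z.imag)), reverse=True
    )
    lead = order[0]
    if lead.imag < 0:
        lead = lead.conjugate()
    return complex(lead)


def stability_indicator(lam0: complex) -> int:
    """1 if the steady state is stable (Re < 0, strict), else 0."""
    return 1 if lam0.real < 0 else 0


# ---------------------------------------------------------------------------
# Ensemble sampling
# ---------------------------------------------------------------------------

def _draw_samples(
    jac: SymbolicJacobian,
    ranges: ParameterRanges,
    m: int,
    rng: np.random.Generator,
    clamp: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    clamp = dict(clamp or {})
    groups = jac.branching_groups
    group_syms = {s.name for g in groups for s in g}
    columns: dict[str, np.ndarray] = {}
    for sym in jac.free_symbols:
        name = sym.name
        if name in clamp:
            columns[name] = np.full(m, float(clamp[name]))
        elif name in group_syms:
            continue  # drawn jointly below
        elif name in ranges.bounds:
            lo, hi = ranges.bounds[name]
            columns[name] = rng.uniform(lo, hi, size=m) if hi > lo else np.full(m, lo)
        else:
            raise ConfigurationError(f"no sampling range declared for parameter {name!r}")
    for grp in groups:
        k = len(grp) + 1  # group size including the eliminated last weight
        simplex = rng.dirichlet(np.ones(k), size=m)
        for idx, sym in enumerate(grp):
            if sym.name in clamp:
                columns[sym.name] = np.full(m, float(clamp[sym.name]))
            else:
                columns[sym.name] = simplex[:, idx]
    return pd.DataFrame({s.name: columns[s.name] for s in jac.free_symbols})


def sample_ensemble(
    jac: SymbolicJacobian,
    ranges: ParameterRanges,
    m: int,
    seed: int,
    _clamp: Mapping[str, float] | None = None,
) -> EnsembleResult:
    """Draw ``m`` random parameter sets and classify their stability.

    Identical ``(ranges, m, seed)`` yield bitwise-identical results.
    """
    if m < 1:
        raise ConfigurationError("need at least one sample")
    rng = np.random.default_rng(seed)
    samples = _draw_samples(jac, ranges, m, rng, clamp=_clamp)
    stacked = jac.evaluate_many({c: samples[c].to_numpy() for c in samples.columns})
    vals = np.linalg.eigvals(stacked)  # batched over the leading axis
    lead = np.empty(m, dtype=complex)
    for i in range(m):
        lead[i] = _pick_leading(vals[i])
    stable = (lead.real < 0).astype(int)
    return EnsembleResult(samples=samples, lead=lead, stable=stable, seed=seed)


def stability_correlation(
    ens: EnsembleResult, normalized: bool = True
) -> pd.Series:
    """Correlation of each parameter with the stability indicator.

    Positive values mark stabilizing parameters, negative destabilizing
    ones; the Pearson normalization calibrates a parameter that fully
    explains stability to +/-1.  With ``normalized=False`` the raw
    covariance is returned instead.  If every sample has the same
    stability label the correlation is undefined and NaN is returned for
    every parameter (with a warning).
    """
    if len(ens.stable) < 2:
        raise ConfigurationError("correlation needs at least two samples")
    s = ens.stable.astype(float)
    out = {}
    s_std = s.std()
    if s_std == 0:
        warnings.warn("stability indicator is constant; correlations undefined")
    for col in ens.samples.columns:
        p = ens.samples[col].to_numpy()
        cov = np.mean((p - p.mean()) * (s - s.mean()))
        if not normalized:
            out[col] = cov
        elif s_std == 0 or p.std() == 0:
            out[col] = np.nan
        else:
            out[col] = cov / (p.std() * s_std)
    return pd.Series(out, name="stability_correlation")


def proportion_stable_sweep(
    jac: SymbolicJacobian,
    ranges: ParameterRanges,
    sweep: Mapping[str, Sequence[float]],
    m_per_cell: int,
    seed: int,
) -> SweepResult:
    """Systematically vary 1-2 parameters while randomizing the rest.

    Per grid cell the swept parameters are clamped to the cell value,
    ``m_per_cell`` draws of the remaining parameters are taken, and the
    fraction of stable samples (PSW) is recorded.  Each cell uses an
    independent child seed derived from ``seed``, so cell results are
    reproducible and order-independent.
    """
    swept = list(sweep)
    if not 1 <= len(swept) <= 2:
        raise ConfigurationError("sweep supports one or two parameters")
    names = {s.name for s in jac.free_symbols}
    for p in swept:
        if p not in names:
            raise ConfigurationError(f"swept parameter {p!r} not in the Jacobian")
        if not len(sweep[p]):
            raise ConfigurationError(f"empty grid for swept parameter {p!r}")
    grids = [np.asarray(sweep[p], dtype=float) for p in swept]
    mesh = np.meshgrid(*grids, indexing="ij")
    cells = np.stack([g.ravel() for g in mesh], axis=-1)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(cells))]
    rows = []
    for cell, cseed in zip(cells, child_seeds):
        clamp = {p: float(v) for p, v in zip(swept, cell)}
        ens = sample_ensemble(jac, ranges, m_per_cell, cseed, _clamp=clamp)
        rows.append({**clamp, "psw": ens.psw, "n": m_per_cell})
    return SweepResult(table=pd.DataFrame(rows), swept=tuple(swept), seed=seed)
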