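"""Press-perturbation response and eigenvector-based importance scores.

A press perturbation is a sustained change of conditions whose direct
impact on the equations is collected in a vector ``p`` (in units of the
normalized turnover; a loss term removing a fraction eps of a variable's
turnover contributes ``-eps``).  For a sufficiently small press the
induced steady-state shift of the normalized variables is

    delta = -J^{-1} p

so an element of 0.05 means a 5% increase of that variable's steady
state.  Eigenvector-based scores summarize the response to *typical*
perturbations: the sensitivity of variable i aggregates left-eigenvector
weight over slow modes, the influence aggregates right-eigenvector
weight, and their product is the dynamical importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import NumericError

__all__ = [
    "press_response",
    "sensitivity_influence",
    "dynamical_importance",
    "SensitivityScores",
]

#: Condition-number thresholds: warn when the Jacobian is nearly singular
#: (the linear response presumes distance from any bifurcation), error when
#: the inverse is numerically meaningless.
COND_WARN = 1e8
COND_ERROR = 1e12


@dataclass(frozen=True)
class SensitivityScores:
    """Per-variable sensitivity, influence and their product."""

    sensitivity: np.ndarray
    influence: np.ndarray

    @property
    def importance(self) -> np.ndarray:
        return self.sensitivity * self.influence


def press_response(j_num: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Steady-state shift ``delta = -J^{-1} p`` induced by a press ``p``.

    Raises when the Jacobian is singular (steady state at a bifurcation;
    the response is undefined there) and warns when it is close enough
    to singular that the linear prediction is unreliable.
    """
    a = np.asarray(j_num, dtype=float)
    b = np.asarray(p, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or b.shape != (a.shape[0],):
        raise NumericError("shape mismatch between Jacobian and press vector")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise NumericError("non-finite input")
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > COND_ERROR:
        raise NumericError(
            "Jacobian is (numerically) singular: steady state at a bifurcation; "
            "press response undefined"
        )
    if cond > COND_WARN:
        warnings.warn(
            f"Jacobian condition number {cond:.2e}: close to a bifurcation, "
            "linear press response may be inaccurate"
        )
    return -np.linalg.solve(a, b)


def sensitivity_influence(j_num: np.ndarray) -> SensitivityScores:
    """Aggregate response scores from the eigensystem of the Jacobian.

    With eigenvalues ``lambda_n`` and bi-orthogonally normalized left and
    right eigenvectors ``v_n``, ``w_n`` (``|w_n| = 1``, ``v_n . w_n = 1``):

        Se_i = log( sum_n |v_{n,i}| / |lambda_n| )
        In_i = log( sum_n |w_{n,i}| / |lambda_n| )

    For a stable state all eigenvalues have negative real part and
    ``|lambda_n|`` reduces to ``-lambda_n`` when the spectrum is real; the
    modulus keeps the scores real-valued for complex pairs.  The scores
    are invariant under eigenvector rescaling by construction.  An
    unstable state triggers a warning but still returns scores.
    """
    a = np.asarray(j_num, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise NumericError("sensitivity_influence requires a square matrix")
    vals, right = scipy.linalg.eig(a)
    if np.linalg.matrix_rank(right) < a.shape[0]:
        raise NumericError("defective Jacobian: eigendecomposition incomplete")
    if np.any(vals.real >= 0):
        warnings.warn("unstable steady state: sensitivity scores are formal")
    if np.any(np.abs(vals) == 0):
        raise NumericError("zero eigenvalue: scores undefined at a bifurcation")
    # right eigenvectors to unit norm; left rows from the inverse satisfy
    # v_n . w_n = 1 exactly (bi-orthogonality).
    norms = np.linalg.norm(right, axis=0)
    right = right / norms
    left = np.linalg.inv(right)  # row n is v_n with v_n . w_n = 1
    inv_mod = 1.0 / np.abs(vals)
    se = np.log(np.abs(left).T @ inv_mod)   # sum over modes n of |v_{n,i}|/|l_n|
    infl = np.log(np.abs(right) @ inv_mod)  # sum over modes n of |w_{n,i}|/|l_n|
    return SensitivityScores(sensitivity=se, influence=infl)


def dynamical_importance(scores: SensitivityScores) -> np.ndarray:
    """Elementwise product of sensitivity and influence."""
    return scores.importance
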