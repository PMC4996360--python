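"""Network inference for the linear ODE model ``dx/dt = W x``.

The estimator is deliberately the simplest standard one: approximate the
derivatives by finite differences on the regular sampling grid (central
differences at interior points, one-sided at the endpoints) and solve the
per-gene ordinary least-squares regression ``dx_i/dt ~ sum_j W[i, j] x_j``.
The full ``n x n`` matrix is inferred by default; a boolean support mask can
restrict the regression to a known edge set.  Alternative estimators (e.g. a
matrix-logarithm of the one-step transition matrix) can be swapped in behind
the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .ode import TrajectorySample

__all__ = ["InferenceResult", "infer_parameters", "parameter_log_errors"]

#: absolute-error floor applied before taking log10, keeping logs finite
LOG_ERROR_FLOOR = 1e-12


@dataclass(frozen=True)
class InferenceResult:
    """Estimated interaction matrix plus a rank-deficiency flag.

    ``rank_deficient`` is set when the regression design did not have full
    column rank (e.g. constant trajectories); the estimate is then the
    minimum-norm least-squares solution.
    """

    weights: np.ndarray  # (n, n)
    rank_deficient: bool = False


def infer_parameters(
    sample: TrajectorySample,
    support_mask: np.ndarray | None = None,
    rcond: float | None = None,
) -> InferenceResult:
    """Least-squares estimate of the interaction matrix from sampled states.

    Parameters
    ----------
    sample
        Regularly spaced trajectory with at least 3 sampling times.
    support_mask
        Optional ``(n, n)`` boolean mask; when given, only the masked entries
        are estimated (per-row regression on the permitted regressors) and all
        other entries are fixed at zero.
    rcond
        Relative singular-value cutoff for the least-squares solve (truncated
        SVD).  ``None`` cuts at machine precision only; a cutoff near the
        relative noise level of the derivative estimates (e.g. ``1e-2`` for
        coarsely sampled trajectories) suppresses noise amplification along
        poorly excited directions, at the cost of a minimum-norm bias there.
    """
    if sample.times.size < 3:
        raise ValidationError("need at least 3 samples to estimate derivatives")
    n = sample.n_nodes
    x = sample.states  # (K, n)
    dxdt = np.gradient(x, sample.dt, axis=0)  # central interior, one-sided ends

    if support_mask is None:
        solution, _res, rank, _sv = np.linalg.lstsq(x, dxdt, rcond=rcond)
        return InferenceResult(solution.T, rank_deficient=rank < n)

    mask = np.asarray(support_mask, dtype=bool)
    if mask.shape != (n, n):
        raise ValidationError(f"support_mask must have shape ({n}, {n})")
    weights = np.zeros((n, n))
    deficient = False
    for i in range(n):
        cols = np.flatnonzero(mask[i])
        if cols.size == 0:
            continue
        coef, _res, rank, _sv = np.linalg.lstsq(x[:, cols], dxdt[:, i], rcond=rcond)
        weights[i, cols] = coef
        deficient = deficient or rank < cols.size
    return InferenceResult(weights, rank_deficient=deficient)


def parameter_log_errors(
    true_weights: np.ndarray,
    estimated: np.ndarray,
    floor: float = LOG_ERROR_FLOOR,
) -> np.ndarray:
    """Per-parameter ``log10(|estimated - true| + floor)``, flattened.

    The additive floor keeps exactly recovered parameters at ``log10(floor)``
    instead of ``-inf``; with the default floor an exact recovery scores -12.
    """
    true_weights = np.asarray(true_weights, dtype=np.float64)
    estimated = np.asarray(estimated, dtype=np.float64)
    if true_weights.shape != estimated.shape:
        raise ValidationError(
            f"shape mismatch: {true_weights.shape} vs {estimated.shape}"
        )
    return np.log10(np.abs(estimated - true_weights) + floor).ravel()
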