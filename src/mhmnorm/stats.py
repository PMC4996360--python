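"""Correlation matrices, Frobenius-norm errors, and the two-sample KS test.

These are the scoring primitives of both benchmarks: gene-gene Pearson
correlation across time points stands in for the simplest graphical model,
the Frobenius norm measures how far a normalized dataset's correlation
structure drifted from the original, and the Kolmogorov-Smirnov two-sample
test compares the error distributions of two normalization methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .errors import ValidationError
from .matrix import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "correlation_matrix",
    "frobenius_error",
    "ks_two_sample",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Gene-gene Pearson correlations with a defined-entry mask.

    Rows of zero variance have no defined correlation; their entries are
    stored as 0 and flagged in ``defined`` so downstream comparisons can
    exclude them.
    """

    values: np.ndarray  # (M, M), symmetric, entries in [-1, 1]
    defined: np.ndarray  # (M, M) bool; False where either row had zero variance

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


def correlation_matrix(x: ExpressionMatrix) -> CorrelationMatrix:
    """Pearson correlation of every gene pair across time points."""
    if x.n_timepoints < 2:
        raise ValidationError("correlation needs at least 2 time points")
    v = x.values
    centered = v - v.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(centered**2, axis=1))
    constant = norms == 0.0
    safe_norms = np.where(constant, 1.0, norms)
    corr = (centered @ centered.T) / np.outer(safe_norms, safe_norms)
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    defined = ~(constant[:, None] | constant[None, :])
    corr[~defined] = 0.0
    return CorrelationMatrix(corr, defined)


def frobenius_error(a: CorrelationMatrix, b: CorrelationMatrix) -> float:
    """Frobenius norm of ``a - b`` over the entries defined in both.

    Zero exactly when the defined entries agree; undefined (zero-variance)
    entries are excluded from the sum.
    """
    if a.values.shape != b.values.shape:
        raise ValidationError(
            f"shape mismatch: {a.values.shape} vs {b.values.shape}"
        )
    mask = a.defined & b.defined
    diff = (a.values - b.values)[mask]
    return float(np.sqrt(np.sum(diff**2)))


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p-value).

    Returns ``(D, p)`` where ``D`` is the supremum distance between the two
    empirical CDFs.  The asymptotic p-value is appropriate at the sample sizes
    the benchmarks produce (hundreds to thousands).
    """
    a = np.asarray(sample_a, dtype=np.float64).ravel()
    b = np.asarray(sample_b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("KS test requires two non-empty samples")
    result = _scipy_stats.ks_2samp(a, b, method="asymp")
    return float(result.statistic), float(result.pvalue)
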