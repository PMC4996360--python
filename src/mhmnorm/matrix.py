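"""Labeled gene-by-timepoint expression matrices and their delimited-text I/O.

An :class:`ExpressionMatrix` holds an ``M x N`` array of finite expression
values for ``M`` genes measured at ``N`` time points (one array per time
point), together with unique row and column labels.  The on-disk format is a
delimited table whose first column carries gene identifiers and whose header
row carries the time-point labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: accepted delimiter aliases for the text format
DELIMITERS = {"tab": "\t", "comma": ","}


def _normalize_labels(
    labels: Sequence[str] | None, n: int, prefix: str, axis: str
) -> tuple[str, ...]:
    if labels is None:
        return tuple(f"{prefix}{k}" for k in range(n))
    out = tuple(str(lab) for lab in labels)
    if len(out) != n:
        raise ValidationError(
            f"{axis} labels have length {len(out)}, expected {n}"
        )
    if len(set(out)) != n:
        raise ValidationError(f"{axis} labels are not unique")
    return out


@dataclass(frozen=True)
class ExpressionMatrix:
    """M genes x N time points of finite real expression values.

    Parameters
    ----------
    values
        Real matrix of shape ``(M, N)``; coerced to float64.  NaN and
        infinities are rejected: the normalization algorithms need exactly
        ``M * N`` observed values.
    gene_ids, time_labels
        Unique labels for rows and columns.  Auto-generated (``g0, g1, ...``
        and ``t0, t1, ...``) when omitted.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...] = None  # type: ignore[assignment]
    time_labels: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValidationError(
                f"expression matrix must be 2-D with M,N >= 1, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError(
                "expression matrix contains non-finite values (NaN/Inf); "
                "missing values are not supported"
            )
        object.__setattr__(self, "values", values.copy())
        object.__setattr__(
            self,
            "gene_ids",
            _normalize_labels(self.gene_ids, values.shape[0], "g", "gene"),
        )
        object.__setattr__(
            self,
            "time_labels",
            _normalize_labels(self.time_labels, values.shape[1], "t", "time"),
        )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same labels, new values (shape must match)."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape != self.values.shape:
            raise ValidationError(
                f"replacement values have shape {values.shape}, expected {self.values.shape}"
            )
        return ExpressionMatrix(values, self.gene_ids, self.time_labels)

    def select_rows(self, indices: Sequence[int]) -> "ExpressionMatrix":
        """Sub-matrix restricted to the given gene rows (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[idx],
            tuple(self.gene_ids[i] for i in idx),
            self.time_labels,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.time_labels == other.time_labels
            and np.array_equal(self.values, other.values)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.time_labels)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            df.to_numpy(dtype=np.float64),
            tuple(str(i) for i in df.index),
            tuple(str(c) for c in df.columns),
        )


def _resolve_delimiter(delimiter: str) -> str:
    if delimiter in DELIMITERS:
        return DELIMITERS[delimiter]
    if delimiter in DELIMITERS.values():
        return delimiter
    raise ValidationError(f"unknown delimiter {delimiter!r}; use 'tab' or 'comma'")


def read_expression_matrix(path: str | Path, delimiter: str = "tab") -> ExpressionMatrix:
    """Read a gene-by-timepoint table (first column = gene id, header = times)."""
    sep = _resolve_delimiter(delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric expression values in {path}: {exc}") from exc
    return ExpressionMatrix(
        values, tuple(str(i) for i in df.index), tuple(str(c) for c in df.columns)
    )


def write_expression_matrix(
    x: ExpressionMatrix, path: str | Path, delimiter: str = "tab"
) -> None:
    """Write the matrix in the same dialect ``read_expression_matrix`` reads."""
    sep = _resolve_delimiter(delimiter)
    x.to_dataframe().to_csv(path, sep=sep, index_label="gene")
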