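"""Linear differential-equation model of gene regulation.

The model relates the expression derivative of each gene to the expression
of every gene through a signed weight matrix ``W`` and a basal (external
input) vector ``B``::

    dx_i/dt = sum_j w_ij * x_j(t) + b_i

Entry ``w_ij`` is the influence of gene *j* (regulator, column) on gene *i*
(target, row); positive weights are activation, negative are inhibition, and
the matrix is directed (``w_ij`` and ``w_ji`` are independent).  This module
holds the data containers, the finite-difference derivative estimator, the
model residual, and the least-squares "mass" function that the search
algorithms minimize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import InvalidInputError

__all__ = [
    "ExpressionMatrix",
    "DerivativeMatrix",
    "estimate_derivatives",
    "residual",
    "mass",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-expression time series: genes on rows, timepoints on columns.

    Parameters
    ----------
    values
        ``(N, T)`` array of expression levels (arbitrary nonnegative scale).
    gene_ids
        ``N`` gene labels; defaults to ``g0 .. g{N-1}``.
    times
        ``T`` strictly increasing sampling times; defaults to ``0 .. T-1``.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...] = field(default=())
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidInputError("expression values must be a 2-D matrix")
        n, t = values.shape
        if n < 2 or t < 3:
            raise InvalidInputError(
                f"need at least 2 genes and 3 timepoints, got {n}x{t}"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("expression values contain non-finite entries")
        gene_ids = tuple(self.gene_ids) or tuple(f"g{i}" for i in range(n))
        if len(gene_ids) != n:
            raise InvalidInputError(
                f"{len(gene_ids)} gene ids for {n} expression rows"
            )
        times = self.times
        times = np.arange(t, dtype=float) if times is None else np.asarray(times, dtype=float)
        if times.shape != (t,):
            raise InvalidInputError(f"expected {t} timepoints, got {times.shape}")
        if not np.all(np.diff(times) > 0):
            raise InvalidInputError("timepoints must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "times", times)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def aligned(self) -> np.ndarray:
        """The ``(N, T-1)`` block of columns paired with forward-difference
        derivatives (all timepoints except the last)."""
        return self.values[:, :-1]


@dataclass(frozen=True)
class DerivativeMatrix:
    """Estimated expression derivatives, one column per aligned timepoint."""

    values: np.ndarray
    aligned_columns: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        cols = np.asarray(self.aligned_columns, dtype=int)
        if values.ndim != 2 or cols.shape != (values.shape[1],):
            raise InvalidInputError("derivative columns and alignment disagree")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "aligned_columns", cols)


def estimate_derivatives(
    expr: ExpressionMatrix, scheme: str = "forward"
) -> DerivativeMatrix:
    """Estimate dx/dt by finite differences.

    The default ``forward`` scheme pairs derivative column *t* with
    expression column *t*::

        d_it = (x_{i,t+1} - x_{i,t}) / (times_{t+1} - times_t)

    for ``t = 0 .. T-2``.  For trajectories produced by a forward-Euler
    integrator this estimator is exact.  ``scheme="central"`` averages the
    forward and backward differences on interior columns (the first column
    falls back to the forward difference), still aligned with columns
    ``0 .. T-2``.
    """
    x = expr.values
    dt = np.diff(expr.times)
    fwd = np.diff(x, axis=1) / dt
    if scheme == "forward":
        d = fwd
    elif scheme == "central":
        d = fwd.copy()
        # interior column t: slope over [t-1, t+1]
        if d.shape[1] > 1:
            span = expr.times[2:] - expr.times[:-2]
            d[:, 1:] = (x[:, 2:] - x[:, :-2]) / span
    else:
        raise InvalidInputError(f"unknown derivative scheme {scheme!r}")
    return DerivativeMatrix(values=d, aligned_columns=np.arange(d.shape[1]))


def _check_shapes(
    W: np.ndarray, B: np.ndarray, expr: ExpressionMatrix, deriv: DerivativeMatrix
) -> tuple[np.ndarray, np.ndarray]:
    W = np.asarray(W, dtype=float)
    B = np.asarray(B, dtype=float).reshape(-1)
    n = expr.n_genes
    if W.shape != (n, n):
        raise InvalidInputError(f"weight matrix must be {n}x{n}, got {W.shape}")
    if B.shape != (n,):
        raise InvalidInputError(f"basal vector must have length {n}, got {B.shape}")
    if deriv.values.shape != (n, expr.n_times - 1):
        raise InvalidInputError(
            "derivative matrix not aligned with expression matrix"
        )
    return W, B


def residual(
    W: np.ndarray,
    B: np.ndarray,
    expr: ExpressionMatrix,
    deriv: DerivativeMatrix,
) -> np.ndarray:
    """Model residuals ``e_it = d_it - (sum_j w_ij x_jt + b_i)``.

    Uses only the aligned expression columns ``0 .. T-2``; an all-zero
    residual means ``(W, B)`` reproduce the estimated derivatives exactly.
    """
    W, B = _check_shapes(W, B, expr, deriv)
    x = expr.values[:, deriv.aligned_columns]
    return deriv.values - (W @ x + B[:, None])


def mass(
    W: np.ndarray,
    B: np.ndarray,
    expr: ExpressionMatrix,
    deriv: DerivativeMatrix,
    sparsity_lambda: float = 0.0,
) -> float:
    """Least-squares objective ("mass") of a candidate weight matrix.

    ``sum_it e_it**2 + sparsity_lambda * sum_ij |w_ij|``; lower is better.
    The default ``sparsity_lambda=0`` is the bare sum of squared residuals.
    The optional L1 term exists because the bare objective cannot separate
    members of an exact solution family (see :mod:`gravinet.svd_space`).
    """
    if sparsity_lambda < 0:
        raise InvalidInputError("sparsity_lambda must be nonnegative")
    e = residual(W, B, expr, deriv)
    value = float(np.sum(e * e))
    if sparsity_lambda:
        value += sparsity_lambda * float(np.abs(W).sum())
    return value
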