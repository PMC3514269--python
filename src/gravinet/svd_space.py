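"""SVD parameterization of the solution family of the linear model.

With ``X`` the aligned ``(N, T-1)`` expression block and ``Y = Xdot - B 1^T``
the derivative targets, every weight matrix satisfying the least-squares
normal equations of ``W X = Y`` can be written as an affine family

    W = W0 + C @ U0.T

where ``W0`` is the minimum-Frobenius-norm particular solution obtained from
the (truncated) pseudoinverse of ``X``, ``U0`` holds the left singular
vectors of ``X`` whose singular values fall at or below the rank tolerance
(the retained left null directions), and ``C`` is an ``(N, K)`` matrix of
free coefficients — each row of ``W`` carries its own null-space freedom.
When the data are fewer than the genes (``T-1 < N``) the family is
nontrivial (``K >= N - (T-1)``) and the bare least-squares mass is constant
across it: the family is exactly the set of candidate networks the data
cannot distinguish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import DegenerateDataError, InvalidInputError
from .model import DerivativeMatrix, ExpressionMatrix

__all__ = [
    "SVDFactors",
    "SolutionSpace",
    "decompose",
    "auto_rank_tol",
    "particular_solution",
    "build_space",
    "compose",
    "membership",
    "project",
]


@dataclass(frozen=True)
class SVDFactors:
    """Full SVD ``X = U diag(S) Vt`` of the aligned expression block.

    ``U`` is ``(N, N)`` (full, so the left null space is explicit when
    ``N > T-1``), ``S`` the nonincreasing singular values, ``Vt`` the
    ``(T-1, T-1)`` right factor (transposed, numpy convention).
    """

    U: np.ndarray
    S: np.ndarray
    Vt: np.ndarray

    @property
    def V(self) -> np.ndarray:
        return self.Vt.T


@dataclass(frozen=True)
class SolutionSpace:
    """Affine family ``W = W0 + C @ null_basis.T`` of admissible networks."""

    W0: np.ndarray
    null_basis: np.ndarray  # (N, K), orthonormal columns
    rank_tol: float

    @property
    def n_genes(self) -> int:
        return self.W0.shape[0]

    @property
    def K(self) -> int:
        return self.null_basis.shape[1]


def decompose(expr: ExpressionMatrix) -> SVDFactors:
    """Full SVD of the aligned ``(N, T-1)`` expression block."""
    x = expr.aligned()
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("expression block contains non-finite entries")
    u, s, vt = np.linalg.svd(x, full_matrices=True)
    return SVDFactors(U=u, S=s, Vt=vt)


def _retained_rank(s: np.ndarray, rank_tol: float) -> int:
    if s.size == 0 or s[0] <= 0:
        return 0
    return int(np.sum(s > rank_tol * s[0]))


def auto_rank_tol(S: np.ndarray, shape: tuple[int, int]) -> float:
    """Noise-adaptive relative rank tolerance for the singular spectrum.

    For an ``n x m`` matrix contaminated by additive white noise of level
    ``sigma``, the noise part of the spectrum occupies the Marchenko-Pastur
    bulk ``[sigma*(sqrt(n)-sqrt(m)), sigma*(sqrt(n)+sqrt(m))]``.  The
    smallest observed singular value sits at the bulk's lower edge, which
    gives the noise estimate ``sigma_hat = S_min / (sqrt(n)-sqrt(m))``; the
    cutoff is the bulk's upper edge ``sigma_hat*(sqrt(n)+sqrt(m))``.
    Directions below it are noise-dominated and are joined to the
    searchable null space rather than inverted.  On (near) noise-free data
    ``S_min`` collapses and essentially nothing is truncated.  The top
    direction is never truncated.
    """
    if S.size == 0 or S[0] <= 0:
        return 0.0
    n, m = shape
    positive = S[S > 0]
    edge_ratio = (np.sqrt(max(n, m)) + np.sqrt(min(n, m))) / max(
        np.sqrt(max(n, m)) - np.sqrt(min(n, m)), 0.5
    )
    cutoff = float(positive[-1]) * edge_ratio
    return min(cutoff, 0.99 * float(S[0])) / float(S[0])


def _resolve_rank_tol(rank_tol, svd: SVDFactors) -> float:
    if rank_tol == "auto":
        shape = (svd.U.shape[0], svd.Vt.shape[0])
        return auto_rank_tol(svd.S, shape)
    return float(rank_tol)


def particular_solution(
    svd: SVDFactors,
    deriv: DerivativeMatrix,
    B: np.ndarray,
    rank_tol: float | str = 1e-10,
) -> np.ndarray:
    """Minimum-norm least-squares solution ``W0`` of ``W X = Xdot - B 1^T``.

    ``W0 = (Xdot - B 1^T) V S+ U^T`` with ``S+`` inverting only singular
    values above ``rank_tol * max(S)``; ``rank_tol="auto"`` uses
    :func:`auto_rank_tol`.
    """
    B = np.asarray(B, dtype=float).reshape(-1)
    y = deriv.values - B[:, None]
    r = _retained_rank(svd.S, _resolve_rank_tol(rank_tol, svd))
    if r == 0:
        raise DegenerateDataError(
            "all singular values fall below the rank tolerance"
        )
    # pinv restricted to the retained spectrum: V_r diag(1/s_r) U_r^T
    v_r = svd.Vt[:r].T
    u_r = svd.U[:, :r]
    return (y @ v_r / svd.S[:r]) @ u_r.T


def build_space(
    expr: ExpressionMatrix,
    deriv: DerivativeMatrix,
    B: np.ndarray,
    rank_tol: float | str = 1e-10,
    force_null_k: int = 0,
) -> SolutionSpace:
    """Construct the solution family from data.

    ``K = N - retained_rank``; ``force_null_k`` moves that many of the
    smallest *retained* singular directions into the null basis as well,
    which deliberately widens the family (used to create a nontrivial search
    space on full-rank data).  ``rank_tol="auto"`` picks the cutoff by the
    optimal hard threshold for noisy singular values, so noise-dominated
    directions are searched instead of inverted.
    """
    n = expr.n_genes
    if not 0 <= force_null_k < n:
        raise InvalidInputError("force_null_k must satisfy 0 <= k < n_genes")
    svd = decompose(expr)
    rank_tol = _resolve_rank_tol(rank_tol, svd)
    r = _retained_rank(svd.S, rank_tol)
    if r - force_null_k <= 0:
        raise InvalidInputError(
            f"force_null_k={force_null_k} leaves no retained direction (rank {r})"
        )
    r_eff = r - force_null_k
    # effective tolerance so W0 is truncated consistently with the basis
    eff_tol = rank_tol if force_null_k == 0 else (svd.S[r_eff - 1] * 0.999) / svd.S[0]
    w0 = particular_solution(svd, deriv, B, rank_tol=eff_tol)
    null_basis = svd.U[:, r_eff:]
    return SolutionSpace(W0=w0, null_basis=null_basis, rank_tol=eff_tol)


def compose(space: SolutionSpace, C: np.ndarray) -> np.ndarray:
    """Materialize the family member ``W0 + C @ null_basis.T``."""
    C = np.asarray(C, dtype=float)
    n, k = space.n_genes, space.K
    if k == 0:
        if C.size:
            raise InvalidInputError("family is a single point; C must be empty")
        return space.W0.copy()
    if C.shape != (n, k):
        raise InvalidInputError(f"coefficients must be {n}x{k}, got {C.shape}")
    return space.W0 + C @ space.null_basis.T


def membership(
    space: SolutionSpace, W: np.ndarray, eps: float = 1e-6
) -> np.ndarray | None:
    """Coefficients of ``W`` in the family, or ``None`` if it lies outside.

    ``C = (W - W0) @ null_basis``; ``W`` is accepted iff its residual off the
    null subspace is below ``eps`` relative to ``max(1, ||W - W0||_F)``.
    """
    W = np.asarray(W, dtype=float)
    delta = W - space.W0
    c_hat = delta @ space.null_basis
    off = delta - c_hat @ space.null_basis.T
    if np.linalg.norm(off) > eps * max(1.0, np.linalg.norm(delta)):
        return None
    return c_hat


def project(space: SolutionSpace, W: np.ndarray) -> np.ndarray:
    """Frobenius-nearest family member of an arbitrary ``W`` (idempotent)."""
    W = np.asarray(W, dtype=float)
    return compose(space, (W - space.W0) @ space.null_basis)
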