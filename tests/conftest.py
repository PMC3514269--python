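"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

import gravinet as gv
from gravinet.model import estimate_derivatives

# Published example time course (4 genes, 4 unit-spaced timepoints).
TABLE1_VALUES = np.array(
    [
        [0.329, 0.135, 0.358, 0.251],
        [0.934, 0.439, 0.314, 0.900],
        [0.911, 0.708, 0.627, 0.600],
        [0.501, 0.595, 0.530, 0.527],
    ]
)
TABLE1_GENES = ("Node0", "Node1", "Node2", "Node3")


@pytest.fixture
def table1_expr() -> gv.ExpressionMatrix:
    return gv.ExpressionMatrix(values=TABLE1_VALUES, gene_ids=TABLE1_GENES)


def simulate_dataset(seed: int = 0, **overrides):
    """One synthetic network + expression dataset, with parameter overrides."""
    import dataclasses

    params = dataclasses.replace(gv.SimParams(), seed=seed, **overrides)
    rng = np.random.default_rng(seed)
    graph = gv.generate_scale_free(params, rng)
    expr, basal, w_true = gv.generate_expression(graph, params, rng)
    return graph, expr, basal, w_true, params


@pytest.fixture
def small_dataset():
    """A 6-gene noiseless dataset with a square full-rank aligned block."""
    return simulate_dataset(seed=3, n_nodes=6, n_times=7, noise_amplitude=0.0)


def k1_system(seed: int):
    """A forced K=1 solution family with a per-row quadratic mass landscape.

    The aligned block is square and full rank (generic random data), so
    moving exactly one retained direction into the null basis leaves one
    free coefficient per row.
    """
    rng = np.random.default_rng(seed)
    expr = gv.ExpressionMatrix(values=rng.normal(size=(6, 7)))
    basal = rng.normal(size=6)
    deriv = estimate_derivatives(expr)
    space = gv.build_space(expr, deriv, basal, rank_tol=1e-10, force_null_k=1)
    assert space.K == 1
    return expr, deriv, basal, space


def grid_search_mass(space, expr, deriv, basal, lo=-8.0, hi=8.0, num=4001):
    """Dense 1-D grid-search oracle for K=1 families.

    The mass separates across rows (each row of W carries one coefficient),
    so the family optimum is the sum of per-row grid minima.
    """
    X = expr.aligned()
    Y = deriv.values - np.asarray(basal)[:, None]
    u = space.null_basis[:, 0]
    du = u @ X
    grid = np.linspace(lo, hi, num)
    total = 0.0
    for i in range(expr.n_genes):
        r0 = Y[i] - space.W0[i] @ X
        masses = ((r0[None, :] - grid[:, None] * du[None, :]) ** 2).sum(axis=1)
        total += masses.min()
    return total


def min_norm_lstsq_oracle(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pseudoinverse-free minimum-norm solution of ``W X = Y``.

    For an underdetermined full-row-rank system (X is N x M with M < N and
    rank M), each row w of W solves ``X^T w = y`` with minimum norm
    ``w = X (X^T X)^{-1} y`` — dual normal equations, solved directly.
    """
    G = X.T @ X
    return Y @ np.linalg.solve(G, X.T)
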