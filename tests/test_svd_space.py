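"""Tests of the SVD decomposition and the affine solution family."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gravinet as gv
from gravinet import DegenerateDataError, InvalidInputError
from gravinet.model import estimate_derivatives
from gravinet.svd_space import (
    build_space,
    compose,
    decompose,
    membership,
    particular_solution,
    project,
)

from conftest import min_norm_lstsq_oracle, simulate_dataset


def _random_problem(seed, n=5, t=7):
    rng = np.random.default_rng(seed)
    expr = gv.ExpressionMatrix(values=rng.normal(size=(n, t)))
    deriv = estimate_derivatives(expr)
    B = rng.normal(size=n)
    return expr, deriv, B


class TestDecompose:
    def test_diagonal_block_singular_values(self):
        expr = gv.ExpressionMatrix(values=np.array([[3.0, 0, 9], [0, 2.0, 9]]))
        sv = decompose(expr)  # aligned block is diag(3, 2)
        np.testing.assert_allclose(sv.S, [3.0, 2.0])

    def test_rank_one_block(self):
        u = np.array([0.6, 0.8])
        expr = gv.ExpressionMatrix(
            values=np.column_stack([5 * u, np.zeros(2), np.ones(2)])
        )
        sv = decompose(expr)
        np.testing.assert_allclose(sv.S, [5.0, 0.0], atol=1e-12)

    @settings(max_examples=20, database=None, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_reconstruction_and_orthogonality(self, seed):
        rng = np.random.default_rng(seed)
        expr = gv.ExpressionMatrix(values=rng.normal(size=(6, 5)))
        sv = decompose(expr)
        x = expr.aligned()
        smat = np.zeros((6, 4))
        np.fill_diagonal(smat, sv.S)
        np.testing.assert_allclose(sv.U @ smat @ sv.Vt, x, atol=1e-10)
        np.testing.assert_allclose(sv.U @ sv.U.T, np.eye(6), atol=1e-8)
        np.testing.assert_allclose(sv.V @ sv.Vt, np.eye(4), atol=1e-8)
        assert np.all(np.diff(sv.S) <= 0)


class TestParticularSolution:
    def test_square_full_rank_matches_direct_inverse(self):
        rng = np.random.default_rng(2)
        expr = gv.ExpressionMatrix(values=rng.normal(size=(4, 5)))
        deriv = estimate_derivatives(expr)
        B = rng.normal(size=4)
        w0 = particular_solution(decompose(expr), deriv, B)
        x = expr.aligned()
        direct = (deriv.values - B[:, None]) @ np.linalg.inv(x)
        np.testing.assert_allclose(w0, direct, atol=1e-8)

    def test_zero_target_gives_zero_solution(self):
        rng = np.random.default_rng(3)
        expr = gv.ExpressionMatrix(values=rng.normal(size=(4, 5)))
        deriv = gv.DerivativeMatrix(values=np.zeros((4, 4)), aligned_columns=range(4))
        w0 = particular_solution(decompose(expr), deriv, np.zeros(4))
        np.testing.assert_allclose(w0, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_underdetermined_matches_min_norm_oracle(self, seed):
        expr, deriv, B = _random_problem(seed, n=4, t=4)  # 4 genes, 3 columns
        w0 = particular_solution(decompose(expr), deriv, B)
        oracle = min_norm_lstsq_oracle(expr.aligned(), deriv.values - B[:, None])
        np.testing.assert_allclose(w0, oracle, atol=1e-8)

    def test_all_singular_values_below_tolerance(self):
        expr = gv.ExpressionMatrix(values=np.zeros((3, 4)))
        deriv = estimate_derivatives(expr)
        with pytest.raises(DegenerateDataError):
            particular_solution(decompose(expr), deriv, np.zeros(3), rank_tol=0.5)


class TestSolutionFamily:
    def test_underdetermined_system_has_nontrivial_family(self):
        expr, deriv, B = _random_problem(0, n=4, t=4)
        space = build_space(expr, deriv, B)
        assert space.K >= 1
        np.testing.assert_allclose(
            space.null_basis.T @ space.null_basis, np.eye(space.K), atol=1e-8
        )

    def test_full_rank_square_system_is_a_point(self):
        expr, deriv, B = _random_problem(1, n=4, t=5)
        space = build_space(expr, deriv, B)
        assert space.K == 0
        np.testing.assert_allclose(compose(space, np.zeros((4, 0))), space.W0)

    def test_force_null_k_bounds(self):
        expr, deriv, B = _random_problem(1, n=4, t=5)
        with pytest.raises(InvalidInputError):
            build_space(expr, deriv, B, force_null_k=4)

    def test_mass_constant_over_exact_null_family(self):
        """The objective cannot distinguish members of an exact family."""
        _, expr, basal, _, _ = simulate_dataset(
            seed=5, n_nodes=5, n_times=4, noise_amplitude=0.0
        )
        deriv = estimate_derivatives(expr)
        space = build_space(expr, deriv, basal, rank_tol=1e-12)
        assert space.K >= 1
        rng = np.random.default_rng(0)
        masses = [
            gv.mass(compose(space, rng.normal(size=(5, space.K))), basal, expr, deriv)
            for _ in range(100)
        ]
        assert np.ptp(masses) <= 1e-8

    def test_compose_membership_round_trip(self):
        expr, deriv, B = _random_problem(4, n=6, t=5)
        space = build_space(expr, deriv, B)
        rng = np.random.default_rng(0)
        C = rng.normal(size=(6, space.K))
        W = compose(space, C)
        C_hat = membership(space, W)
        assert C_hat is not None
        np.testing.assert_allclose(C_hat, C, atol=1e-8)
        np.testing.assert_allclose(membership(space, space.W0), 0.0, atol=1e-10)

    def test_membership_rejects_out_of_family_points(self):
        expr, deriv, B = _random_problem(4, n=6, t=5)
        space = build_space(expr, deriv, B)
        # perturbation orthogonal to the null basis, unit Frobenius norm
        q, _ = np.linalg.qr(
            np.eye(6) - space.null_basis @ space.null_basis.T
        )
        bad = space.W0 + np.outer(np.eye(6)[0], q[:, 0])
        assert membership(space, bad, eps=1e-6) is None

    def test_project_idempotent_and_nearest(self):
        expr, deriv, B = _random_problem(5, n=5, t=4)
        space = build_space(expr, deriv, B)
        rng = np.random.default_rng(1)
        W = rng.normal(size=(5, 5))
        P = project(space, W)
        np.testing.assert_allclose(project(space, P), P, atol=1e-10)
        in_family = compose(space, rng.normal(size=(5, space.K)))
        np.testing.assert_allclose(project(space, in_family), in_family, atol=1e-10)

    def test_project_matches_grid_search_on_k1_toy(self):
        expr, deriv, B = _random_problem(6, n=3, t=3)  # 3 genes, 2 columns
        space = build_space(expr, deriv, B)
        assert space.K == 1
        rng = np.random.default_rng(2)
        W = rng.normal(size=(3, 3))
        proj = project(space, W)
        # 1-D grid over each row's coefficient: nearest member in Frobenius norm
        grid = np.linspace(-10, 10, 20001)
        u = space.null_basis[:, 0]
        best_c = []
        for i in range(3):
            dists = ((W[i] - space.W0[i])[None, :] - grid[:, None] * u[None, :]) ** 2
            best_c.append(grid[np.argmin(dists.sum(axis=1))])
        grid_proj = compose(space, np.array(best_c)[:, None])
        np.testing.assert_allclose(proj, grid_proj, atol=2e-3)

    def test_min_norm_property_of_particular_solution(self):
        expr, deriv, B = _random_problem(7, n=5, t=4)
        space = build_space(expr, deriv, B)
        rng = np.random.default_rng(3)
        for _ in range(20):
            W = compose(space, rng.normal(size=(5, space.K)))
            assert np.linalg.norm(space.W0) <= np.linalg.norm(W) + 1e-10


class TestAutoRankTol:
    def test_noisy_bulk_is_truncated(self):
        rng = np.random.default_rng(0)
        signal = np.outer(rng.normal(size=20), rng.normal(size=15)) * 2
        noisy = signal + rng.uniform(-0.05, 0.05, size=(20, 15))
        expr = gv.ExpressionMatrix(values=noisy)
        deriv = estimate_derivatives(expr)
        space = build_space(expr, deriv, np.zeros(20), rank_tol="auto")
        # rank-1 signal: nearly all directions are noise and join the family
        assert space.K >= 12

    def test_noise_free_rank_deficient_data_keeps_numerical_rank(self):
        rng = np.random.default_rng(8)
        low_rank = rng.normal(size=(6, 2)) @ rng.normal(size=(2, 5))
        expr = gv.ExpressionMatrix(values=low_rank)
        deriv = estimate_derivatives(expr)
        numeric = build_space(expr, deriv, np.zeros(6), rank_tol=1e-10)
        auto = build_space(expr, deriv, np.zeros(6), rank_tol="auto")
        assert numeric.K == 4
        # auto may additionally drop numerically-null directions, never signal
        assert 4 <= auto.K <= 5
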