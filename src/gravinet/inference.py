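"""Model/Results interface tying the pipeline together.

``GRNModel`` wraps an expression time series (plus optional basal vector),
builds the SVD solution family lazily, and ``fit`` runs one of the search
methods — ``gfa`` (gravitation-field), ``ga``, ``sa``, or ``dem`` (the
no-search particular solution) — returning a ``GRNResults`` with the
estimated weight matrix, the objective value, the search trace, and
reporting helpers.

Example
-------
>>> from gravinet import GRNModel, SimParams, generate_scale_free, generate_expression
>>> import numpy as np
>>> rng = np.random.default_rng(0)
>>> params = SimParams(seed=0)
>>> graph = generate_scale_free(params, rng)
>>> expr, basal, w_true = generate_expression(graph, params, rng)
>>> res = GRNModel(expr, basal=basal).fit(method="gfa", seed=0)
>>> net = res.network(tau=0.5)
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
import pandas as pd

from ._exceptions import InvalidInputError
from . import baselines, gfa as gfa_mod
from .evaluation import Metrics, confusion, ppv_se, threshold_network
from .io import write_network_sif, write_weights_tsv
from .model import DerivativeMatrix, ExpressionMatrix, estimate_derivatives, mass
from .svd_space import SolutionSpace, build_space

logger = logging.getLogger(__name__)

__all__ = ["GRNModel", "GRNResults"]


class GRNModel:
    """Linear-ODE gene-regulatory-network model bound to a dataset.

    Parameters
    ----------
    expr
        Expression time series (genes on rows).
    basal
        Known basal expression-change vector ``B``; defaults to zeros.  The
        model never estimates it from data.
    rank_tol
        Relative singular-value cutoff separating retained from null
        directions of the aligned expression block.
    force_null_k
        Move this many of the smallest retained directions into the null
        basis (widens the search family on full-rank data).
    derivative_scheme
        ``"forward"`` (default) or ``"central"`` finite differences.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        basal: np.ndarray | None = None,
        rank_tol: float = 1e-10,
        force_null_k: int = 0,
        derivative_scheme: str = "forward",
    ) -> None:
        self.expr = expr
        self.basal = (
            np.zeros(expr.n_genes)
            if basal is None
            else np.asarray(basal, dtype=float).reshape(-1)
        )
        if self.basal.shape != (expr.n_genes,):
            raise InvalidInputError("basal vector length must match gene count")
        self.rank_tol = rank_tol
        self.force_null_k = force_null_k
        self.deriv: DerivativeMatrix = estimate_derivatives(expr, derivative_scheme)
        self._space: SolutionSpace | None = None

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, times: np.ndarray | None = None, **kwargs
    ) -> "GRNModel":
        """Build from a genes-by-timepoints DataFrame (index = gene ids).

        ``times`` defaults to the numeric column labels when they parse,
        else to ``0, 1, 2, ...``.
        """
        if times is None:
            try:
                times = np.asarray([float(c) for c in df.columns])
            except (TypeError, ValueError):
                times = None
        expr = ExpressionMatrix(
            values=df.to_numpy(dtype=float),
            gene_ids=tuple(str(i) for i in df.index),
            times=times,
        )
        return cls(expr, **kwargs)

    @property
    def space(self) -> SolutionSpace:
        """The SVD solution family (built on first access)."""
        if self._space is None:
            self._space = build_space(
                self.expr,
                self.deriv,
                self.basal,
                rank_tol=self.rank_tol,
                force_null_k=self.force_null_k,
            )
        return self._space

    def fit(
        self,
        method: str = "gfa",
        sparsity_lambda: float = 0.0,
        params=None,
        seed: int | None = None,
    ) -> "GRNResults":
        """Estimate the weight matrix with the requested search method.

        When the family is a single point (K = 0) there is nothing to
        search and every method short-circuits to the particular solution.
        """
        space = self.space
        history: list[float] | None = None
        if method == "dem" or space.K == 0:
            if method != "dem" and space.K == 0:
                logger.info(
                    "solution family is a point (K=0); %s short-circuits to "
                    "the particular solution", method,
                )
            W = baselines.traditional_dem(space)
        elif method == "gfa":
            p = params or gfa_mod.GFAParams()
            if seed is not None:
                p = dataclasses.replace(p, seed=seed)
            result = gfa_mod.run(
                space, self.expr, self.deriv, self.basal, p, sparsity_lambda
            )
            W, history = result.best.W, result.history
        elif method == "ga":
            p = params or baselines.GAParams()
            if seed is not None:
                p = dataclasses.replace(p, seed=seed)
            W = baselines.ga_run(
                space, self.expr, self.deriv, self.basal, p, sparsity_lambda
            ).W
        elif method == "sa":
            p = params or baselines.SAParams()
            if seed is not None:
                p = dataclasses.replace(p, seed=seed)
            W = baselines.sa_run(
                space, self.expr, self.deriv, self.basal, p, sparsity_lambda
            ).W
        else:
            raise InvalidInputError(
                f"unknown method {method!r}; choose from gfa, ga, sa, dem"
            )
        mass_value = mass(
            W, self.basal, self.expr, self.deriv, sparsity_lambda=sparsity_lambda
        )
        return GRNResults(
            model=self, method=method, weights=W, mass_value=mass_value,
            sparsity_lambda=sparsity_lambda, history=history,
        )


class GRNResults:
    """Fitted network: estimated weights plus diagnostics and reporting."""

    def __init__(
        self,
        model: GRNModel,
        method: str,
        weights: np.ndarray,
        mass_value: float,
        sparsity_lambda: float = 0.0,
        history: list[float] | None = None,
    ) -> None:
        self.model = model
        self.method = method
        self.weights = weights
        self.mass_value = mass_value
        self.sparsity_lambda = sparsity_lambda
        self.history = history

    def network(self, tau: float = 0.5) -> nx.DiGraph:
        """Thresholded directed signed graph of the estimate."""
        return threshold_network(self.weights, tau, self.model.expr.gene_ids)

    def evaluate(
        self, truth: nx.DiGraph, tau: float = 0.5, sign_aware: bool = False
    ) -> Metrics:
        """PPV and Se of the thresholded estimate against a truth graph."""
        return ppv_se(confusion(self.network(tau), truth, sign_aware=sign_aware))

    def to_sif(self, path, tau: float = 0.5) -> None:
        write_network_sif(self.network(tau), path)

    def to_weights_tsv(self, path) -> None:
        write_weights_tsv(self.weights, self.model.expr.gene_ids, path)

    def summary(self, tau: float = 0.5, max_edges: int = 20) -> str:
        """Plain-text report: fit header plus the strongest edges."""
        expr = self.model.expr
        net = self.network(tau)
        lines = [
            "Gene regulatory network inference results",
            "=" * 45,
            f"method:            {self.method}",
            f"genes (N):         {expr.n_genes}",
            f"timepoints (T):    {expr.n_times}",
            f"null dimension K:  {self.model.space.K}",
            f"mass (objective):  {self.mass_value:.6g}",
            f"sparsity lambda:   {self.sparsity_lambda:g}",
            f"threshold tau:     {tau:g}",
            f"edges >= tau:      {net.number_of_edges()}",
            "",
            f"{'regulator':<12}{'target':<12}{'weight':>10}  effect",
            "-" * 45,
        ]
        edges = sorted(
            net.edges(data=True), key=lambda e: -abs(e[2]["weight"])
        )[:max_edges]
        for u, v, data in edges:
            effect = "activation" if data["sign"] > 0 else "inhibition"
            lines.append(f"{u!s:<12}{v!s:<12}{data['weight']:>10.3f}  {effect}")
        if net.number_of_edges() > max_edges:
            lines.append(f"... ({net.number_of_edges() - max_edges} more edges)")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GRNResults method={self.method!r} N={self.model.expr.n_genes} "
            f"mass={self.mass_value:.4g}>"
        )
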