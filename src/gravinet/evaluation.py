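"""Edge-level evaluation of inferred networks and the replicate benchmark.

A weight matrix is turned into a directed signed graph by threshold
interception (an edge exists iff ``|w_ij| >= tau``; 0.5 by default), and
compared with the ground truth over all ordered gene pairs, self-pairs
included.  Precision (PPV = TP/(TP+FP)) and sensitivity (Se = TP/(TP+FN))
summarize the comparison; 0/0 is reported as missing, never as zero.

``benchmark`` re-simulates a fresh network and dataset per run, infers it
with every requested method on identical data, and averages the metrics —
the protocol behind method-comparison tables for this class of algorithms.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._exceptions import InvalidInputError
from . import baselines, gfa as gfa_mod
from .model import estimate_derivatives
from .simulator import SimParams, generate_expression, generate_scale_free
from .svd_space import build_space

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "threshold_network",
    "confusion",
    "ppv_se",
    "benchmark",
    "METHODS",
]

METHODS = ("gfa", "ga", "sa", "dem")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise InvalidInputError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class Metrics:
    """PPV and sensitivity; ``None`` marks an undefined (0/0) value."""

    ppv: float | None
    se: float | None


def threshold_network(
    W: np.ndarray, tau: float = 0.5, gene_ids: tuple[str, ...] | None = None
) -> nx.DiGraph:
    """Directed signed graph of all entries with ``|w_ij| >= tau``.

    Edge ``j -> i`` (regulator to target) carries the weight and its sign;
    self-loops are kept.  The boundary is inclusive: ``|w| == tau`` is an
    edge.
    """
    if tau <= 0:
        raise InvalidInputError("threshold tau must be positive")
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise InvalidInputError("weight matrix must be square")
    labels = gene_ids if gene_ids is not None else tuple(range(n))
    if len(labels) != n:
        raise InvalidInputError("gene_ids length must match matrix size")
    g: nx.DiGraph = nx.DiGraph()
    g.add_nodes_from(labels)
    for i in range(n):
        for j in range(n):
            if abs(W[i, j]) >= tau:
                g.add_edge(
                    labels[j],
                    labels[i],
                    weight=float(W[i, j]),
                    sign=1 if W[i, j] > 0 else -1,
                )
    return g


def _edge_signs(g: nx.DiGraph) -> dict[tuple, int]:
    out = {}
    for u, v, data in g.edges(data=True):
        sign = data.get("sign")
        if sign is None:
            w = data.get("weight", 1.0)
            sign = 1 if w >= 0 else -1
        out[(u, v)] = int(sign)
    return out


def confusion(
    predicted: nx.DiGraph, truth: nx.DiGraph, sign_aware: bool = False
) -> ConfusionCounts:
    """Count TP/FP/FN over all ordered node pairs (self-pairs included).

    With ``sign_aware=True`` a predicted edge of the wrong sign counts as a
    false positive and leaves the true edge unrecovered (a false negative).
    """
    if set(predicted.nodes) != set(truth.nodes):
        raise InvalidInputError("predicted and truth graphs differ in node set")
    pred = _edge_signs(predicted)
    true = _edge_signs(truth)
    tp = fp = fn = 0
    for pair, sign in pred.items():
        if pair in true and (not sign_aware or sign == true[pair]):
            tp += 1
        else:
            fp += 1
    for pair, sign in true.items():
        if pair not in pred or (sign_aware and pred[pair] != sign):
            fn += 1
    return ConfusionCounts(TP=tp, FP=fp, FN=fn)


def ppv_se(counts: ConfusionCounts) -> Metrics:
    """Precision and sensitivity; a zero denominator yields ``None``."""
    ppv = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else None
    se = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else None
    return Metrics(ppv=ppv, se=se)


def _infer_one(
    method: str,
    space,
    expr,
    deriv,
    B,
    seed: int,
    sparsity_lambda: float,
    gfa_params: gfa_mod.GFAParams | None,
    ga_params: baselines.GAParams | None,
    sa_params: baselines.SAParams | None,
) -> np.ndarray:
    if method == "dem" or space.K == 0:
        # a point family leaves nothing to search: every method returns W0
        return baselines.traditional_dem(space)
    if method == "gfa":
        params = dataclasses.replace(gfa_params or gfa_mod.GFAParams(), seed=seed)
        return gfa_mod.run(space, expr, deriv, B, params, sparsity_lambda).best.W
    if method == "ga":
        params = dataclasses.replace(ga_params or baselines.GAParams(), seed=seed)
        return baselines.ga_run(space, expr, deriv, B, params, sparsity_lambda).W
    if method == "sa":
        params = dataclasses.replace(sa_params or baselines.SAParams(), seed=seed)
        return baselines.sa_run(space, expr, deriv, B, params, sparsity_lambda).W
    raise InvalidInputError(f"unknown method {method!r}; choose from {METHODS}")


def benchmark(
    methods: list[str],
    sim_params: SimParams | None = None,
    n_runs: int = 50,
    base_seed: int = 0,
    tau: float = 0.5,
    sparsity_lambda: float = 0.01,
    rank_tol: float | str = 1e-10,
    force_null_k: int = 0,
    sign_aware: bool = False,
    gfa_params: gfa_mod.GFAParams | None = None,
    ga_params: baselines.GAParams | None = None,
    sa_params: baselines.SAParams | None = None,
) -> pd.DataFrame:
    """Replicate benchmark: simulate, infer with every method, score.

    Run *r* simulates one network and dataset with seed ``base_seed + r``,
    gives the identical data to every method, thresholds at ``tau`` and
    scores against the generating matrix thresholded the same way.  Returns
    one row per method with mean and standard deviation of PPV and Se and
    the accumulated wall time.  ``sparsity_lambda`` (default 0.01) is the L1
    pressure handed to the search methods; the bare least-squares mass is
    constant across an exact solution family, so a sparsity term is what
    gives the search a direction (the DEM baseline never uses it).
    ``rank_tol`` accepts ``"auto"`` (noise-adaptive hard threshold) besides
    the default numerical tolerance; auto truncation shrinks the estimates
    toward a sparse high-precision regime, the numerical tolerance keeps
    every data direction and yields denser, higher-recall networks.
    """
    if n_runs < 1:
        raise InvalidInputError("n_runs must be >= 1")
    for m in methods:
        if m not in METHODS:
            raise InvalidInputError(f"unknown method {m!r}; choose from {METHODS}")
    sim_params = sim_params or SimParams()
    scores: dict[str, dict[str, list[float]]] = {
        m: {"ppv": [], "se": []} for m in methods
    }
    runtimes = {m: 0.0 for m in methods}
    for r in range(n_runs):
        run_seed = base_seed + r
        rng = np.random.default_rng(run_seed)
        graph = generate_scale_free(sim_params, rng)
        expr, B, W_true = generate_expression(graph, sim_params, rng)
        truth = threshold_network(W_true, tau, expr.gene_ids)
        deriv = estimate_derivatives(expr)
        space = build_space(expr, deriv, B, rank_tol=rank_tol, force_null_k=force_null_k)
        for m in methods:
            t0 = time.perf_counter()
            W_hat = _infer_one(
                m, space, expr, deriv, B, run_seed, sparsity_lambda,
                gfa_params, ga_params, sa_params,
            )
            runtimes[m] += time.perf_counter() - t0
            metrics = ppv_se(
                confusion(threshold_network(W_hat, tau, expr.gene_ids), truth, sign_aware)
            )
            scores[m]["ppv"].append(np.nan if metrics.ppv is None else metrics.ppv)
            scores[m]["se"].append(np.nan if metrics.se is None else metrics.se)
    rows = []
    for m in methods:
        ppv = np.asarray(scores[m]["ppv"])
        se = np.asarray(scores[m]["se"])
        rows.append(
            {
                "method": m,
                "ppv_mean": float(np.nanmean(ppv)) if not np.all(np.isnan(ppv)) else np.nan,
                "ppv_sd": float(np.nanstd(ppv, ddof=1)) if np.sum(~np.isnan(ppv)) > 1 else np.nan,
                "se_mean": float(np.nanmean(se)) if not np.all(np.isnan(se)) else np.nan,
                "se_sd": float(np.nanstd(se, ddof=1)) if np.sum(~np.isnan(se)) > 1 else np.nan,
                "runtime_s": runtimes[m],
            }
        )
    return pd.DataFrame(rows)
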