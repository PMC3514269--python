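"""Synthetic benchmark generator: scale-free regulatory networks and
expression time series from the linear ODE.

The network grows from a small seed of regulators; each new node receives
``m`` incoming edges whose regulator is drawn by preferential attachment on
out-degree, and each such edge is then, with probability ``p_reconnect``,
re-drawn from the same power-law attachment weights (the "reconnection"
step).  Out-degree therefore concentrates on a few hub regulators while
most nodes regulate little — the control-node-limited, power-law topology
of real transcriptional networks.  A subset of nodes carries an inhibitory
self-loop (degradation-type autoregulation).

Expression is produced by forward-Euler integration of ``dx/dt = W x + B``
where ``W`` combines the signed edge weights with a gene-specific
first-order decay on the diagonal (rates drawn uniformly, mimicking
heterogeneous mRNA half-lives); a uniform random perturbation on
``[-eta, +eta]`` is added to every recorded value.  Because the growth graph is acyclic and
self-loops are inhibitory, the spectrum of the interaction matrix is its
(nonpositive) diagonal, and the decay terms alone guarantee stable, bounded
trajectories; a rescaling fallback handles user configurations that break
this property.

What the generator does *not* emulate: nonlinear (saturating) kinetics,
feedback cycles between distinct genes, and multiplicative measurement
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._exceptions import InvalidInputError, SimulationError
from .model import ExpressionMatrix

__all__ = [
    "SimParams",
    "generate_scale_free",
    "generate_expression",
    "weight_matrix_from_graph",
    "integrate_euler",
    "export_truth",
]


@dataclass(frozen=True)
class SimParams:
    """Settings of the synthetic benchmark.

    Defaults give a 20-node network observed at 15 timepoints — fewer
    samples than genes, so the inference problem is genuinely
    underdetermined — with edge magnitudes in ``[0.6, 1.5]`` (above the 0.5
    detection threshold), uniform perturbation noise of amplitude 0.05, and
    first-order decay rates in [0.15, 0.45] per time unit (below the
    threshold, so a bare decay diagonal is not itself counted as an edge;
    distinct rates keep the trajectory modes linearly independent).
    """

    n_nodes: int = 20
    seed_nodes: int = 3  # m0
    edges_per_new_node: int = 1  # m
    p_reconnect: float = 0.2
    p_self_loop: float = 0.15
    weight_magnitude_range: tuple[float, float] = (0.6, 1.5)
    p_negative_sign: float = 0.5
    basal_range: tuple[float, float] = (-0.3, 0.3)
    n_times: int = 15  # T
    dt: float = 1.0  # unit sampling interval, matching published time courses
    x0_range: tuple[float, float] = (0.0, 1.0)
    noise_amplitude: float = 0.05  # eta
    decay_range: tuple[float, float] = (0.15, 0.45)
    stabilization_margin: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_nodes > self.seed_nodes >= 2:
            raise InvalidInputError("need n_nodes > seed_nodes >= 2")
        if self.n_times < 3:
            raise InvalidInputError("need at least 3 timepoints")
        if self.noise_amplitude < 0 or self.dt <= 0:
            raise InvalidInputError("noise amplitude must be >= 0 and dt > 0")
        if self.edges_per_new_node < 1:
            raise InvalidInputError("each new node needs >= 1 incoming edge")
        lo, hi = self.weight_magnitude_range
        if not 0 < lo <= hi:
            raise InvalidInputError("weight magnitudes must be positive")


def _draw_weight(params: SimParams, rng: np.random.Generator) -> float:
    lo, hi = params.weight_magnitude_range
    magnitude = rng.uniform(lo, hi)
    sign = -1.0 if rng.random() < params.p_negative_sign else 1.0
    return sign * magnitude


def _preferential_regulator(
    graph: nx.DiGraph, candidates: list[int], rng: np.random.Generator
) -> int:
    # attachment weight: out-degree + 0.25; the small offset keeps new
    # regulators reachable while concentrating control on a few hubs
    weights = np.array(
        [graph.out_degree(j) + 0.25 for j in candidates], dtype=float
    )
    return int(rng.choice(candidates, p=weights / weights.sum()))


def generate_scale_free(params: SimParams, rng: np.random.Generator) -> nx.DiGraph:
    """Grow a directed, signed, scale-free regulatory network.

    Edge ``j -> i`` means gene *j* regulates gene *i*; weights are stored on
    the ``weight`` edge attribute, signs on ``sign``.  Growth edges always
    run from older to newer nodes, so the graph is acyclic apart from
    self-loops.
    """
    g: nx.DiGraph = nx.DiGraph()
    g.add_nodes_from(range(params.n_nodes))
    m0 = params.seed_nodes
    # seed regulators: feed-forward clique (every older seed regulates newer)
    for j in range(m0):
        for i in range(j + 1, m0):
            g.add_edge(j, i, weight=_draw_weight(params, rng))
    for v in range(m0, params.n_nodes):
        candidates = list(range(v))
        regulators: set[int] = set()
        for _ in range(min(params.edges_per_new_node, v)):
            j = _preferential_regulator(g, candidates, rng)
            if rng.random() < params.p_reconnect:  # reconnection: re-draw
                j = _preferential_regulator(g, candidates, rng)
            if j in regulators:
                free = [c for c in candidates if c not in regulators]
                if not free:
                    break
                j = _preferential_regulator(g, free, rng)
            regulators.add(j)
            g.add_edge(j, v, weight=_draw_weight(params, rng))
    lo, hi = params.weight_magnitude_range
    for v in range(params.n_nodes):
        if rng.random() < params.p_self_loop:
            # inhibitory autoregulation keeps the linear system stable
            g.add_edge(v, v, weight=-rng.uniform(lo, hi))
    for _, _, data in g.edges(data=True):
        data["sign"] = 1 if data["weight"] > 0 else -1
    return g


def weight_matrix_from_graph(graph: nx.DiGraph, n_nodes: int | None = None) -> np.ndarray:
    """Dense weight matrix with the row=target, column=regulator convention."""
    n = n_nodes if n_nodes is not None else graph.number_of_nodes()
    W = np.zeros((n, n))
    for j, i, data in graph.edges(data=True):
        W[i, j] = data["weight"]
    return W


def integrate_euler(
    W: np.ndarray, B: np.ndarray, x0: np.ndarray, dt: float, n_steps: int
) -> np.ndarray:
    """Forward-Euler trajectory of ``dx/dt = W x + B``: ``(N, n_steps)``
    array whose first column is ``x0``."""
    x = np.asarray(x0, dtype=float).copy()
    out = np.empty((x.size, n_steps))
    for t in range(n_steps):
        out[:, t] = x
        x = x + dt * (W @ x + np.asarray(B))
    return out


def _stabilize(A: np.ndarray, decay: np.ndarray, margin: float) -> np.ndarray:
    """Return the effective system matrix ``s*A - diag(decay)`` with the
    largest eigenvalue real part at most ``-margin``."""
    decay_diag = np.diag(decay)
    scale = 1.0
    for _ in range(60):
        W = scale * A - decay_diag
        if np.max(np.linalg.eigvals(W).real) <= -margin:
            return W
        scale *= 0.8
    raise SimulationError("could not stabilize the synthetic ODE system")


def generate_expression(
    graph: nx.DiGraph, params: SimParams, rng: np.random.Generator
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Synthesize a noisy expression time series from a network.

    Returns ``(expression, basal, W_true)`` where ``W_true`` is the
    post-stabilization matrix that actually generated the trajectories (the
    ground truth against which inferred networks are scored).
    """
    n = graph.number_of_nodes()
    A = weight_matrix_from_graph(graph, n)
    decay = rng.uniform(*params.decay_range, size=n)
    W_true = _stabilize(A, decay, params.stabilization_margin)
    B = rng.uniform(*params.basal_range, size=n)
    x0 = rng.uniform(*params.x0_range, size=n)
    clean = integrate_euler(W_true, B, x0, params.dt, params.n_times)
    noisy = clean + rng.uniform(
        -params.noise_amplitude, params.noise_amplitude, size=clean.shape
    )
    expr = ExpressionMatrix(
        values=noisy,
        gene_ids=tuple(f"Node{i}" for i in range(n)),
        times=np.arange(params.n_times) * params.dt,
    )
    return expr, B, W_true


def export_truth(graph: nx.DiGraph) -> list[tuple[int, int, float, int]]:
    """Deterministic, sorted ``(regulator, target, weight, sign)`` records."""
    return sorted(
        (j, i, float(d["weight"]), int(d.get("sign", 1 if d["weight"] > 0 else -1)))
        for j, i, d in graph.edges(data=True)
    )
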