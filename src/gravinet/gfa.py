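"""Gravitation-field search over the SVD solution family.

Candidate networks are "dusts": points of the affine family, carried as
coefficient matrices ``C`` with the materialized weight matrix and a scalar
"mass" (the least-squares objective; lower is better).  Each epoch the
population is split into random groups, the minimum-mass dust of each group
becomes the group's centre, and every surrounding dust steps toward its
centre in coefficient space.  A step whose materialized weights leave the
``[-w_max, w_max]`` box has its pace halved and is retried; a dust that
cannot move legally after ``max_pace_halvings`` attempts is absorbed
(deleted).  A mover that beats its centre takes over the centre role and the
group's movement pass restarts.

Moving in coefficient space keeps every dust inside the solution family by
construction; the box is enforced on the materialized weight matrix, which
is the domain constraint of the original algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._exceptions import DegenerateSpaceError, InvalidInputError
from .model import DerivativeMatrix, ExpressionMatrix, mass
from .svd_space import SolutionSpace, compose

__all__ = [
    "Dust",
    "GFAParams",
    "GFAResult",
    "make_mass_fn",
    "initialize_dusts",
    "divide",
    "select_centre",
    "move_dust",
    "run",
]

MassFn = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class Dust:
    """One candidate solution: coefficients, materialized weights, mass."""

    C: np.ndarray
    W: np.ndarray
    mass_value: float


@dataclass(frozen=True)
class GFAParams:
    """Tunables of the gravitation-field search.

    ``init="prior"`` (default) seeds half the population at sparsified
    particular solutions — entries below a per-dust random cutoff in
    ``(0, init_prior_cutoff]`` zeroed, then projected back into the family —
    and the other half at random perturbations of the particular solution;
    this encodes the prior that regulatory networks are sparse.
    ``init="anchored"`` uses random perturbations only (coefficients
    uniform on ``[-init_coeff_scale, +init_coeff_scale]``).
    ``init="box"`` samples a dense weight matrix uniform on the
    ``[-w_max, w_max]`` box and projects it onto the family (a
    data-blind initialization kept for reference).
    """

    n_dusts: int = 60
    n_groups: int = 6
    pace: float = 0.5
    max_pace_halvings: int = 3
    w_max: float = 100.0
    max_epochs: int = 50
    stagnation_epochs: int = 10
    seed: int = 0
    init: str = "prior"
    init_coeff_scale: float = 1.0
    init_prior_cutoff: float = 0.5
    max_group_restarts: int = 10

    def __post_init__(self) -> None:
        if self.n_dusts < 1 or self.n_groups < 1 or self.n_groups > self.n_dusts:
            raise InvalidInputError("need 1 <= n_groups <= n_dusts")
        if not 0 < self.pace <= 1:
            raise InvalidInputError("pace must lie in (0, 1]")
        if self.w_max <= 0 or self.max_pace_halvings < 1:
            raise InvalidInputError("w_max and max_pace_halvings must be positive")
        if self.init not in ("prior", "anchored", "box"):
            raise InvalidInputError(f"unknown init mode {self.init!r}")


@dataclass
class GFAResult:
    """Outcome of a search run."""

    best: Dust
    history: list[float] = field(default_factory=list)
    n_absorbed: int = 0
    epochs_run: int = 0


def make_mass_fn(
    expr: ExpressionMatrix,
    deriv: DerivativeMatrix,
    B: np.ndarray,
    sparsity_lambda: float = 0.0,
) -> MassFn:
    """Bind the data into a ``W -> mass`` objective shared by all searchers."""
    return lambda W: mass(W, B, expr, deriv, sparsity_lambda=sparsity_lambda)


def _in_box(W: np.ndarray, w_max: float) -> bool:
    return bool(np.all(np.abs(W) <= w_max))


def initialize_dusts(
    space: SolutionSpace,
    mass_fn: MassFn,
    params: GFAParams,
    rng: np.random.Generator,
) -> list[Dust]:
    """Draw the initial population inside the family and the domain box."""
    if space.K == 0:
        raise DegenerateSpaceError("solution family is a single point (K=0)")
    n, k = space.n_genes, space.K
    dusts: list[Dust] = []
    while len(dusts) < params.n_dusts:
        c = None
        for _ in range(1000):
            if params.init == "prior" and len(dusts) % 2 == 0:
                # sparsified particular solution: zero the weak entries,
                # then take the nearest family member
                cutoff = rng.uniform(0.0, params.init_prior_cutoff)
                w_sparse = np.where(np.abs(space.W0) >= cutoff, space.W0, 0.0)
                jitter = rng.uniform(-0.05, 0.05, (n, k))
                cand = (w_sparse - space.W0) @ space.null_basis + jitter
            elif params.init in ("anchored", "prior"):
                cand = rng.uniform(-params.init_coeff_scale, params.init_coeff_scale, (n, k))
            else:
                w_raw = rng.uniform(-params.w_max, params.w_max, (n, n))
                cand = (w_raw - space.W0) @ space.null_basis
            if _in_box(compose(space, cand), params.w_max):
                c = cand
                break
        if c is None:  # clip the last candidate into the box, re-project once
            w_clip = np.clip(compose(space, cand), -params.w_max, params.w_max)
            c = (w_clip - space.W0) @ space.null_basis
        w = compose(space, c)
        dusts.append(Dust(C=c, W=w, mass_value=mass_fn(w)))
    return dusts


def divide(
    dusts: Sequence[Dust], n_groups: int, rng: np.random.Generator
) -> list[list[Dust]]:
    """Uniformly random partition into ``n_groups`` nonempty groups."""
    if n_groups < 1 or n_groups > len(dusts):
        raise InvalidInputError("need 1 <= n_groups <= number of dusts")
    order = rng.permutation(len(dusts))
    groups: list[list[Dust]] = [[] for _ in range(n_groups)]
    for rank, idx in enumerate(order):
        if rank < n_groups:  # deal one dust per group first: no empty group
            groups[rank].append(dusts[idx])
        else:
            groups[int(rng.integers(n_groups))].append(dusts[idx])
    return groups


def select_centre(group: Sequence[Dust]) -> int:
    """Index of the minimum-mass dust; ties go to the first encountered."""
    if len(group) == 0:
        raise InvalidInputError("cannot select a centre from an empty group")
    masses = [d.mass_value for d in group]
    return int(np.argmin(masses))


def move_dust(
    surr: Dust,
    centre: Dust,
    space: SolutionSpace,
    params: GFAParams,
    mass_fn: MassFn,
) -> Dust | None:
    """Step ``surr`` toward ``centre``; ``None`` means absorbed.

    The candidate ``C' = C + pace * (C_centre - C)`` is legal when the
    materialized weights stay inside the box; otherwise the pace is halved,
    up to ``max_pace_halvings`` attempts in total.
    """
    pace = params.pace
    delta = centre.C - surr.C
    for _ in range(params.max_pace_halvings):
        c_new = surr.C + pace * delta
        w_new = compose(space, c_new)
        if _in_box(w_new, params.w_max):
            return Dust(C=c_new, W=w_new, mass_value=mass_fn(w_new))
        pace *= 0.5
    return None


def run(
    space: SolutionSpace,
    expr: ExpressionMatrix,
    deriv: DerivativeMatrix,
    B: np.ndarray,
    params: GFAParams | None = None,
    sparsity_lambda: float = 0.0,
) -> GFAResult:
    """Full gravitation-field search; returns the best dust ever observed."""
    params = params or GFAParams()
    if space.K == 0:
        raise DegenerateSpaceError("solution family is a single point (K=0)")
    mass_fn = make_mass_fn(expr, deriv, B, sparsity_lambda)
    rng = np.random.default_rng(params.seed)
    dusts = initialize_dusts(space, mass_fn, params, rng)

    best = dusts[select_centre(dusts)]
    result = GFAResult(best=best)
    since_improvement = 0
    last_best = best.mass_value
    for epoch in range(params.max_epochs):
        if len(dusts) <= params.n_groups:
            break
        new_population: list[Dust] = []
        for group in divide(dusts, params.n_groups, rng):
            members = list(group)
            restarts = 0
            while True:
                ci = select_centre(members)
                centre = members[ci]
                survivors = [centre]
                rest = [d for j, d in enumerate(members) if j != ci]
                restarted = False
                for pos, surr in enumerate(rest):
                    moved = move_dust(surr, centre, space, params, mass_fn)
                    if moved is None:
                        result.n_absorbed += 1
                        continue
                    survivors.append(moved)
                    if moved.mass_value < best.mass_value:
                        best = moved
                    if (
                        moved.mass_value < centre.mass_value
                        and restarts < params.max_group_restarts
                    ):
                        restarts += 1
                        members = survivors + rest[pos + 1 :]
                        restarted = True
                        break
                if not restarted:
                    members = survivors
                    break
            new_population.extend(members)
        dusts = new_population
        result.epochs_run = epoch + 1
        if best.mass_value < last_best:
            since_improvement = 0
        else:
            since_improvement += 1
        last_best = best.mass_value
        result.history.append(best.mass_value)
        if since_improvement >= params.stagnation_epochs:
            break
    result.best = best
    return result
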