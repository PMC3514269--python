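"""Comparison optimizers over the same solution family and mass function.

Three comparators share the objective and search space of the
gravitation-field algorithm:

* a genetic algorithm (tournament selection, uniform crossover, additive
  uniform mutation, elitism),
* simulated annealing (single-coordinate Gaussian proposals, Metropolis
  acceptance, geometric cooling), and
* the "traditional" differential-equation-model answer: the minimum-norm
  particular solution with no search at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import DegenerateSpaceError, InvalidInputError
from .gfa import Dust, GFAParams, MassFn, _in_box, initialize_dusts, make_mass_fn
from .model import DerivativeMatrix, ExpressionMatrix
from .svd_space import SolutionSpace, compose

__all__ = ["GAParams", "SAParams", "ga_run", "sa_run", "traditional_dem"]


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm settings (rates per spec of standard operators)."""

    pop_size: int = 60
    generations: int = 50
    crossover_rate: float = 0.9
    mutation_rate: float = 0.05
    mutation_scale: float = 0.1  # fraction of the +/- w_max box half-width
    tournament_size: int = 3
    elitism: int = 1
    w_max: float = 100.0
    seed: int = 0
    init: str = "prior"
    init_coeff_scale: float = 1.0

    def __post_init__(self) -> None:
        for rate in (self.crossover_rate, self.mutation_rate):
            if not 0 <= rate <= 1:
                raise InvalidInputError("GA rates must lie in [0, 1]")
        if min(self.pop_size, self.generations, self.tournament_size) < 1:
            raise InvalidInputError("GA sizes must be positive")


@dataclass(frozen=True)
class SAParams:
    """Simulated-annealing settings.

    ``initial_temp=None`` autosets the temperature to the standard deviation
    of the masses of 50 random dusts.  The proposal step perturbs one random
    coefficient with a Gaussian of scale ``proposal_scale * 2 * w_max``,
    annealed with ``sqrt(temp / initial_temp)`` so late-stage moves are fine.
    """

    initial_temp: float | None = None
    cooling: float = 0.95
    steps_per_temp: int = 20
    min_temp_fraction: float = 1e-4
    proposal_scale: float = 0.05
    w_max: float = 100.0
    seed: int = 0
    init: str = "prior"
    init_coeff_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.cooling < 1:
            raise InvalidInputError("cooling must lie in (0, 1)")
        if self.steps_per_temp < 1 or self.min_temp_fraction <= 0:
            raise InvalidInputError("invalid SA schedule parameters")


def _init_population(
    space: SolutionSpace,
    mass_fn: MassFn,
    n: int,
    w_max: float,
    init: str,
    init_coeff_scale: float,
    rng: np.random.Generator,
) -> list[Dust]:
    gfa_params = GFAParams(
        n_dusts=n, n_groups=1, w_max=w_max, init=init, init_coeff_scale=init_coeff_scale
    )
    return initialize_dusts(space, mass_fn, gfa_params, rng)


def ga_run(
    space: SolutionSpace,
    expr: ExpressionMatrix,
    deriv: DerivativeMatrix,
    B: np.ndarray,
    params: GAParams | None = None,
    sparsity_lambda: float = 0.0,
) -> Dust:
    """Genetic-algorithm search; returns the minimum-mass individual ever seen."""
    params = params or GAParams()
    if space.K == 0:
        raise DegenerateSpaceError("solution family is a single point (K=0)")
    mass_fn = make_mass_fn(expr, deriv, B, sparsity_lambda)
    rng = np.random.default_rng(params.seed)
    pop = _init_population(
        space, mass_fn, params.pop_size, params.w_max,
        params.init, params.init_coeff_scale, rng,
    )
    best = min(pop, key=lambda d: d.mass_value)
    step = params.mutation_scale * params.w_max

    def tournament() -> Dust:
        idx = rng.integers(len(pop), size=params.tournament_size)
        return min((pop[i] for i in idx), key=lambda d: d.mass_value)

    for _ in range(params.generations):
        elite = sorted(pop, key=lambda d: d.mass_value)[: params.elitism]
        children: list[Dust] = list(elite)
        while len(children) < params.pop_size:
            pa, pb = tournament(), tournament()
            c = pa.C.copy()
            if rng.random() < params.crossover_rate:
                take_b = rng.random(c.shape) < 0.5
                c[take_b] = pb.C[take_b]
            mutate = rng.random(c.shape) < params.mutation_rate
            if mutate.any():
                delta = rng.uniform(-step, step, c.shape) * mutate
                # shrink the mutation until the composed weights stay in-box
                for _ in range(10):
                    if _in_box(compose(space, c + delta), params.w_max):
                        c = c + delta
                        break
                    delta *= 0.5
            w = compose(space, c)
            if not _in_box(w, params.w_max):  # crossover overshoot: keep parent
                c, w = pa.C, pa.W
            child = Dust(C=c, W=w, mass_value=mass_fn(w))
            children.append(child)
            if child.mass_value < best.mass_value:
                best = child
        pop = children
    return best


def sa_run(
    space: SolutionSpace,
    expr: ExpressionMatrix,
    deriv: DerivativeMatrix,
    B: np.ndarray,
    params: SAParams | None = None,
    sparsity_lambda: float = 0.0,
) -> Dust:
    """Simulated-annealing search; returns the best state ever visited."""
    params = params or SAParams()
    if space.K == 0:
        raise DegenerateSpaceError("solution family is a single point (K=0)")
    mass_fn = make_mass_fn(expr, deriv, B, sparsity_lambda)
    rng = np.random.default_rng(params.seed)

    state = _init_population(
        space, mass_fn, 1, params.w_max, params.init, params.init_coeff_scale, rng
    )[0]
    best = state

    temp0 = params.initial_temp
    if temp0 is None:
        probe = _init_population(
            space, mass_fn, 50, params.w_max, params.init, params.init_coeff_scale, rng
        )
        temp0 = float(np.std([d.mass_value for d in probe]))
    temp0 = max(temp0, 1e-12)
    base_step = params.proposal_scale * 2.0 * params.w_max

    temp = temp0
    n, k = state.C.shape
    while temp > temp0 * params.min_temp_fraction:
        scale = base_step * max(np.sqrt(temp / temp0), 1e-3)
        for _ in range(params.steps_per_temp):
            c_new = state.C.copy()
            c_new[rng.integers(n), rng.integers(k)] += rng.normal(0.0, scale)
            w_new = compose(space, c_new)
            if not _in_box(w_new, params.w_max):
                continue
            m_new = mass_fn(w_new)
            d_mass = m_new - state.mass_value
            if d_mass <= 0 or rng.random() < np.exp(-d_mass / temp):
                state = Dust(C=c_new, W=w_new, mass_value=m_new)
                if state.mass_value < best.mass_value:
                    best = state
        temp *= params.cooling
    return best


def traditional_dem(space: SolutionSpace) -> np.ndarray:
    """The no-search baseline: the minimum-norm particular solution."""
    return space.W0.copy()
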