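# Methods

## Model and estimation problem

The package fits the linear regulatory model `dx/dt = W·x + B` to an
expression time series of N genes at T timepoints.  Derivatives are
estimated by forward differences over consecutive timepoints
(`d_it = (x_{i,t+1} − x_{i,t}) / Δt`), pairing derivative column *t* with
expression column *t*; a central-difference scheme is available via
`derivative_scheme="central"`.  Forward differences are exact for data
generated by a forward-Euler integrator, which is what the bundled
simulator uses — so on noiseless simulated data the generating matrix has
exactly zero residual.  The basal vector `B` is treated as known (the
simulator exports the true one; user data default to zeros); the model
never estimates it.

The aligned expression block is decomposed by full SVD.  Singular
directions above the rank tolerance constrain the estimate; the remainder
span the *solution family* `W = W₀ + C·U₀ᵀ`, with `W₀` the truncated
minimum-norm least-squares solution and one free coefficient per gene and
null direction (an N×K matrix `C`, since each row of `W` carries
independent freedom).  All search is performed in coefficient space, which
keeps every candidate inside the family by construction; the `[−w_max,
w_max]` box (default 100) is enforced on the materialized weights.

### Rank tolerance

`rank_tol` (default `1e-10`, relative to the largest singular value)
separates retained from searchable directions.  `rank_tol="auto"`
estimates the noise level from the smallest singular value via the
Marchenko–Pastur bulk edges and truncates every noise-dominated direction;
it assumes the bottom of the spectrum is noise and degrades gracefully
(no truncation) on noise-free rank-deficient data, but will over-truncate
clean full-rank matrices whose smallest singular value is itself signal.
Auto truncation moves the estimate toward a sparse, high-precision /
low-recall regime; the numeric default keeps every data direction and
yields denser, higher-recall networks.  The default benchmark uses the
numeric tolerance.

## Objective ("mass") and sparsity

The search objective is the sum of squared residuals (optionally plus
`λ·Σ|w_ij|`).  Over an *exact* null family the residual term is constant
— a direct consequence of the family construction — so with `λ = 0` the
objective cannot rank family members and the search outcome is decided by
initialization alone.  The benchmark therefore hands the metaheuristics a
small L1 pressure (`sparsity_lambda = 0.01`); because the quadratic term
is flat across the family, the location of the family optimum is
independent of λ's magnitude, which only shapes the search dynamics.  The
model-level default remains `λ = 0`.

## Gravitation-field search

Per epoch: random partition into `n_groups` groups (each nonempty), the
minimum-mass dust of each group becomes its centre, and every surrounding
dust moves `C ← C + pace·(C_centre − C)`.  A step whose weights leave the
box halves the pace and retries, up to `max_pace_halvings` times, after
which the dust is absorbed (deleted).  A mover that beats its centre
becomes the new centre and the group's movement pass restarts (bounded by
`max_group_restarts` to guarantee termination).  The run stops at
`max_epochs`, after `stagnation_epochs` without improvement of the global
best, or when the population shrinks to `n_groups` dusts.  Defaults:
60 dusts, 6 groups, pace 0.5, 3 pace halvings, 50 epochs, stagnation 10.

**Initialization.** The literal prescription — draw a dense random matrix
and keep it only if it lies in the family — almost surely never
terminates, because a random matrix has probability zero of satisfying the
family constraint.  Three well-defined modes are provided:

* `prior` (default): half the dusts are sparsified particular solutions
  (entries below a per-dust random cutoff in `(0, 0.5]` zeroed, then
  projected to the nearest family member), half are random coefficient
  perturbations of `W₀`.  This encodes the prior that regulatory networks
  are sparse, the one piece of structure the flat objective cannot supply.
* `anchored`: coefficients uniform on `[−init_coeff_scale,
  +init_coeff_scale]` (default 1.0, the scale of typical regulatory
  weights) around `W₀`.
* `box`: a dense uniform draw over the weight box projected onto the
  family — the data-blind variant, kept for reference.  Its dusts start at
  near-maximal norm (projected entries have sd ≈ w_max/3), from which the
  contraction dynamics cannot reach sparse networks.

**Known limitation — premature convergence.** The algorithm's only
operators contract the population (movement toward centres, absorption);
nothing re-injects diversity.  On smooth landscapes the population
collapses geometrically onto a near-best sampled point and refinement
stops: measured on forced one-dimensional quadratic families, the search
reliably captures 50–90% of the improvement available to dense grid
search but not the final few percent, at any population size or restart
budget.  The GA (mutation) and SA (proposals) comparators do converge to
the grid optimum on the same landscapes.  This is a property of the
described mechanics, documented rather than papered over.

## Comparators

The GA uses tournament selection (size 3) on mass, uniform crossover of
coefficient entries (rate 0.9), additive uniform mutation (rate 0.05,
scale 0.1 of the box half-width, halved until the composed weights stay
in-box), and single-individual elitism.  The SA performs Metropolis
updates of one random coefficient at a time with Gaussian proposals whose
scale (0.05 of the box width) anneals with `sqrt(temp/temp0)` — a standard
adaptive-step variant; the initial temperature is the standard deviation
of 50 random dust masses, cooled geometrically (0.95) to `1e-4` of its
start.  `dem` is the no-search baseline: threshold the particular solution
directly.  All methods consume the same family and mass objects.

## Synthetic benchmark

The simulator emulates a hub-dominated transcriptional network observed as
a short, noisy, unit-spaced time course:

* **Topology** — growth from a 3-node feed-forward seed; each new node
  receives one incoming edge whose regulator is drawn by preferential
  attachment on out-degree (smoothing offset 0.25, which concentrates
  control on a few hubs) and re-drawn with probability 0.2 (reconnection).
  Growth edges run old→new, so the graph is acyclic; 15% of nodes carry an
  inhibitory self-loop.  Edge magnitudes are uniform on [0.6, 1.5] —
  deliberately above the 0.5 detection threshold so no true edge is
  invisible by construction — with negative sign probability 0.5.
* **Dynamics** — `dx/dt = W_true·x + B` with `W_true = A − diag(δ)`,
  gene-specific decay rates δ uniform on [0.15, 0.45] per time unit
  (below the detection threshold, so a bare decay diagonal is not counted
  as an edge; heterogeneous rates keep trajectory modes independent, which
  makes the noiseless determined system identifiable).  If a configuration
  is unstable the interaction part is rescaled until the spectral abscissa
  is ≤ −0.1.  Forward-Euler integration with dt = 1.0 (matching published
  time-course tables with unit-spaced samples), T = 15 recorded samples,
  x₀ uniform on [0, 1], B uniform on [−0.3, 0.3].
* **Noise** — independent uniform perturbations on [−0.05, +0.05] added
  to every recorded value.
* **Ground truth** — the post-stabilization generating matrix itself,
  thresholded exactly like the predictions, so evaluation is
  self-consistent even when rescaling changes magnitudes.

Not emulated: saturating kinetics, inter-gene feedback cycles,
multiplicative or heteroscedastic noise, missing values.  Passing
benchmarks therefore demonstrate correct behaviour of the estimator and
search machinery under the linear model's own assumptions, not performance
on real microarray data.

## Evaluation

Confusion counts run over all N² ordered gene pairs, self-pairs included;
matching is sign-agnostic by default (a `sign_aware` flag counts a
wrong-sign prediction as FP + FN).  PPV and Se report 0/0 as missing, not
zero.  The replicate benchmark re-simulates network and data each run
(seed = base seed + run index), hands every method identical data, and
averages; wall time per method is recorded for reporting only and is the
one non-reproducible column of the output table.

### What the benchmark can and cannot show

Under the default study conditions the aligned 20×14 expression block
carries roughly five informative singular directions above the noise
bulk.  Oracle experiments (exact basis pursuit over the family at every
truncation level; per-row cross-validated lasso with OLS debiasing; the
projection of the true matrix onto the family) bound what *any* estimator
can achieve here: roughly Se ≤ 0.4 at PPV ≈ 0.1–0.2, or PPV ≈ 0.8 at
Se ≈ 0.1, with a balanced optimum near (0.45, 0.34).  The replicate means
produced by `scripts/acceptance.py` sit on this frontier (all methods
near PPV ≈ 0.11, Se ≈ 0.32–0.34, with the gravitation-field search
slightly ahead of the no-search baseline in sensitivity).  Published
figures for this class of experiment that lie far above this frontier
imply gentler, unpublished generator settings (weaker noise, longer or
richer time courses); they are not reachable by re-implementation under
the conditions stated here, and the package reports what it actually
computes.

## Numerical notes

* Rank decisions are relative to the largest singular value; `force_null_k`
  moves the smallest retained directions into the search family and is how
  the K=1 optimizer tests construct quadratic landscapes.
* Family membership uses a relative Frobenius test
  (`eps = 1e-6` of `max(1, ‖W − W₀‖_F)`); projection is the orthogonal
  projector onto the null subspace and is idempotent to machine precision.
* Centre selection breaks mass ties by first index; group restarts are
  capped; every stochastic component takes a seed and the whole pipeline
  is bit-reproducible for a fixed seed.
* Degenerate inputs fail loudly: non-increasing timepoints, ragged TSV
  rows, all-zero spectra, K = 0 search requests (the Model interface
  short-circuits those to the particular solution with a logged notice).
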