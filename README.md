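# gravinet

Reverse engineering of gene regulatory networks (GRNs) from short
expression time series, for computational biologists benchmarking
network-inference methods on simulated scale-free networks.

## The model

Gene expression is modeled by the linear differential-equation system

```
dx_i/dt = Σ_j w_ij · x_j(t) + b_i
```

where `w_ij` is the signed strength with which gene *j* regulates gene *i*
(positive = activation, negative = inhibition) and `b_i` is a basal term.
With `X` the N×(T−1) aligned expression block, `Ẋ` the finite-difference
derivatives and `B` known, every weight matrix consistent with the data in
the least-squares sense forms the affine family

```
X = U·S·Vᵀ              (SVD)
W₀ = (Ẋ − B·1ᵀ)·V·S⁺·Uᵀ  (minimum-norm particular solution)
W  = W₀ + C·U₀ᵀ          (general solution; U₀ = left null directions)
```

When the series is shorter than the gene count (T−1 < N) the family is a
genuine continuum: the data cannot distinguish its members.  The package
searches this family for a sparse signed network with a **gravitation-field
algorithm** (GFA): candidate solutions ("dusts") carry a mass — the sum of
squared model residuals, optionally plus an L1 sparsity term — and are
grouped randomly each epoch; every dust steps toward its group's
minimum-mass centre with a halving pace, dusts that cannot move legally
inside the `[−100, 100]` weight box are absorbed, and a mover that beats
its centre takes over the group.  Genetic-algorithm and simulated-annealing
searchers and the no-search particular solution (`dem`) run over the
identical family and objective as comparators.  An edge is finally declared
where `|w_ij| ≥ τ` (default 0.5), and predictions are scored against the
generating network by precision (PPV = TP/(TP+FP)) and sensitivity
(Se = TP/(TP+FN)).

A scale-free network simulator (growth + preferential attachment with a
reconnection step, inhibitory self-loops, signed uniform weights,
forward-Euler dynamics with gene-specific decay, uniform perturbation
noise) makes the entire benchmark self-contained.

## Worked example

```
$ gravinet simulate --nodes 20 --timepoints 15 --seed 1 --out-dir demo
wrote expression.tsv (20x15), basal.tsv, weights.tsv, truth.sif (23 edges) to demo

$ cd demo && gravinet infer --expr expression.tsv --basal basal.tsv \
      --method gfa --seed 1 --sparsity-lambda 0.01
Gene regulatory network inference results
=============================================
method:            gfa
genes (N):         20
timepoints (T):    15
null dimension K:  6
mass (objective):  0.988149
sparsity lambda:   0.01
threshold tau:     0.5
edges >= tau:      54

regulator   target          weight  effect
---------------------------------------------
Node6       Node6           -1.782  inhibition
Node11      Node11          -1.761  inhibition
Node7       Node11          -1.394  inhibition
...

$ gravinet evaluate --pred network.sif --truth truth.sif --json
{"TP": 5, "FP": 49, "FN": 18, "ppv": 0.0926, "se": 0.2174}
```

The summary reports the family dimension K (here 6: 20 genes observed at
14 aligned timepoints), the objective value of the selected network, and
the thresholded edge list with regulation signs; `evaluate` counts directed
edges over all ordered gene pairs, self-loops included.  Single runs vary
widely — method comparisons should use the replicate benchmark:

```
$ gravinet benchmark --runs 50 --methods gfa,ga,sa,dem --seed 1 --out bench.tsv
```

which re-simulates a fresh network per run, gives every method identical
data, and reports mean ± sd of PPV and Se per method.

The same pipeline is available programmatically:

```python
from gravinet import GRNModel, io

expr = io.read_expression_tsv("demo/expression.tsv")
basal, _ = io.read_basal_tsv("demo/basal.tsv")
res = GRNModel(expr, basal=basal).fit(method="gfa", sparsity_lambda=0.01, seed=1)
print(res.summary(tau=0.5))
res.to_sif("network.sif")
```

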