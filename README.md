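# netdiff

Estimating the **structural difference between two causal Bayesian networks**
learned from two datasets — in particular when the datasets have very
different sample sizes.

## The problem

Comparing the causal mechanisms of two systems (disease vs. control cohorts,
two cell types, two patient populations) is usually done by learning a causal
network from each dataset and comparing the results. Writing `E_i` for the
edge set of network `G_i`, the target of inference is the edge difference

```
[E_i − E_j]((X,Y)) = 1  if the edge X→Y is in G_i but not G_j,  0 otherwise
```

over all ordered pairs (orientation mode) or unordered pairs (skeleton mode).
Treating every pair as an instance of a binary classification problem lets
standard ranking metrics (AUCROC, AUPR) and cross-entropy quantify how well an
estimator recovers the true difference.

The catch: structure discovery quality depends on sample size. If `D_i` has
1000 rows and `D_j` has 200, edges of moderate strength are found in `D_i` and
missed in `D_j` even when present in both systems — and the naive "learn each,
subtract" approach reports them as differences. `netdiff` implements three
estimators:

- **naive** — one discovery run per dataset; score 1 iff the edge is found in
  `D_i` only.
- **bootstrap (bs)** — per dataset, run discovery on B with-replacement
  resamples and record each edge's discovery frequency in [0, 1]; score the
  difference of frequencies in [−1, 1].
- **equal-sample-size resampling (rsbs)** — like bootstrap, but the larger
  dataset is scored on B *without*-replacement subsamples at the smaller
  dataset's size, equalizing statistical power before differencing. Not
  applicable when the sizes are equal.

Two structure discovery backends are built in: PC-stable with the Fisher-z
conditional-independence test (default α = 0.05), and Greedy Equivalence
Search with the Gaussian BIC score (penalty discount 1). Both return
CPDAG-style patterns; undirected pattern edges count toward both orientations
by default (configurable).

The package also ships the paired-network simulator used to validate all of
this: random DAGs parameterized as linear-Gaussian structural equation models
with every marginal variance equal to 1 (coefficients β = b·u with
P(b=1)=0.6, P(b=−1)=0.4, u ~ U(0.1, 0.35)), a derived second network differing
in a controlled number of edges, per-edge Cohen's f² effect sizes computed in
closed form, a factorial experiment grid with a one-standard-deviation
best-method tabulation rule, and a permutation protocol that manufactures a
ground-truth pair from any single real dataset.

## Worked example

```python
import netdiff as nd

# a 20-node, 40-edge network and a partner differing in 8 edges
g1 = nd.random_network(n_vars=20, n_edges=40, seed=7)
pair = nd.derive_pair(g1, n_diff=8, seed=8)

d1 = nd.sample_data(pair.g1, 1000, seed=9)   # large dataset from G1
d2 = nd.sample_data(pair.g2, 200, seed=10)   # small dataset from G2

scores = nd.bootstrap_diff(d1, d2, algorithm="pc", b=50, mode="orientation", seed=11)
labels = nd.true_edge_diff(pair.g1, pair.g2, mode="orientation")
report = nd.classification_metrics(labels, scores)
```

The four edges deleted from `G1` in this pair are `V01→V14`, `V05→V06`,
`V07→V08` and `V07→V17`. The top bootstrap difference scores are

```
V06->V18: +0.98
V07->V17: +0.94
V05->V06: +0.86
V01->V14: +0.86
V08->V09: +0.86
V11->V15: +0.74
```

— three of the four truly deleted edges rank in the top five (the others are
sample-size artifacts of exactly the kind the scores are designed to expose as
*uncertain* rather than certain). The metrics print as

```
bootstrap: AUCROC=0.957  AUPR=0.440  CE=0.080
naive:     AUCROC=0.981  AUPR=0.222  CE=0.509
```

The bootstrap's graded scores roughly double the naive method's area under the
precision-recall curve and cut its cross-entropy by a factor of six: resampling
confidence, not just presence/absence, is what makes unequal-sample-size
comparison workable.

A command-line interface mirrors the library
(`netdiff simulate-pair | sample | discover | diff | evaluate | grid |
realdata`); e.g.

```
netdiff diff d1.csv d2.csv --method bs --b 50 --mode skeleton --out scores.tsv
```

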