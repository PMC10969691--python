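# Methods

## Model and problem

Each system is a causal Bayesian network: a DAG `G = (V, E)` whose joint
distribution factorizes according to the graph with causal edge semantics.
Given datasets `D_i`, `D_j` generated by networks `G_i`, `G_j` over the same
variables, the estimand is the edge-set difference `E_i − E_j`: the pairs
whose edge is present in `G_i` and absent from `G_j`. The difference in the
reverse direction is a distinct estimand (its positives are disjoint).
Estimation is evaluated as binary classification over the pair universe —
`Nv·(Nv−1)` ordered pairs in orientation mode, `Nv·(Nv−1)/2` unordered
pairs in skeleton mode.

## Estimators

All three estimators delegate structure discovery to a backend `M` that
returns a CPDAG-style pattern, and differ only in how they convert discovery
output into per-pair scores:

- **naive**: run `M` once per dataset; score((X,Y)) = 1 iff the indicator
  from `D_i` is 1 and from `D_j` is 0. Binary output, no uncertainty.
- **bootstrap (bs)**: run `M` on `B` with-replacement resamples of each
  dataset; per-pair discovery frequencies `Ê_i, Ê_j ∈ [0,1]`; score =
  `Ê_i − Ê_j ∈ [−1,1]`.
- **equal-sample-size resampling (rsbs)**: frequencies for the larger dataset
  come from `B` without-replacement subsamples at the smaller dataset's size;
  the smaller dataset is bootstrapped; the difference is taken in (i, j)
  order. Raises a "not applicable" error when the sizes are equal (by design —
  the method exists to correct a power imbalance that is absent there).

`B` defaults to 50 and is configurable. Resampling RNG streams are derived
from the call seed *and a content digest of the dataset*, so the two argument
orders reuse bit-identical frequency maps and `diff(i,j) = −diff(j,i)`
exactly; both evaluation modes are read off the same resample runs.

## Discovery backends

No external causal discovery engine is bundled; both backends are first-class
implementations living behind the same adapter surface:

- **PC-stable** with the Fisher-z partial-correlation test (default
  α = 0.05). Order-independent skeleton phase, collider orientation by
  separating sets, Meek rules R1–R3 to the maximally oriented pattern.
  Conflicting collider orientations fall back to undirected. An optional
  conditioning-set size cap trades fidelity for speed.
- **GES** (greedy equivalence search) with the Gaussian BIC score
  `score(v|P) = −n/2·log σ̂²_{v|P} − c/2·log n·(|P|+1)`, penalty discount
  `c = 1`. Forward/backward phases over CPDAGs with the standard
  Insert/Delete operators (clique and blocked-path validity conditions),
  PDAG-to-DAG extension by sink elimination, and compelled-edge relabelling
  after every operator. The neighbor-subset enumeration per operator is
  capped at 10 candidates; this only binds on unusually dense neighborhoods.

CPDAGs leave some edges undirected. In orientation mode an undirected edge
contributes an indicator of 1 to *both* orderings under the default
`undirected_policy="both"` (an undirected pattern edge does not rule out
either direction); `"none"` is available and the choice is recorded in every
serialized output. Skeleton mode is unaffected.

## Evaluation

- **AUCROC**: trapezoidal area, equal to the probability that a random
  positive outscores a random negative with ties counting one half.
- **AUPR**: interpolation-free step-wise summation (the average-precision
  convention); conventions differ across software, so this one is fixed here.
- **Cross-entropy**: difference scores live in [−1,1] and are not
  probabilities. The default mapping is `p = clip(max(s,0), 1e−6, 1−1e−6)` —
  a negative score is evidence *against* membership in `E_i − E_j`, so it is
  clamped to (near) zero probability. The alternative `p = (s+1)/2` is
  available as `ce_mapping="shift"`. The mapping in force is recorded in each
  report.
- **Thresholded metrics** (sensitivity, specificity, PPV, NPV, F1, accuracy):
  the threshold is scanned over midpoints of consecutive distinct scores
  (plus sentinels below/above the range) and chosen to maximize F1; ties
  break toward the higher threshold, i.e. fewer predicted positives.
  Zero-denominator ratios are reported as 0 and flagged in the report's
  `zero_division` field. Degenerate label sets (no positives or no
  negatives) yield `None` ranking metrics rather than 0.
- **Effect size**: for edge X→Y, Cohen's
  `f² = (R²(Pa(Y)) − R²(Pa(Y)∖X)) / (1 − R²(Pa(Y)))`, computed from the
  *population* R² of the implied covariance rather than any sample — in
  simulation the ground-truth network is known, so the population value is
  the right reference. The effect-size/score relationship is summarized by
  the Spearman rank correlation (undefined cases — fewer than 3 edges, zero
  variance — are flagged, not coerced to 0).

## Simulator

`G1` is a uniformly random node order with `Ne` edges sampled uniformly
without replacement among the order-respecting pairs. (No canonical random-DAG
distribution exists; this scheme is simple, seedable, hits the requested edge
count exactly, and is documented precisely because results can depend on the
degree distribution it induces.)

Coefficients follow `β = b·u`, `P(b=1)=0.6`, `P(b=−1)=0.4`,
`u ~ Uniform(0.1, 0.35)`; noise scales are solved node-by-node in topological
order so every marginal variance is exactly 1 (tolerance 1e−8 — the
floating-point closure of the recursive variance computation). When a node's
pre-noise variance exceeds 1 no valid noise scale exists; the
coefficient draw is discarded and, at the `random_network` level, a fresh DAG
is generated for the next attempt. This parameterization produces edge effect
sizes mainly in the small-to-medium band `f² ∈ [0.02, 0.35)` (verified on 20
random 200-edge networks: ≥ 80 % of edges fall in the band).

`G2` is derived from `G1` by deleting `⌈Nd/2⌉` random edges and adding
`⌊Nd/2⌋` order-respecting non-edges (deletions get the extra edge when `Nd`
is odd, recorded in the pair metadata). Shared edges keep bitwise-identical
coefficients; added edges are drawn by the same law; all noise scales of `G2`
are re-solved. On variance overflow only the added-edge coefficients are
redrawn (up to 100 times, then a fresh addition set) — `G1` is fixed context
and is never regenerated. Using `G1`'s generation order for additions
guarantees `G2`'s acyclicity without cycle checks.

Sampling evaluates the structural equations in topological order with
independent Gaussian noise. All randomness derives from per-purpose child
streams of a master seed; no global RNG state.

### What the simulator does and does not emulate

Data are exactly multivariate Gaussian, linear, homoscedastic, fully
observed, and i.i.d., with unit marginals. Real biomedical data are none of
these (mixed types, heavy tails, latent confounding, selection). Passing
tests on simulated data therefore validate the estimators' behavior under
the stated model, not their field performance — which is why the real-data
permutation protocol exists: it takes any user dataset, permutes two disjoint
variable sets (size `Np`, default 2 or 6) to sever their dependences in two
full-size copies, treats the patterns learned from the full copies as the
reference pair, and evaluates the estimators on a 60 % subsample of one copy
versus ratio-subsamples {0.1, 0.2, 0.5, 1}·N1 of the other (all subsampling
without replacement; ceil applied to fractional sizes).

## Experiment grid

The default `GridSpec` is `Nv = 100`, `Ne = {1.5, 2, 2.5}·Nv`,
`Nd = ⌈{0.05, 0.1, 0.2, 0.5, 1}·Ne⌉`, `N1 = {500, 1000, 2000, 5000}`,
`N2 = ⌈{0.1, 0.2, 0.5, 1}·N1⌉`, 50 repeats — 240 conditions, 12,000 dataset
pairs, 180 conditions where rsbs applies. The full grid is cluster-scale and
is enumerated but not executed by the test suite; a clearly labeled
smoke preset (`Nv = 20`, one condition axis each, 10 repeats, B = 25) covers
the qualitative claims at desk scale. The per-module test and acceptance
runs use 10–20-node networks with B = 10–25 so the whole suite completes in
minutes.

The best-method tabulation marks, per condition, every method whose mean
metric lies within one standard deviation of the best method's mean — the SD
used is the *best* method's SD, with the inequality mirrored for
cross-entropy where lower is better. rsbs percentages are over its applicable
conditions only; conditions missing a metric are excluded and counted.

## Known limitations

- GES here is a faithful but unoptimized implementation; at hundreds of
  variables the per-iteration operator scan dominates. PC's worst case is
  likewise exponential in neighborhood size (the optional conditioning-set
  cap mitigates).
- The Fisher-z test assumes Gaussianity; on heavy-tailed data its calibration
  (and hence PC's α) degrades.
- Bootstrap frequencies are granular at 1/B; with the default B = 50 scores
  resolve to 0.02. Ranking metrics are insensitive to this; cross-entropy is
  mildly affected near 0 and 1.
- Orientation-mode results depend materially on the undirected-edge policy;
  both policies are exposed and every report records the one in force.
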