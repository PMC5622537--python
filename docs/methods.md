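# Methods

## Diffusion model

The package works on an undirected gene network, loaded from a three-column
edge list (two identifiers plus a confidence score on the 0–1000 scale used
by STRING-style resources). Edges below the confidence threshold (default
700) are dropped; duplicate gene pairs arising from many-to-one protein→gene
mapping are collapsed to the highest-scoring edge; self-pairs are removed.
Adjacency is binary by default — the confidence scores survive thresholding
but there is no principled reason to let them weight the diffusion — with a
`weighted=True` option (scores/1000) for sensitivity analysis. Nodes are
ordered lexicographically so every matrix is reproducible bit-for-bit, and
isolated nodes are kept in the index with zero rows in `W`: their diffusion
value decays to `(1−a)·X0` and they can never be predicted, but gene
indexing stays stable across analyses.

The normalized adjacency `W = D^{-1/2} A D^{-1/2}` has spectral radius at
most 1, so the recurrence `X_{t+1} = a·W·X_t + (1−a)·X0` is a contraction
for retention parameter `a < 1` and converges to
`X* = (1−a)(I − a·W)^{-1} X0`. The default `a = 0.7` balances seed
retention against propagation; smaller values keep `X*` close to `X0`,
larger values spread mass further and blur list-specific signal. The
iterative solver starts at `X0`, stops when the max-norm update falls below
`tol = 1e-6` (configurable; `max_iter = 10000`), and accepts an `(n, K)`
matrix of seed vectors so the whole permutation null is diffused in one
pass of sparse matrix–dense matrix products. The closed-form sparse solve
is exact and serves as the independent oracle in the tests; the two agree
to < 1e-8 on every test network at `tol = 1e-10`.

## Smoothing index and permutation adjustment

`S(g) = X*(g)/(X0(g) + eps)` measures how much mass a gene holds after
diffusion relative to what it started with; `eps > 0` both regularizes the
ratio for non-seeds (`X0 = 0`) and tunes how strongly the inputs dominate
the ranking. The empirical p-value permutes the *multiset* of seed values
over all node labels — preserving the seed count and the weight alphabet
(1 / 0.5) — recomputes `S_k` with the same `a` and `eps`, and counts ties
as exceedances:

```
pS(g) = (1 + #{S_k(g) >= S(g)}) / (K + 1),   K = 999 by default
```

so `pS` is bounded in `[1/(K+1), 1]` and `Sp = −log10(pS)·S` is zero
exactly where `pS = 1`. Permuting over all nodes (rather than swapping only
with non-seeds) was chosen because it preserves the null's value structure
and makes every gene exchangeable under the null; a permutation-invariant
`X0` (all genes seeded equally) correctly degenerates to `pS = 1`
everywhere. Ranking is by descending `Sp`, ties broken by descending `S`,
then lexicographic gene identifier — fully deterministic.

### Epsilon calibration

For single-list analyses `eps` is calibrated so that the top-2N genes by
`Sp` (N = number of input genes) split 1:1 into input and predicted genes.
For a fixed diffusion the seed/non-seed index ratio is
`eps/(1+eps) · X*(seed)/X*(non-seed)`, strictly increasing in `eps`, so the
input count in the window is monotone and bisection on log-`eps` (range
1e-4–64, 40 steps) is valid. The permutation null is computed once and
reused for every candidate — the permuted `X*` does not depend on `eps`,
only the denominators do — which makes calibration exact and cheap. Balance
within ±1 input gene is accepted; unattainable balance (e.g. all genes
seeded) is an error that reports the counts at both extremes. The window
can be overridden; joint multi-list runs skip calibration and fix
`eps = 1`, because their purpose is prioritizing the inputs themselves
rather than predicting neighbors.

## Network resampling and module extraction

For the top-m ranked genes, `Omega(m) = Sp(m)' A_m Sp(m)` (the quadratic
form, each undirected edge counted twice) summarizes score-weighted
connectivity of the induced subgraph. Its null distribution comes from
q = 200 degree-preserving randomizations of `A_m`: double edge swaps
applied in vectorized batches — each batch proposes simultaneous swaps,
rejects any that would create a self-loop or duplicate edge or that
conflict with an earlier proposal in the same batch, and applies the rest —
with a total attempt budget of 10 swaps per edge. The degree sequence is
preserved by construction and asserted in tests; graphs admitting no swap
(< 2 edges, triangles) are returned unchanged. p-values use the same
pseudocount form as `pS` (`(1 + #{Omega_k >= Omega})/(q + 1)`; a
`pseudocount=False` flag gives the plain exceedance fraction).

The default rank grid steps by 10 up to twice the seed count, then by 25 up
to five times it. Two p-values are recorded per grid point: `p_NR` for the
whole prefix and `p_inc` for the *increment* — the connectivity contributed
by edges touching the genes added since the previous grid point, measured
against the same rewired draws.

The increment test exists because the prefix statistic alone cannot locate
a module's far boundary: once a connected high-`Sp` core is inside the
prefix, rewiring scatters its edges onto the low-`Sp` tail and
`Omega_k < Omega` essentially always, so `p_NR` stays at its minimum for
*every* larger cutoff. Module extraction therefore proceeds in two steps:
find the first run of grid points with `p_NR` at or below the significance
level (default 0.05) sustained over a confirmation window (default 3 grid
points — a single noisy dip cannot seed a module), take the start of that
run as the onset, then extend the cutoff while the prefix stays significant
and each added chunk is itself significant (`p_inc <=` level). The module
is the full top-m* prefix — not just its largest connected component — with
induced edges, connected components and a per-source membership breakdown;
"no significantly connected prefix" is a valid, explicit outcome. When a
profile carries no increment p-values the rule degrades to the largest
sustained-significant prefix.

## Over-representation and enrichment map

All pathway tests are upper-tail hypergeometric probabilities computed
exactly (scipy), never by normal approximation, and corrected with
Benjamini–Hochberg. Gene sets outside the 10–200 size band are discarded on
load. Queries, annotations and pathways are restricted to the chosen
background before testing; two background modes are supported (network
genes only, or network genes plus all original-list genes), and
module-annotation overlap tests additionally accept an explicit background
set such as "network minus input genes". The expected overlap is reported
as `|M|·|annotation|/|background|` alongside the tail probability. A
per-gene variant tests whether a gene's interactors contain more risk genes
than expected (draws = the gene's neighbors; isolated genes get p = 1).

The enrichment map keeps pathways with adjusted p below 0.01, clusters them
by single linkage on `1 − o` (overlap coefficient
`o = |A∩B|/min(|A|,|B|)`) cut at the edge threshold, retains at most 20
representatives per cluster (most significant first), weights nodes by
`−log10(adjusted p)` and draws an edge when `o > 0.5` and the pair ranks in
the top-5 most similar pathways of at least one endpoint (ties broken by
pathway name, so the map is invariant to input order).

## Synthetic benchmark

The generator emulates the statistical structure of a high-confidence
interaction-network study without any download:

- **Network**: configuration model with power-law degrees (exponent 2.5,
  minimum degree 2, maximum ~sqrt(n)), multi-edges and self-loops dropped.
  This gives direct control of the degree tail that the permutation
  adjustment is meant to counteract. Default 2000 nodes.
- **Planted module**: a random gene subset (default 100) wired into a
  connected subgraph (random spanning tree plus random pairs) at internal
  edge density 0.1. Edges are only added, so degrees outside the module are
  untouched; densities too low to connect the module are rejected.
- **Seed lists**: six lists, each an independent 30% sample of the module
  plus off-module contamination making up 5% of the list
  (`k_off = k_on·c/(1−c)`, so `c < 1` is required and zero coverage yields
  an empty list). Independent sampling makes the expected pairwise overlap
  ≈ coverage² of the module — the low-overlap regime seen across real
  disease-gene studies, where most genes occur in a single list.
- **Pathways**: 50 gene sets with sizes uniform in 10–200; 20% of them draw
  80% of their genes from the module (ground-truth positives), the rest are
  uniform draws (nulls).

Everything is a pure function of the scenario seed; `write_scenario` emits
byte-identical edge lists, gene lists, GMT and a truth file on reruns.

What the synthetic benchmark does *not* capture: real interaction networks
have community structure, degree–function correlation and annotation
biases; real study lists are not independent samples (shared discovery
pipelines correlate their errors); real pathway databases overlap heavily.
Passing the recovery tests shows the statistics behave as designed under
their own assumptions, not that any particular biological module is
correct.

## Problem sizes and numerical choices

The standard benchmark scenario used by the acceptance script and the
deepest test is 2000 nodes with a 100-gene module and K = 199 permutations
(q = 200 rewires); at that size the full pipeline runs in about a minute.
Unit tests use 150–500-node scenarios with K down to 19. Exceedance
comparisons use a 1e-12 absolute guard so float noise cannot flip a tie;
convergence is judged in max-norm; all RNG flows through
`numpy.random.default_rng` with per-stage seeds derived by hashing a root
seed with the stage name (kept below 2^31).

## Known limitations

- `p_NR`'s one-sidedness means the method detects *excess* connectivity
  only; anti-modular structure is invisible.
- The increment rule inherits the grid resolution: the module boundary is
  located to within one grid step.
- Calibration assumes the input-count-vs-epsilon curve is monotone; the
  permutation null makes it only almost surely so, and the implementation
  accepts ±1 gene of slack.
- Degree-preserving rewiring mixes slowly on graphs with very skewed
  degree sequences; 10 swaps per edge is a pragmatic default, not a proof
  of mixing.
- With few permutations (small K) the p-value floor `1/(K+1)` compresses
  `Sp`'s dynamic range; K = 999 is recommended whenever runtime allows.
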