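# nsiasd — network-diffusion prioritization of disease genes

Disease-gene lists produced by independent genome-wide studies of the same
disorder often barely overlap, yet the genes they contain tend to sit close
together in molecular interaction networks. `nsiasd` turns that observation
into a quantitative pipeline: it diffuses weighted seed-gene scores over a
protein-interaction network, ranks every gene by a permutation-adjusted
*network smoothing index*, tests whether the top-ranked genes form a
significantly connected *disease module*, and characterizes the results
with hypergeometric pathway over-representation. It was built with autism
risk-gene lists in mind (several low-overlap lists drawn from CNV, mutation
and curated-database studies) but is agnostic to the disease.

## The model

Given an undirected network with symmetrically normalized adjacency
`W = D^{-1/2} A D^{-1/2}` and a nonnegative seed vector `X0` (positive only
on input genes, e.g. 1 for strong evidence and 0.5 for weaker lists), the
diffusion recurrence

```
X_{t+1} = a·W·X_t + (1 − a)·X0,      X* = lim X_t      (a = 0.7)
```

converges to the unique fixed point `X* = (1−a)(I − a·W)^{-1} X0`. Each
gene g is scored by the network smoothing index and its permutation
adjustment:

```
S(g)  = X*(g) / (X0(g) + eps)
pS(g) = (1 + #{S_k(g) >= S(g)}) / (K + 1)        (K = 999 label permutations)
Sp(g) = −log10(pS(g)) · S(g)
```

The permutation term deflates hub genes that accumulate diffused mass
wherever the seeds are placed. `eps` controls how strongly the inputs
themselves dominate; it can be calibrated automatically so the top-2N
ranking splits 1:1 into input and predicted genes, or fixed at 1 for joint
multi-list prioritization.

Whether the top-m genes form a connected module is tested by network
resampling: the quadratic connectivity score `Omega(m) = Sp(m)' A_m Sp(m)`
is compared with q = 200 degree-preserving rewirings of the induced
subgraph, over a grid of rank cutoffs m; the extracted module is the prefix
where significance is sustained and each added rank chunk still contributes
more connectivity than chance. Pathway over-representation uses upper-tail
hypergeometric probabilities with Benjamini–Hochberg correction (gene-set
sizes 10–200), and significant pathways are linked into an enrichment map
by overlap coefficient (`o > 0.5`, top 5 links per pathway).

Because the original STRING/SFARI inputs are external downloads, the
package ships a synthetic benchmark generator: heavy-tailed networks with a
planted connected module, noisy low-overlap seed lists sampled from it, and
pathway sets partially enriched in the module — every stage is testable
with known ground truth.

## Worked example

```python
import nsiasd as ns

scenario = ns.SyntheticScenario(n_nodes=300, module_size=30,
                                module_edge_density=0.25, n_lists=3,
                                list_coverage=0.4, rng_seed=1)
data = ns.generate_scenario(scenario)
net = data.network

lists = {name: ns.restrict_to_network(genes, net)[0]
         for name, genes in data.lists.items()}
seeds = ns.build_seed_vector(lists, {"list1": 1.0, "list2": 0.5, "list3": 0.5}, net)
scores = ns.score_genes(net, seeds, epsilon=1.0, K=999, rng_seed=3)
print(scores.table.head(5)[["gene", "x0", "x_star", "S", "pS", "Sp"]])

profile = ns.nr_profile(scores, net, m_grid=[20, 30, 40, 50, 60], q=200, rng_seed=4)
module = ns.extract_module(profile, scores, net)
```

Output:

```
network: 300 genes, 606 edges
   gene  x0  x_star      S    pS     Sp
G000173 0.5  0.4702 0.3135 0.001 0.9404
G000114 1.0  0.6188 0.3094 0.001 0.9282
G000053 1.0  0.5725 0.2862 0.001 0.8587
G000154 1.0  0.5719 0.2859 0.001 0.8578
G000095 1.0  0.5697 0.2848 0.001 0.8545
module: m*=30, precision=0.87, recall=0.87
```

The top-ranked genes beat all 999 permutations (`pS = 0.001`), so their
adjusted index is `-log10(0.001)·S = 3S`. Network resampling flags the
top-30 prefix as a significantly connected module; 26 of its 30 genes
belong to the 30-gene planted module. ORA on the module then recovers the
pathways that were generated to be enriched in it (adjusted p ≈ 1e-18 for
the strongest one, against a 300-gene network background).

The same analyses are scriptable from the shell:

```bash
nsiasd simulate --out-dir sim/                      # synthetic benchmark
nsiasd score --network sim/edges.tsv --seeds sim/list1.txt:1.0 \
       --epsilon auto --seed 7 --out scores.tsv
nsiasd module --scores scores.tsv --network sim/edges.tsv --out module.tsv
nsiasd ora --genes sim/list1.txt --gmt sim/pathways.gmt \
       --network sim/edges.tsv --out ora.tsv
nsiasd pipeline --config run.yaml                   # everything, from YAML
```

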