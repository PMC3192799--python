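# stressnet

Stress-induced rewiring of expression-weighted protein–protein interaction
networks: overlapping module detection via a community landscape, and
quantification of how stress changes module overlap, inter-module
connectivity, and bridge proteins.

## The scientific problem

A cell's interactome does not change its wiring diagram on the timescale of
an acute stress response — what changes is how much traffic each interaction
can carry. Approximating protein abundance by mRNA level, each interaction
(i, j) is assigned a condition-specific weight

    w(i, j) = (A(i) + A(j)) / 2,

the average abundance of the interacting partners (a product rule is
available as a variant). The unstressed condition uses baseline absolute
expression; the stressed condition multiplies each baseline abundance by the
gene's stress fold-change ratio. Genes without a measurement are imputed
with the median of the observed values of the same profile. The two weighted
interactomes share every edge and differ only in weights, so all
between-condition comparisons are paired.

On each weighted interactome the package computes:

* **Weighted topology** — the effective (weighted) degree of node *n* is the
  effective number of its incident weights,
  `N_eff(V) = (Σ V_i)² / Σ V_i²`, a scale-invariant continuous count; hubs
  are nodes above the top-1% effective-degree threshold of the unstressed
  network; shortest paths run on costs 1/w (Dijkstra, exact), giving the
  weighted diameter and mean weighted path length; the strongest/weakest 4%
  of links form comparable subnetworks with a darker top/bottom-1% tier.

* **Overlapping modules** — every node spreads a unit of influence by a
  damped random walk with restart (damping α = 0.8); the community
  centrality c(n) sums the influence of all nodes on *n*, forming a
  landscape whose local maxima (over a structurally supported neighbour
  relation) anchor modules. Proportional hill climbing then splits each
  node's centrality among its uphill neighbours in proportion to edge
  weight, giving membership strengths H_i(n) with Σ_i H_i(n) = c(n). No
  module merging is applied.

* **Module-level metrics** — a node's *modular overlap* is the effective
  number of its memberships {H_i(n)}; modules form a coarse-grained network
  with link weights `O_ij = Σ_n 2·H_i(n)·H_j(n)/c(n)`; a module's effective
  degree is the effective number of its links; a node's *bridgeness* sums,
  over adjacent module pairs, the smaller of its two memberships. Per-node
  dynamics between conditions are classified (centrality-change groups A–E,
  bridge classes induced/persistent/decreased) and screened for "bridging
  integrators" whose overlap and centrality rise together.

* **Statistics** — two-sided Wilcoxon signed-rank tests on the paired edge,
  degree, and overlap vectors; a two-sided Mann–Whitney U test on the
  (unpaired) module effective degrees; exact null distributions at small n.

Because the original yeast inputs are large, version-pinned downloads, the
package ships a first-class synthetic generator: planted overlapping
modules (consecutive modules share nodes belonging to exactly two), a
heavy-tailed baseline profile with missing entries, and stress fold-changes
that repress designated ribosome-like modules and induce designated stress
modules, with multiplicative log-normal noise.

## Worked example

`examples/02_detect_overlapping_modules.py` builds two 4-cliques joined by a
shared bridge protein and decomposes the landscape:

```
2 modules, anchored at summits: ['rpl1', 'hsp1']
  bridge  c=0.476  module 0: 50%, module 1: 50%
  hsp1    c=1.205  module 1: 100%
  ...
bridge protein: effective number of modules 2.00 (a 50/50 split counts as 2),
bridgeness 0.238 (the smaller membership summed over adjacent module pairs)
inter-module link weight O_01 = 0.238
```

Each clique forms one hill; the bridge protein sits on the saddle between
them, belongs half-and-half to both modules (modular overlap 2.0), and
carries the entire inter-module link weight — the saddle-point geometry that
the bridgeness measure is designed to detect.

`examples/03_compare_heat_shock.py` runs the full pipeline on a reduced
synthetic heat shock and prints the comparison report (median weight,
weighted diameter and its ratio, effective degrees, hub census, and all four
tests). `stressnet make-demo demo.yaml && stressnet run-all demo.yaml` does
the same from the shell at the bundled ~1000-node scale.

## Layout

`src/stressnet/` — `synthetic` (generators), `io` (readers/writers, physical
-interaction filter, giant component), `weighting` (imputation and the
two-step weight construction), `topology` (effective numbers, hub census,
weighted paths, extreme-link subnetworks), `moduland` (community landscape
and proportional memberships), `metrics` (overlap, O_ij, bridgeness,
dynamics classes), `stats` (tests and the comparison report), `pipeline` +
`cli` (configuration-driven runner). `docs/methods.md` documents the model,
parameter choices and limitations.
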