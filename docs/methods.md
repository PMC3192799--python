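# Methods

## Model and assumptions

The package treats an interactome as a fixed, simple, undirected graph whose
edges carry condition-specific positive weights derived from expression:
stress does not rewire the network on the minutes timescale, it re-weights
it. Protein abundance is approximated by mRNA level, which is defensible for
severe, acute stresses where transcriptome and translatome correlate well;
the weight of an interaction is the arithmetic mean of its endpoints'
abundances (a multiplicative variant is provided). Only the giant component
of the physically supported interaction set is analysed, because shortest
paths and influence spreading are undefined across components. Absolute
(linear) expression values are used throughout; log-transformed inputs can
be exponentiated on read (`from_log2`), and an optional rescaled log weight
transform `w -> log10(1000 w)` is exposed but not the default.

Missing expression values are imputed with the **median** of the observed
values of the same profile — the median rather than the mean because
expression distributions carry extreme right tails — and the number of
imputed network nodes is recorded per profile.

## Community landscape and overlapping modules

Influence of a seed node s is the stationary distribution of a damped
random walk with restart: with probability α the walker steps to a
neighbour chosen proportionally to edge weight, with probability 1−α it
returns to s. The vector f_s is nonnegative, sums to one, and for α < 1 its
maximum sits at the seed. Community centrality sums influence over all
seeds, c(n) = Σ_s f_s(n); by linearity this equals n_nodes times the
stationary vector with a uniform restart distribution, which is how it is
computed (one sparse power iteration, max-norm tolerance 1e-10, iteration
cap with a residual-reporting error). Total landscape mass is therefore
exactly the node count.

**Structural support.** Sporadic single edges between otherwise unrelated
dense regions are a known failure mode of landscape methods: a module's
would-be summit can be annexed by one such edge pointing at a marginally
higher node, deleting the module. The detector therefore distinguishes two
graphs derived from the input: a *reinforced* graph, in which every edge's
weight is multiplied by (1 + common-neighbour count), concentrating the
spread inside cohesive regions while keeping every link; and a *supported*
graph, which drops edges whose common-neighbour support is below half the
median support of both endpoints' edges (a relative rule that adapts to
density and never fires on dyads, stars or trees; nodes that would be
isolated keep their original edges). The landscape and the membership
recursion run on the reinforced graph — so memberships respond to the
weight of every link, including weak inter-module ones — while summit
acceptance (module cores) uses the supported neighbour relation. Every
local maximum of the reinforced graph is also one of the supported graph,
so the hill-climbing invariant below is preserved. `spreading="raw"`
disables both constructions.

**Summits and plateaus.** A node is a module core iff no neighbour (in the
supported relation) beats it in the strict total order (c, node id); on a
plateau the largest id wins, so every plateau yields exactly one core and
the decomposition is deterministic on any input.

**Proportional hill climbing.** Processing nodes by decreasing (c, id), a
core keeps its whole centrality in its own module; every other node splits
its centrality among its uphill neighbours U(n) in proportion to connecting
edge weight, inheriting their already-final module proportions:

    H_i(n) = c(n) · Σ_{j∈U(n)} [ w(n,j) / Σ_{j'} w(n,j') ] · H_i(j)/c(j).

By induction Σ_i H_i(n) = c(n) (enforced at 1e-9); no merging of primary
modules is applied. Module "core proteins" are the top-5 members by
centrality (extendable to 8); "central modules" are those whose summit
centrality exceeds a threshold. The threshold default of 500 matches the
centrality scale of the original yeast-interactome analysis, not this
package's normalisation (mass = node count, mean c = 1): on synthetic
graphs pass a quantile of the observed summit centralities instead.
Absolute centrality values are normalisation-dependent everywhere; only
ratios and orderings are meaningful across implementations.

## Overlap, module graph, bridgeness

A node's modular overlap is the effective number of its membership vector;
the module graph's link weights O_ij = Σ_n 2 H_i(n) H_j(n)/c(n) count both
directions between modules and are consistent with membership carrying
centrality mass (the division by c(n) makes O invariant to the landscape's
overall scale). A module's effective degree is the effective number of its
O links; bridgeness sums min(H_i(n), H_j(n)) over module pairs with
O_ij > 0 in the same condition. Ratios with zero denominators are excluded
from ranked outputs, matching the convention of excluding zero-bridgeness
nodes from bridge dynamics.

Centrality-change groups A–E are an explicit, threshold-parameterised
rendering of what the original analysis drew as free-hand circles; defaults
(t_low, t_high, t_extra) = (1, 100, 1000) and every report states the
thresholds used. Bridge dynamics use the stated cuts: high bridge > 10,
extreme fold flag > 1e5.

## Statistics

Two-sided tests throughout. Wilcoxon signed-rank (paired; zero differences
dropped, at least six informative pairs required, exact null for n ≤ 25,
normal approximation with continuity correction beyond) for edge weights,
effective degrees and per-node overlap; Mann–Whitney U (exact for
min(n) ≤ 20 without ties, tie-corrected normal approximation otherwise) for
module effective degrees, whose module sets differ between conditions. No
multiplicity correction is applied across the report's four tests.
P-values below 2.2e-16 display as "< 2.2e-16".

The type-I calibration of the paired test is run on nulls that satisfy the
test's own assumptions: per run, two exchangeable noisy-weight vectors
(ratio-1 fold changes, multiplicative log-normal noise) over independent
interactions. Exchangeability — not a noiseless-baseline-versus-noisy-draw
design — makes the paired differences exactly symmetric under H0, because
log-normal noise has median one but mean above one. On whole-pipeline nulls
(two neutral draws on one connected graph) the same test is strongly
*conservative* (rejection well below nominal): per-node overlap differences
are anti-correlated through membership-mass conservation. A dedicated test
asserts this direction (never anti-conservative).

## Synthetic data: what it emulates and what it does not

The generator plants `n_modules` blocks of `module_size` nodes in a chain;
consecutive blocks share `overlap_nodes_per_pair` nodes belonging to
exactly two modules. A node splits its intra-module linking propensity
equally among its modules (pairwise probability p_intra/(|M(u)|·|M(v)|) per
shared module), so overlap nodes keep an interior-like degree — shared
proteins have bounded interaction capacity, they do not double it.
Non-sharing pairs link with p_inter; `hub_boost` extra edges on each
module's top-degree node heavy-tail the degree distribution. The bundled
study conditions are 8 modules × 130 nodes, 6-node overlaps,
p_intra = 0.9, p_inter = 0.01 (the detectable-modularity regime used for
all planted-recovery validation), hub_boost = 10 — about a thousand nodes.

Baselines are i.i.d. log-normal with median 0.8 (the scale of absolute
mRNA-level data) and σ = 1, with 8% of genes missing; stress represses the
three "ribosome-like" modules 4–8-fold, induces the two "stress" modules
4–8-fold, leaves the rest at ratio 1, and multiplies every ratio by
log-normal noise (sd 0.2 on the log scale) before dropping 8% of genes.

What the emulation does **not** carry, and the consequence: real expression
is correlated with network position — in unstressed yeast the repressed
ribosomal cluster is simultaneously the highest-expressed, hub-rich,
inter-module connector set, so its repression drains inter-module weight
globally. With module-uniform fold changes and mean-combined weights, a
cross-module edge between modules scaled by r_A and r_B changes by
(r_A + r_B)/2, which is never below the geometric mean of the two intra
scalings (AM–GM): cross-module contacts *relatively strengthen*, and the
effective-number statistic is convex near concentrated memberships, so the
emulated stress tends to *increase* per-node modular overlap. Passing
direction-of-effect tests on global topology (diameter up, hubs down,
weights and degrees down, overlap distribution significantly shifted)
therefore does transfer to real data; the *sign* of the overlap shift under
this emulation does not, and is reported as computed. Emulating the
expression–connectivity coupling would require correlating the baseline
generator with the graph, which its interface deliberately does not do.

## Numerical choices and degenerate inputs

Strength→cost transform for shortest paths is the reciprocal (1/w) by
default — weakening interactions must lengthen paths; `raw` and `neglog`
are hooks. Diameter and path distributions are exact (all-sources Dijkstra
on a sparse cost matrix); disconnected inputs raise an error naming the
giant-component remedy. Hub thresholds and extreme-link fractions are
rank-based with (value, id) tie-breaks and exclusive thresholds. Zero
edge weights are rejected at construction, not dropped. Equal-seed runs are
bit-identical end to end; the pipeline derives one child seed per stage
from the run seed via `numpy.random.SeedSequence`.

## Problem sizes

Validation uses 4 × 30-node planted graphs (module recovery, 20 + 40
seeds), graphs ≤ 50 nodes against a Bellman–Ford all-pairs oracle (200
graphs), ~1000-node emulations for direction-of-effect (20 seeds), and 400
small null runs for test calibration.

## Known limitations

Identifier matching between expression tables and the interaction network
is the caller's responsibility (opaque case-sensitive strings; no alias
resolution). The influence rule is one concrete member of the family of
damped, weight-proportional spreading functions; α and the spreading mode
are exposed. Protein half-lives, translational efficiency and measured
protein abundances are out of scope. The landscape export provides
coordinates for external 3D rendering but no plotting.
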