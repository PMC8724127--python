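# Methods

This note documents the models, conventions and numerical choices behind
`hubrank`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Network model and measures

A connectome is a symmetric, hollow, non-negative weighted adjacency matrix
over a shared ROI index. Edge weights follow the streamline-count formula

    w_ij = n_ij * (1 / L_ij) * (2 / (V_i + V_j))

with `n_ij` the streamline count for the unordered ROI pair, `L_ij` the
mean streamline length in mm (deterministic tractography produces
proportionally more false positives among long fibers, hence the 1/L
correction) and `V_i, V_j` the ROI voxel counts (a residual size
correction after sub-parcellation). Streamlines with both endpoints in the
same ROI are dropped: the formula is pairwise and the matrix hollow.
No weight threshold is applied anywhere; the binary graph places a unit
edge wherever the weighted graph has strictly positive weight.

The five node measures are: **degree** and **strength** (row sums of the
binary and weighted matrix), **coreness** (k-core number), **betweenness**
and **closeness**, the latter three on the *binarized* graph since their
definitions here are in terms of unweighted shortest paths. Betweenness is
normalized by the number of eligible pairs `(n-1)(n-2)/2` with endpoints
excluded, so it reads literally as the *fraction* of shortest paths through
the node and lies in [0, 1]. Closeness is the reciprocal of the summed BFS
distances; on disconnected graphs it is computed over the node's reachable
set and scaled by `(r-1)/(n-1)` (Wasserman–Faust component scaling, `r` =
reachable-set size), with isolated nodes assigned 0 and a warning emitted
— connectedness is implicitly assumed by the closeness definition, and the
scaling is the standard way to keep scores comparable across components.
The heavy graph algorithms are igraph's C implementations; the test suite
checks them node-for-node against naive brute-force re-implementations
(iterative peeling, exhaustive BFS path counting) and against networkx.

## Ranking, Spearman, hubness

Nodes are ranked per measure with rank 1 for the largest value; ties
receive average (fractional) ranks, the statistical convention that keeps
the rank sum at `n(n+1)/2`. Rankings are compared with Spearman
correlation; the closed form `1 - 6 Σd²/(n(n²-1))` is exact only without
ties, so the implementation uses the product-moment correlation of the two
rank vectors, which coincides with the closed form in the tie-free case
(unit-tested). Correlation with a constant vector is undefined and returns
NaN.

The composite **hubness** score of a node is the equally weighted mean of
its five measure ranks (lower = more hub-like); per-measure weights are
exposed for sensitivity analyses but equal weighting is the default and the
convention used throughout. The hubness *ranking* ranks scores ascending.

## Group aggregation

**ATM** averages the weighted matrices elementwise and ranks the measure on
the aggregate; the aggregate's binary graph keeps every edge with positive
mean weight (the union graph). Because the union densifies with population
size, an optional edge-prevalence threshold (keep an edge only if present
in ≥ f of subjects) is available, but the strict-positivity rule is the
default. **MTA** ranks nodes within each subject and averages the ranks per
node; the group score is kept as the raw mean of ranks rather than
re-ranked, since Spearman comparisons are invariant to the monotone
re-ranking except under ties.

**Representation power** of a group ranking is its mean Spearman
correlation with the subjects' own rankings. When a group ranking is
constant — the ATM union graph can make coreness identical across all
nodes — its correlation is undefined; the implementation records 0 for
such subjects (a constant ranking carries no node-ordering information)
and warns. On zero-noise populations ATM and MTA coincide and both have
representation power exactly 1.

## Sub-parcellation

Parcels are split into `k = n_voxels // 400` ROIs (k = 1 below 400 voxels)
by k-means on voxel center coordinates in mm: k-means++ initialization, 10
restarts, 300-iteration cap, squared-Euclidean objective, seeded per parcel
so results are independent of parcel processing order. Cluster ids are
relabelled in lexicographic centroid order for stability. Empty-cluster
events are handled by scikit-learn's internal relocation. k-means Voronoi
cells are contiguous for convex parcels but not guaranteed in general, so
contiguity is audited (connected-component count per ROI) and reported as
a warning rather than enforced.

## Downstream analyses

- **Sample-size curves**: for each sample size, subject samples are drawn
  without replacement (independent across the 100 default replicates), the
  sample's MTA hubness ranking is correlated with the full population's.
  The default size grid is {1, 2, 5, 10, 20, 50, 100, 200, 500, 1000}
  truncated at the population size.
- **Consistent hubs**: per measure, the `floor(q*n)` best MTA scores (ties
  at the threshold included, which keeps the set monotone in q); the hub
  set is the intersection over the five measures.
- **Parcel-level ranks**: sub-parcellation does not align ROIs across
  hemispheres, so interhemispheric comparisons use parcels, each summarized
  by the *median* of its ROIs' hubness ranks (even-count medians are
  midpoints of the central pair).
- **Hemispheric asymmetry**: per homologous pair, paired differences of
  left and right parcel median ranks across subjects are tested with a
  two-sided Wilcoxon signed-rank test (scipy's exact method for small
  samples without ties; a paired t-test is available via config). A pair is
  called dominant on the side with better (lower) ranks iff p < 0.01 *and*
  the absolute mean difference exceeds a margin of 5% of the total number
  of ranked units (the node count for ROI-rank medians; passed explicitly,
  defaulting to the rounded table maximum as a lower-bound estimate of the
  scale). No multiple-testing correction is applied by default, matching
  the raw per-parcel p < 0.01 convention for this analysis. Type-I error on
  a symmetric null is verified in the tests to stay within alpha plus
  Monte-Carlo error.
- **Intraparcel heterogeneity**: per-parcel min/max/median/IQR of
  group-level ROI hubness rank scores, plus the Spearman correlation of
  parcel median rank with parcel spread and (when an asymmetry report is
  supplied) with asymmetry magnitude.

## Synthetic population generator

The generator emulates the statistical structure the analyses assume: a
population of symmetric, hollow, non-negative subject matrices sharing a
common hub architecture, with inter-subject variability in both weights and
topology.

Construction. The base connectome is a stochastic block graph with one
block per parcel: within-parcel density is 3x the baseline (0.1 by
default), interhemispheric density 0.5x. The left hemisphere is generated
and mirrored to the right with a symmetric interhemispheric block, so
homologous nodes are statistically identical — a convenient exact null for
the asymmetry analyses. A fraction of nodes (10% by default, chosen on the
left and mirrored) are hubs: their incident edge probabilities and weights
are multiplied by `hub_weight_boost` (3 by default), so hubs stand out in
degree-like measures and strength alike. Edge weights are lognormal
(sigma 0.5 on the log scale).

Planted effects. `asymmetry_effects` scales the incident *weights* of the
left-hemisphere nodes of chosen parcels by a factor delta; each edge is
scaled once, by the endpoint deviating most from 1, so a parcel's left
mean strength scales by approximately delta relative to its right homolog.
`heterogeneity_slope` imposes a centered linear within-parcel gradient of
expected connectivity — node gain `1 + slope*(position - 1/2)`, |slope| <
2, applied to both edge probability and weight and mirrored across
hemispheres. Centering matters: an uncentered gradient lifts the whole
parcel into the saturated top of the rank distribution, where rank spread
*shrinks*; the centered gradient spans below- and above-average nodes and
therefore widens the parcel's rank spread, which is what the heterogeneity
analysis is designed to detect.

Subject noise. Each subject matrix is the base times i.i.d. elementwise
lognormal noise (sigma 0.5 by default), after which each node pair's edge
presence is independently toggled with probability 0.05 (new edges drawn at
the base weight scale). Defaults (50 subjects, 200 nodes) are the standard
test-bed used across the experiments; 0.5/0.05 produce clearly noisy but
recognizably shared architecture. All randomness flows from one seed
through per-subject `SeedSequence` substreams, so populations are bitwise
reproducible and with zero noise every subject equals the base exactly.

What the generator does *not* emulate: spatial embedding and
distance-dependent connectivity, realistic tractography biases (the 1/L
correction's upstream cause), cortico-subcortical connections, and any
calibration to empirically observed inter-subject variability — there is no
quantitative model of that variability to calibrate to. Passing tests
therefore demonstrate correctness and qualitative behavior of the methods
(e.g. the MTA-over-ATM ordering, curve shapes, planted-effect recovery),
not quantitative agreement with human-population values, which depend on
the real data.

The streamline generator inverts the weight formula: per edge it draws a
mean length uniformly from the length range, emits
`round(count_scale * w * L * (V_i+V_j)/2)` constant-length records (at
least 1), so rebuilding recovers `count_scale * w` exactly up to integer
rounding. `count_scale` trades table size against rounding error; at the
default ROI size of 400 voxels, a scale giving per-pair counts of order
100 keeps the strength-ranking round trip above 0.99 Spearman.

## Problem sizes

The experiments are sized for interactive use: representation-power
comparisons run over 10–20 populations of 50 subjects x 200 nodes;
sample-size curves over a 100-subject population with 100 replicates per
size; asymmetry recovery over 100 parcel pairs x 50 subjects; oracle
equivalence over 100 random graphs of up to 50 nodes. These sizes give
Monte-Carlo errors far smaller than the effects being demonstrated.

## Known limitations

- Contiguity of k-means ROIs is audited, not guaranteed.
- The closeness component-scaling convention, while standard, is one of
  several; rankings on connected graphs are unaffected.
- The asymmetry margin's scale (fraction of ranked units) must be supplied
  by the caller for exactness; the fallback inferred from the table
  maximum slightly underestimates it.
- ATM's default union binarization densifies with population size; use the
  prevalence threshold for very large populations if an interpretable
  aggregate topology matters.
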