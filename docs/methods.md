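# Methods

## Problem setting

`netseed` locates regions of a protein–protein interaction (PPI) network
that are significantly enriched in disease-associated "seed genes" drawn
from heterogeneous evidence sources (expression signatures, SNP
associations, drug targets, curated disease genes), and tests how closely a
focal gene set — e.g. the 9-gene AMP-activated protein kinase (AMPK) core —
is related to those seeds. The package implements four stages: rank-based
expression signatures, consensus module detection with seed enrichment,
hypergeometric term enrichment, and network-proximity statistics with
uniform-sum p-value combination. A synthetic-data module generates inputs
with known ground truth so each stage is testable without downloads.

## Network scaffold

The analysis universe is the giant component of a simplified (no
self-loops, no duplicate edges) undirected gene-symbol graph, loaded from a
two-column TSV edge list. Gene symbols are upper-cased on load because
interaction databases and seed lists mix cases. Ties between equal-size
largest components are broken in favour of the component containing the
lexicographically smallest symbol, for determinism. Seed genes absent from
the network are dropped (and counted in the log) before any test: the
hypergeometric universe is the network node set, so absent genes cannot
participate.

## Expression signatures

For each brain region (or any condition stratum), case profiles are divided
by the mean of that region's control profiles, each ratio profile is ranked
from most to least expressed (average ranks on ties), ranks are summed per
region, and genes are re-ranked by rank sum. The top *k* and bottom *k*
genes form the region signature; the default half-length is k = 125,
chosen as the length that gives a well-separated sample map while staying
small relative to an array's probe count. Because only within-sample ranks
enter after the control division, the procedure is invariant to any
positive per-sample rescaling (asserted by test).

The sample map connects per-sample signatures (top-k/bottom-k of a single
ranked profile) whose pairwise distances are in the smallest
`edge_fraction` (default 20%) of all pairs; ties at the cutoff break by
lexicographic pair order. The distance between two signatures is the
signed-overlap distance `1 − (|up∩up| + |down∩down|)/(2k)`. The original
map method's distance is defined in work we do not re-derive here; the
signed-overlap form is this package's default and the metric is pluggable
(`signature_map(..., metric=...)`). A probe→gene collapse (keep the
max-mean probe) is provided as an optional pre-step; by default rows are
used as given.

## Consensus reference modules

Module detection uses igraph's spinglass Potts-model heuristic
(`community_spinglass`, backend parameters at igraph defaults), run
`n_runs` times (default 100) with run *r* seeded `base_seed + r`. The
backend is pluggable; any modularity-maximising partitioner with the same
call signature can be substituted. Since the heuristic's output varies
between runs, per-run modules are consolidated:

1. **Per-run enrichment.** Every module of size ≥ 2 gets an upper-tail
   hypergeometric test (universe N = network size, K = seeds, n = module
   size, k = seeds in module); modules with p ≤ α (default 0.05, unadjusted
   — one decision per test, matching standard multi-run practice; BH across
   modules is available in `enrichment_stats` but off by default) are kept.
   Size-1 modules are excluded because a one-draw test is degenerate.
2. **Size grouping.** Enriched modules are grouped with Sturges histogram
   bins: `ceil(log2(m)) + 1` equal-width right-closed bins over
   [min size, max size], the minimum joining the first bin. The rule is
   documented bit-exactly here rather than emulating any specific
   histogram library's "pretty" break placement.
3. **Greedy merging.** Within a group, the overlapping pair with the
   largest Jaccard overlap is repeatedly considered; the union is accepted
   iff it is still significantly enriched at α and induces a connected
   subgraph. A rejected pair is never retried; disjoint modules are never
   merged. Pair ordering (largest Jaccard first) is this package's
   decision; the accept/reject rule itself fixes only the outcome per pair.
4. **Cross-group consolidation.** The same greedy pass is applied once more
   across group results: the size bins are a pre-ordering heuristic, and
   the same underlying community found at sizes 29 and 30 in different runs
   would otherwise be reported twice when a bin boundary separates them.

A reference module is therefore a connected, significantly seed-enriched
node set with the union of all genes and interactions the contributing runs
support, plus provenance (which run and module index contributed). If a
candidate's induced subgraph is disconnected (possible for raw partition
modules), it is split into connected components and only significant
components of size ≥ 2 are kept, preserving the connectedness contract.

The partitioning stage does not depend on the seed lists, so one set of
partitions is shared across all seed-list combinations in a run; this also
makes null-calibration experiments (resampled seed lists on fixed
partitions) cheap.

## Enrichment statistics

The upper-tail hypergeometric p-value P(X ≥ k) is evaluated through
scipy's survival function; tests verify it against exhaustive enumeration
for every valid query with N ≤ 12. Benjamini–Hochberg adjustment is the
standard step-up procedure (via statsmodels), verified against a hand
implementation. Term enrichment runs one hypergeometric test per term of a
GMT-style map, BH-adjusts across terms, reports both raw and adjusted
p-values, and flags terms at the raw threshold α = 0.001 (the conventional
strict cutoff for ontology term reporting); the background defaults to the
set of annotated genes and is configurable. Discrete-test conservatism is
accepted; no mid-p option. Ontology-graph propagation and semantic
redundancy pruning are out of scope.

## Focal-set statistics

Three analyses, with the AMPK core (PRKAA1/2, PRKAB1/2, PRKAG1/2/3, ACACA,
ACACB) as the motivating focal set:

1. **Frequency.** A node's count is the number of reference-module
   collections containing it. Focal vs non-focal counts are compared with a
   one-sided Wilcoxon rank-sum test, exact by full enumeration of group
   assignments (midranks on ties) when C(n1+n2, n1) ≤ 50 000, else the
   tie-corrected normal approximation. Shapiro–Wilk p-values for both count
   distributions are reported as diagnostics only; the non-parametric test
   is always used, avoiding an unspecified normality decision rule.
2. **Neighborhood enrichment.** The closed neighborhood (core + direct
   neighbors) is tested for enrichment in each seed list and their union,
   BH-adjusted across the tested rows.
3. **Distance null.** Each focal node's shortest-path distances to the
   seeds are summarised either as per-node means ("avg": one statistic per
   focal node) or as the full focal×seed distance vector ("all"). For each
   of `n_resamples` (default 1000) random subsets of non-seed, non-focal
   nodes of matching size, the matched statistic vector is computed and
   compared with a one-sided Wilcoxon test (focal shorter). Equal-length
   vectors use the signed-rank test paired by position (zeros dropped, the
   classic convention; an all-zero difference vector scores 0.5);
   unequal-length vectors fall back to rank-sum. The signed-rank p is exact
   (dynamic programming over rank subset sums) when there are no ties among
   absolute differences and ≤ 25 informative pairs, else the tie-corrected
   normal approximation with continuity correction — mirroring R's
   `wilcox.test` conventions. "avg" averages over seeds per focal node, so
   the focal vector has exactly one entry per focal node.

The per-resample p-values are combined through the uniform-sum null: under
H0 they would be Uniform(0,1), so their sum S has mean n/2 and variance
n/12; the combined p is the lower tail Φ((S − n/2)/√(n/12)) (default) or
the exact Irwin–Hall CDF

    F(x) = (1/n!) Σ_{k=0}^{⌊x⌋} (−1)^k C(n,k) (x−k)₊ⁿ.

The alternating sum cancels catastrophically in floating point, so terms
are accumulated in arbitrary-precision arithmetic sized to the worst-case
term magnitude (≈ 30 digits for small n, a few hundred at n ≈ 1000);
correctness is checked against an independent reference distribution, a
10⁶-draw Monte-Carlo oracle, the symmetry identity
F(n/2+t) + F(n/2−t) = 1, and the normal limit.

### Limits of the combination step

The combination treats the n_resamples p-values as independent, but they
all condition on the one observed focal set: if the focal set happens to be
slightly closer (or farther) than typical, *every* resample p-value shifts
together. The sum's variance is therefore n·Var(p) + n(n−1)·Cov(pᵢ,pⱼ)
with strictly positive covariance, and under an exchangeable (null) focal
set the combined p is strongly overdispersed — close to a 0/1 mixture
rather than uniform (measured in this package's calibration experiment:
KS-vs-uniform p ≈ 10⁻²⁹ over 200 exchangeable replicates). The combined p
should therefore be read as a *score* that orders focal sets by proximity,
not as a calibrated tail probability; very small values are necessary but
not sufficient evidence. The per-resample p-values and the Shapiro–Wilk
diagnostics are returned so users can inspect the full distribution. This
is a property of the published combination design itself; the package
implements it faithfully and documents the caveat.

## Synthetic data and what it does (not) show

- **Planted-partition networks** (equal edge probability within modules
  p_in, between modules p_out; no degree correction): the simplest model a
  modularity partitioner provably separates. Gene names are `G0001…` with
  module membership only in metadata, so no string-ordering artifact can
  leak ground truth into rank-based stages. Real PPI networks are
  scale-free with hubs; degree-corrected generation is deliberately out of
  scope, so recovery rates here do not predict recovery on real networks.
- **Seed lists**: Bernoulli sampling at rate q_in inside designated disease
  modules, q_out elsewhere — an evidence source concentrated in, but not
  confined to, disease-relevant modules.
- **Expression**: per-gene lognormal baselines shared across samples;
  case samples of a region multiplied by 2^(±log2_effect) on that region's
  planted up/down genes; multiplicative log2-scale noise. Defaults (12
  cases, 12 controls per region, log2_effect 2, noise_sd 0.1) mirror a
  small multi-region case/control brain study. Probe multiplicity, batch
  effects and array-specific noise are not modelled.
- **Annotations**: random gene sets plus one planted term copied verbatim
  from a chosen module, so term enrichment must rank it first.

## Problem sizes and numerical choices

The synthetic study uses a 3×30-node planted network (p_in 0.3, p_out
0.01), seed rates q_in 0.5 / q_out 0.02, 20 consensus runs (20 runs
saturate consensus on a 90-node, 3-module network; the 100-run default is
kept for real networks), 20 replicates for recovery medians, 500 seed-list
replicates for the type-I calibration (q = 0.2 on both sides, chosen so the
discrete test's achievable levels are reasonably dense), 2000 replicates
for the combination calibration and 200 for the distance-null calibration
on a 3×100-node network. All generators and the whole pipeline are
bit-reproducible given their seeds; spinglass runs are seeded
`base_seed + run`.

Known limitations: no identifier remapping (matching is on normalised
symbols only); unweighted, undirected networks only; the signature-distance
metric is a stand-in (see above); the combination step's calibration caveat
above.
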