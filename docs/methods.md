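# Methods

## Model and procedure

The pipeline treats disease progression as an ordered sequence of stages
with unpaired sample groups. Its unit of inference is the *stage
transition*: each adjacent pair (earlier, later) is compared gene-by-gene
with a two-group one-way ANOVA on log2 intensities. For two groups the F
statistic on (1, n₁+n₂−2) degrees of freedom equals the square of the
pooled-variance t statistic; the asymptotic p-value comes from the F
distribution. Family-wise error is controlled per comparison by Bonferroni
over the m genes of the matrix (p_adj = min(1, m·p)); the alternative of
pooling the correction across all transitions is not implemented because
each comparison is an independent family here, but the per-gene tables
expose raw p-values so any other correction can be applied downstream.

Fold change is the ratio of arithmetic group means after back-transforming
the log2 values to the linear scale (later over earlier). Selection
requires p_adj < α and fold change ≥ threshold (up) or ≤ 1/threshold
(down). The default threshold of 1.0 makes the fold-change filter purely
directional: between adjacent disease stages expression shifts are small,
and a 2-fold cutoff empties the inter-stage sets, so significance plus
direction is the operative rule. The threshold remains a config knob.

The trajectory screen is pure set algebra. With direction-matched selection
sets S₁…S_K ordered by the transition sequence, C_k = ∩_{j≤k} S_j is the
continuing set at stage k and D_k = C_k \ C_{k+1} the deviated set
*attached to the earlier stage k* of the k→k+1 transition. This attachment
convention is enforced everywhere (truth tables, reports, node
annotations): a published row "357 continuing at stage I, 115 deviated"
means |C_I| = 357 and |C_I| − |C_II| = 115. The disjoint-union identity
|C_k| = |C_{k+1}| + |D_k| is re-verified before any count table is emitted.
The two directions are screened independently; a gene whose sign flips
simply leaves both continuing tracks.

Compartment filtering intersects every continuing set with the genes
carrying at least one of a compartment's GO cellular-component terms
(defaults: extracellular matrix GO:0031012 + extracellular space GO:0005615
for the up direction, mitochondrion GO:0005739 for the down direction).
Because intersection distributes, filtering the continuing sets equals
filtering the selection sets first.

Enrichment of each deviated set is the one-sided hypergeometric upper tail
P(X ≥ k) for X ~ Hypergeom(N, K, n) per biological-process term, with the
background universe restricted to genes present in both the annotation and
the expression matrix (an unrestricted background would inflate
enrichment). Bonferroni across tested terms is the default, matching the
correction philosophy of the differential screen; Benjamini–Hochberg is
available. Annotations are taken as flat gene→term pairs; ontology-graph
propagation (true-path rule) is out of scope.

Network analysis reads STRING detailed-scores edge tables, keeping edges
whose chosen evidence channel (default `experimental`) has a positive
score — a conservative "experimentally supported only" graph. The
complex detector re-implements the classic molecular-complex-detection
scheme: vertex weight = k·density of the highest k-core of the closed
neighborhood; seeds are visited in descending weight; neighbors join while
their weight ≥ seed_weight·(1−VWP); each vertex belongs to at most one
complex; complexes without a 2-core are discarded; haircut (default on)
iteratively strips degree-1 members; fluff (default off) adds dense outside
neighbors. Defaults (VWP 0.2, haircut on, fluff off, 2-core minimum) are
the plugin's published defaults. Density is simple-graph density
2E/(V(V−1)) without self-loops. Modules rank by score = density × size,
ties by size, then seed id.

The hub subnetwork collects nodes whose *parent-graph* degree lies in a
configured range (the published analysis used 8–18 and 8–19 on its real
networks). The "key chain" replaces a manual hierarchical-layout reading
with a reproducible criterion: the simple path in the hub subgraph
maximizing the sum of parent degrees, found by exhaustive branch-and-bound,
with ties broken toward longer paths and then the lexicographically
smallest sequence. The search is guarded to ≤ 25 hub nodes; the end-to-end
driver records a note (rather than failing) when the guard trips or the
hub set is empty, while the standalone operation raises. The chain is a
deterministic re-interpretation of a visual step and is reported as a
descriptive artifact, not a tested quantity.

## Synthetic data

The generator emulates a microarray-scale cohort: baseline log2 intensity
per gene ~ Normal(8, 1.5); homoscedastic Gaussian noise (default SD 0.5) on
the log2 scale; seven stages with sample counts (54, 28, 50, 49, 58, 47,
20). Genes are allocated to classes (default 10% continuously up, 10%
continuously down, 80% null) by largest-remainder rounding, so class counts
are exact. A trending gene gains ±1.5 log2 units (the default effect) at
every transition up to its drop stage d (uniform over 1..K by default) and
is flat afterwards, so a perfect screen places it in D_d; d = K means the
gene persists through the last stage. Annotations plant compartment labels
(P = 0.8 for the matching class, 0.1 background) and class-linked
biological-process terms (0.6 vs 0.05). Interaction tables plant disjoint
near-cliques among non-null genes (default 3 modules of 6 at edge
probability 0.9) over an Erdős–Rényi background (default 0.01), with
integer channel scores in STRING's 0–1000 convention and a noisy-or
combined score. All randomness fans out from one top-level seed by
per-stage name hashing, so identical (parameters, seed) reproduce every
file byte-for-byte.

What the generator does **not** emulate: probe-level structure and
probe-to-gene collapse, normalization artifacts, batch effects,
heteroscedastic or intensity-dependent variance, correlated genes outside
planted modules, annotation incompleteness bias, and scale-free topology of
real interactomes. Passing recovery tests therefore demonstrates that the
screen's logic is correct under its own assumptions, not that those
assumptions hold in any particular cohort.

## Numerical choices and degenerate inputs

- Zero pooled variance with equal means is defined as (F = 0, p = 1);
  with distinct means as (F = ∞, p floored at the smallest positive
  double). p-values are never reported as exact 0.
- Fold change exactly 1 has direction "none" and is never selected.
- Effect 0 is a valid generator setting (global null); negative effect or
  non-positive noise SD are parameter errors.
- Gene sets are serialized sorted; module and hub orderings have total,
  deterministic tie-breaks; floats are written with 10 significant digits
  so write→read→write is byte-stable.

## Problem sizes used in validation

Recovery checks run the full screen at the design's real sample sizes
(306 arrays) with 500 genes per replicate over 10 seeds; null-calibration
of the family-wise error rate uses 2,000 simulated 40-gene datasets; the
complex detector is checked against an independent peeling-based core
decomposition on 100 random graphs up to 200 nodes and against planted
6-cliques in 500-gene backgrounds over 20 seeds. These sizes were chosen to
make Monte-Carlo error small relative to the asserted margins.

## Replication limits

Absolute genome-wide counts reported for the original cohort (e.g. 3,968
genes up-regulated at stage I of GSE41258) depend on the accession's probe
curation and preprocessing, and hub degrees (e.g. FN1/MMP2 at degree 18)
depend on the interaction database version; neither is recoverable from a
synthetic or down-scaled setting, so they are documented here as context
and are not test targets. The per-stage *deviated* counts, by contrast,
are pure arithmetic consequences of the published continuing counts and
are reproduced exactly by `scripts/acceptance.py`. Whether the published
signal chains are optimal under any formal criterion cannot be determined
from the text; the key-chain operation defines one.
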