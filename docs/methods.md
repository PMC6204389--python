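# Methods

`coexnet` re-implements, as a tested library, a weighted gene co-expression
workflow for fungal RNA-seq of the kind used to study *Trichoderma reesei*
growing on plant biomass: count preprocessing, signed network and module
inference, dense-subcluster and hub detection, hypergeometric functional
enrichment, and position-weight-matrix (PWM) prediction of Xyr1-binding
sites (XBS) in promoters. This note records the models, the parameters that
matter, the synthetic data the tests run on, and the design choices made
where the procedure was genuinely open.

## Expression preprocessing

Raw gene-level counts are filtered on counts-per-million computed from raw
library sizes: a gene is kept if CPM >= 1 in at least 3 samples (both
configurable). Between-sample normalisation is the trimmed mean of M-values
(TMM), re-implemented rather than called: per-gene log2 ratios against a
reference sample are trimmed 30% on M and 5% on average intensity, averaged
with inverse asymptotic binomial-variance weights, and the resulting factors
are rescaled to geometric mean 1. The reference sample is the one whose
upper-quartile of scaled counts is closest to the mean upper quartile. Genes
with a zero count in either member of a pair are excluded from that pair's
trimmed mean. The implementation is cross-checked in the tests against
edgeR's `calcNormFactors`.

Expression is reported as RPKM on TMM-effective library sizes:
`count / (libsize * factor / 1e6) / (length / 1e3)`.

Differential expression against the control condition is a pure fold-change
rule: `log2fc = log2((mean_t + c) / (mean_control + c))` on normalised
condition means with pseudocount c = 0.25 guarding zero denominators; a gene
is up at a time point if log2fc >= 1, down if <= -1, and its overall status
is up/down if any time point qualifies (mixed if both directions occur).
No dispersion estimation or significance testing is attempted — the
criterion of record is the two-fold cutoff.

## Signed network and modules

Pairwise Pearson correlation is computed across samples; in the assembled
pipeline (CLI and tests) the correlation input is `log2(RPKM + 1)`, the
standard variance-stabilised scale for co-expression work. Zero-variance
genes receive correlation 0 with a warning rather than being dropped.

The signed adjacency is `adj = (0.5 * (1 + cor))^beta`, mapping correlation
-1 to 0 and +1 to 1 so anti-correlated genes are weakly connected. The
softpower beta is chosen as the smallest candidate in 1..30 whose scale-free
topology fit reaches signed R^2 = 0.85: connectivity `k_i = sum_j adj_ij` is
binned into 10 equal-width bins and log10 frequency is regressed on log10
mean connectivity, with signed R^2 = -sign(slope) * R^2. If no candidate
reaches the target, the maximiser is used with a warning (typical for small
synthetic designs).

Topological overlap is
`TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)` with
`l_ij = sum_u a_iu a_uj`; the tests verify it against a literal triple-loop
evaluation. Modules come from average-linkage hierarchical clustering on
1 - TOM with a static height cut; clusters below 30 genes become background.
Modules whose eigengenes (first principal component of the standardised
module expression, oriented so the mean gene-eigengene correlation is
positive) are closer than dissimilarity 0.15 (correlation > 85%) are merged
iteratively, closest pair first, the merged module keeping the larger
constituent's label. The comparison is strict: a dissimilarity of exactly
0.15 does not merge.

**Cut height.** The cut procedure behind the published module count is not
specified beyond `hclust ("average")`, so a deterministic static cut is
used, with the default height set to 0.97 of the maximum merge height.
The rationale is the shape of the merge-height distribution when a
background of uncorrelated genes is present: coherent modules complete low,
while merges that attach background genes and join module pairs crowd into
a dense band just under the maximum height. A cut placed inside that band
(e.g. at a high quantile of merge heights) lets background accrete into
modules; a fraction of the maximum sits reliably below it. A module split
by a conservative cut is re-united by the eigengene merge stage. Dynamic
tree cut is deliberately not implemented.

Exported edges are within-module gene pairs with |cor| strictly > 0.8,
annotated with the correlation and the signed adjacency (0.064 at cor 0.8,
beta 26). Anti-correlated pairs qualify via the absolute value even though
the adjacency is signed — both conventions are implemented exactly as used.

## Subclusters and hubs

MCODE is re-implemented from its published definition. Vertex weight = order
k of the highest k-core of the node's closed neighbourhood times that
core's density. Complexes grow outward from unvisited highest-weight seeds
(ties broken lexicographically for determinism), admitting neighbours whose
weight strictly exceeds `(1 - node_score_cutoff) * seed_weight`, bounded by
`max_depth`; complexes lacking a 2-core are discarded and the haircut
iteratively strips singly-connected members. Defaults are degree cutoff 2,
node score cutoff 0.2, K-core 2, max depth 100, haircut on, fluff off. Note
that two dense regions joined by a bridge edge whose endpoints share the
seed's weight are grown into a single complex — a direct consequence of the
growth rule, confirmed in the tests by an independent step tracer.

Hubs are nodes whose degree strictly exceeds the nearest-rank 90th
percentile of their module's degree distribution ("higher than 90% of the
degree distribution"); the per-module reading is the default because hub
counts are reported per module set, and a global-distribution mode exists
behind a flag. Modules with fewer than 10 nodes yield no hubs. Unnormalised
shortest-path betweenness (Brandes, via networkx) is reported alongside and
its Pearson correlation with degree is a diagnostic only — hubs are not
filtered on it.

## Enrichment

Over-representation uses the hypergeometric upper tail
`P(X >= k)` for k query hits of a K-gene term in an n-gene query against an
N-gene background, with Benjamini-Hochberg adjustment across the tested
terms (those with at least one query hit). GO mode calls significance at
q <= 0.05 and skips queries below 10 genes (the subcluster rule); KOG mode
requires raw p <= 1e-3 and q <= 0.05 and uses all annotated genes as
background. Annotations are assumed pre-propagated to ancestor terms; no
ontology parsing is performed, so the statistical core stays exact while
the ontology file is a data concern.

## Promoters and binding-site prediction

Promoters are the 1.5 kb immediately upstream of the start codon: for a
plus-strand gene with ATG at position s, the genomic window
[max(1, s-1500), s-1]; for a minus-strand gene with ATG at CDS end e, the
window [e+1, min(contig_end, e+1500)] reverse-complemented. Truncation at
contig ends is flagged.

A PWM is built from aligned site sequences or a 4 x width count matrix with
a background-proportional pseudocount: cell (b, j) receives
`pseudocount * 4 * background_b` extra observations (one per cell under a
uniform background), giving frequencies `(c + 1)/(n + 4)` in the uniform
default. Log-odds are in bits against the background (default: 0-order
composition; uniform in the synthetic setting, where the null is then
analytically checkable).

The null distribution of the window score is computed exactly: full
enumeration over 4^w words for widths up to 8, otherwise a positionwise
convolution on a score grid of 1e-3 bits. The distribution carries its own
resolution (half the accumulated bin width) so that exact window scores map
onto the correct probability mass; p-value lookups and the scan cutoff
tolerate that resolution, which keeps every reported hit at p <= the scan
threshold. Windows containing N are skipped entirely. Both strands are
scanned (the reverse strand via the reverse-complemented matrix, with its
own null distribution when the background is asymmetric). Hit offsets
follow the convention that -1 is the base immediately upstream of the ATG
and a hit's offset is the 5'-most base of the matched window on the gene's
sense orientation, for either strand of the match.

## Reports

The module summary counts nodes, within-module exported edges, and up/down
DEGs per module, with percentages taken against the transcriptome-wide DEG
totals supplied by the caller, rounded half-up to one decimal; the total
row recomputes its percentages from the summed counts (summing the rounded
per-module percentages is not reproduced — the direct computation is
printed). The hub cross-tab reports each hub set's DE share (nearest
integer percent) and, among the DE hubs, the share with at least one
predicted binding site (one decimal). The focal-gene neighbourhood report
lists all genes sharing an exported edge with a focal regulator,
cross-tabulated with DE status, binding-site presence and caller-supplied
functional classes (CAZyme, transporter, TF, ...); signal-peptide or family
prediction is out of scope.

## Synthetic data

The generator emulates the study design: 4 conditions (an inert control
sugar at 24 h; an inducing substrate at 6, 12, 24 h) x 3 replicates,
~1,200 genes of which six planted modules of 100 genes (two induced, two
repressed, two condition-independent) sit on a 600-gene background. All
randomness flows from one seeded generator through deterministic
substreams; identical configs give identical outputs.

Each module has a latent per-sample log2 profile: a condition effect of
+/- log2(de_fold) on substrate samples (de_fold defaults to 4) plus a
module-specific noise vector with per-sample sd tau = 1.2. The noise is
centred within every condition group, so the planted condition contrast is
exact at the latent level, and the noise vectors are orthogonalised across
modules so that distinct planted modules remain mutually distinguishable at
the design's 12 samples — with independent draws, sampling noise alone
makes same-direction module pairs correlate above 0.8 in a sizeable
fraction of datasets and they fuse during clustering, which would measure
the sample size, not the method. A gene with loading rho has profile
`rho * P + sqrt(1 - rho^2) * sd(P) * eps`, so two genes correlate at
rho_i * rho_j in expectation; loadings are drawn uniformly in
sqrt(within_module_cor) +/- 0.05 (mean pairwise correlation ~0.8 at the
default target), and five designated anchor genes per module carry the
latent profile exactly (loading 1, no gene noise) — the hub-like structure
the anchor-recovery tests presume, since at 12 samples the sampling sd of a
realised gene-latent correlation (~0.06) makes a "highest loading" gene
inside a narrow band unidentifiable. Background genes get independent
replicate noise of sd 0.3 log2, a realistic biological-replicate scale.

Counts are gamma-Poisson: per-gene rates `length/1000 * 2^(baseline + y)`
(baseline log2 abundance ~ N(3.5, 1.5^2)) are multiplied by gamma noise of
dispersion 0.05 and drawn as a multinomial conditioned on a library size
uniform in 5-15 million reads, so column sums land inside the configured
range by construction while gene marginals are negative-binomial-like.

The genome generator writes contigs of 50 genes on alternating strands
(1.5 kb promoter, 300 bp CDS, 100 bp spacer), fills them from a 0-order
background (uniform by default), and plants one exact-consensus motif
instance (default: a 10-mer with a GGC(A/T)3-style core) at a recorded
offset on a random strand in a configurable fraction of promoters. The
annotation generator assigns each term to genes at a background frequency
(uniform in 0.02-0.08 by default) and raises one planted term per module to
`min(1, fold * background)` inside that module.

What the generator does not emulate: real gene catalogues, genomic motif
clustering or higher-order sequence composition, correlated annotation
structure (GO DAG), length biases in counting, or batch effects. Passing
recovery tests therefore show the pipeline recovers the structure it
assumes, at desk scale (~1,200 genes), not that it reproduces the published
network statistics, which depend on the original dataset.

## Numerical choices and degenerate inputs

- Correlations are clipped to [-1, 1]; NaN correlations (zero variance)
  become 0 with a warning.
- The scale-free fit requires at least two nonempty connectivity bins and
  raises on degenerate (constant-connectivity) input.
- Merges at exactly the cut height are split (strict cut), so an
  identity-like TOM yields zero modules under any cut.
- Eigengene sign: mean gene-eigengene correlation positive; ties in module
  sizes during merging resolve to the first-listed module.
- MCODE seed ties break lexicographically; haircut iterates to a fixed
  point.
- BH adjustment delegates to statsmodels; the hypergeometric tail uses
  scipy's log-space survival function.
- Percentile cutoffs are nearest-rank; hub calls use strict inequality, so
  regular graphs have no hubs.
- PWM building rejects pseudocount 0 whenever a count is 0.

## Problem sizes in the test suite

The default recovery dataset is ~1,200 genes x 12 samples; the scan null
runs on 2.1 Mb of background promoter sequence; null calibrations use 10
network datasets of 300 genes and 50 annotation resamplings. These sizes
give tight recovery statistics (module ARI ~0.9, DE recovery ~0.97, motif
sensitivity ~1.0 in typical seeds) while the whole suite runs in well under
a minute.
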