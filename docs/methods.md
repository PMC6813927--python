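# Methods

This note records the models implemented in `triadnet`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Preprocessing

Genes enter the network when their TPM exceeds a threshold (default 0.5)
in at least one sample of the target tissue; the comparison is strict
(`> 0.5`), so a gene at exactly the threshold is dropped. Filtering is on
TPM, but correlation is computed on normalized **counts** of the surviving
genes: counts carry the mean–variance information that robust correlation
benefits from, while TPM is the natural scale for presence/absence.

Depth normalization uses median-of-ratios size factors: per gene, the
geometric mean across samples (genes with any zero count excluded); per
sample, the median over genes of count / geometric mean. No rescaling is
applied afterwards, so a sample sequenced exactly twice as deep gets
exactly twice the factor. The variance-stabilizing step is
`log2(count / sf + 1)`: monotone in counts, ratio-invariant (doubling
count and factor together changes nothing), and rank-preserving — the
properties the downstream correlations depend on. A dispersion-trend VST
(as in DESeq2) would shrink low-count variance more aggressively; at the
cost of that refinement, the chosen transform is exactly reproducible and
dependency-free. This is a deliberate, documented substitution.

## Network model

- **Correlation.** Biweight midcorrelation (bicor) with the standard
  tuning constant 9: observations are weighted by (1 − u²)² where u is the
  deviation from the gene's median in units of 9 MADs. The
  `max_p_outliers` parameter (default 0.05) caps, per tail, the fraction
  of samples that can receive zero weight, by rescaling each tail so its
  outer quantile maps to |u| = 1. Genes with zero MAD (majority-constant
  profiles) fall back to ordinary mean-centered correlation and are
  reported; zero-variance genes get zero correlation and are reported.
  When all weights are equal — e.g. profiles whose deviations from the
  median all share one magnitude — bicor reduces exactly to Pearson; this
  is a test invariant.
- **Adjacency.** Signed hybrid (default): a = s^β for s > 0, else 0, so
  anti-correlated genes are never connected; `unsigned` (|s|^β) is
  available. The diagonal is 1 for the TOM input view and excluded from
  connectivity (both views are exposed on `AdjacencyMatrix`).
- **Soft threshold.** Powers 1..20 are scanned; for each, connectivity
  k_i = Σ_j a_ij is histogrammed into 10 equal-width bins (empty bins
  dropped) and log10(frequency) is regressed on log10(mean k per bin). The
  signed fit index is −sign(slope)·R². The chosen β is the smallest power
  exceeding the target (default 0.9). If no power qualifies — the expected
  outcome on unstructured data — the scan records that; `fit()` then falls
  back to the best-fitting scanned power with a warning rather than
  aborting, since a network on weakly structured data is still sometimes
  wanted.
- **Module detection.** Average-linkage clustering of 1 − TOM, cut
  statically at a fraction (default 0.99) of the maximum merge height.
  Clusters below `min_module_size` (default 30) are unassigned (module 0).
  The dynamic tree-cut used by blockwise WGCNA at atlas scale is not
  reimplemented: the static cut reproduces the documented parameters
  (minimum size 30, merge height 0.15) with far simpler, fully testable
  semantics, and the cut height is configurable. Between well-separated
  modules the inter-module merges sit near the dendrogram top, so the
  0.99 fraction splits them while keeping within-module merges intact.
- **Eigengenes and merging.** A module eigengene is the first right
  singular vector (over samples) of the member genes' z-scored profiles:
  unit Euclidean norm, sign oriented so the mean member correlation is
  nonnegative, with variance-explained reported as the top eigenvalue
  share. Merging is iterative: while the closest eigengene pair satisfies
  1 − cor < merge height (default 0.15), merge and recompute. Eigengene
  and kME correlations are ordinary Pearson — eigengenes are already
  denoised aggregates, so robust weighting buys nothing there.
- **Determinism.** Ties anywhere (hub ranking, label assignment) break by
  lexicographic gene id; modules are numbered 1.. by decreasing size.
  Identical inputs give byte-identical outputs.

## Module–tissue relationships

Eigengenes are correlated with one-hot tissue indicators; significance is
the Student asymptotic test, t = r√(n−2)/√(1−r²) with n−2 df, two-sided.
BH adjustment treats the full module × tissue grid as one family — the
table is computed in one call, so one family is the natural unit; a
per-tissue family would be defensible too, and the difference only
rescales FDRs by a small factor. The tissue-specificity rule — r > 0.5 and
FDR < 0.05 with the target, and for every other tissue r < 0.3 or r ≤ 0 —
is monotone in its thresholds: raising `r_high` can only remove modules.

## Enrichment

Gene-set enrichment per module is the two-sided Fisher exact test on the
2×2 table over a background universe, with expected counts
|set|·|module|/|background|. The default background is genes assigned to
nonzero modules; including module 0 or all expressed genes is a switch,
because the right universe is genuinely ambiguous and materially changes
expected counts. GO-term enrichment is a hypergeometric upper tail per
term with BH across terms within the module. A length-weighted variant
(Wallenius noncentral hypergeometric, odds = mean term length / mean
background length) is provided for length-biased designs; with unit
lengths it reduces to the plain hypergeometric, which is the default since
the synthetic data fixes gene lengths at 1 kb. Sets overlapping other sets
can be resolved by a caller-supplied priority order before testing.

## Homeolog copy number and expression bias

Copy-number categories: triad = exactly (1, 1, 1) across A/B/D; duplet =
two subgenomes with one copy each; monad = a single copy anywhere; other =
everything else. Bias classification uses exact centroid fractions (1/3,
1/2) rather than the 2-decimal prints — the rounded values would tilt the
decision boundaries off the simplex's three-fold symmetry. Distance ties
(measure-zero, but reachable on grids) break by the fixed priority
balanced → suppressed A/B/D → dominant A/B/D. Per-tissue classification
averages TPM across the tissue's samples **before** forming contribution
ratios (median available); triads with zero total expression in a tissue
are excluded for that tissue. Per-homeolog labels derive from the triad
category by the natural mapping: balanced → all balanced; X dominant → X
dominant, others suppressed; X suppressed → X suppressed, others dominant.

## Guide-gene subnetworks

A subnetwork seeded by guide genes contains every gene whose TOM to at
least one guide exceeds `weight_min` (default 0.05), with all
above-threshold edges among the recruited nodes (a guide-edges-only mode
exists). Hub connectivity of a node reports its direct-edge count and the
percentage of subnetwork nodes it touches; the denominator includes the
node itself, which is the convention that reproduces 41 edges / 53 nodes
= 77.4%.

## Synthetic data

The generator emulates a polyploid expression atlas at desk scale.
Defaults (all overridable):

| parameter | default | rationale |
|---|---|---|
| tissues × samples | 8 × 5 = 40 | desk-scale version of an 8-tissue, 130-sample atlas |
| modules | 4 × 80 genes (meiotic-anther-, leaf-, root-associated, tissue-free) + 180 background = 500 genes | smallest design exercising selection vs. rejection |
| factor model | gene = loading · factor + noise; loading ~ U(0.5, 1.5); factor ~ N(0, signal_sd²), signal_sd = 2 | classic latent-factor module structure |
| tissue effect | +3 · signal_sd in associated tissue | yields module–tissue r ≈ 0.7–0.9, the magnitude real atlases show |
| noise_sd | 1 (log2 units) | within-module correlation ~0.8 before count noise |
| triad_fraction | 0.6 | roughly the triad share of polyploid wheat genes |
| category mixture | balanced 0.70, each suppressed 0.06, each dominant 0.04 | balanced-majority, as in polyploid wheat atlases |
| centroid concentration | 200 | "high": draws hug their centroid, classes are separable |
| library sizes | U(0.5, 2) million | per-sample depth variation |
| counts | Poisson (dispersion 0; gamma-Poisson if > 0) | simplest integer law preserving the mean structure |

Mechanics: homeolog groups (triads of 3 genes or monads) are laid out
first, within each module and the background. Each group draws a baseline
(log2 U(4, 9)), its module's loading-scaled factor, and shared sample
noise; the linear total is split among triad members by a contribution
vector drawn from a Dirichlet centered on the (floored) category centroid.
Centroids containing zeros get a small uniform floor (0.01, renormalized)
so all Dirichlet parameters are positive; the floor leaves the balanced
centroid exactly at (1/3, 1/3, 1/3) and keeps every category's
infinite-concentration limit inside its own decision region. Counts are
Poisson around library-size-scaled relative expression; TPM is recomputed
from counts at unit gene length, so TPM columns sum to exactly 10⁶.

What the generator does **not** emulate: read-level noise and mapping
ambiguity between near-identical homeologs, batch/study effects,
gene-length variation, overlapping or hierarchical modules,
tissue-dependent bias categories (one contribution vector per triad), and
realistic chromosome coordinates. Passing recovery tests therefore shows
the pipeline's logic is correct under its own model assumptions, not that
real-data performance is guaranteed; in particular homeolog mapping
ambiguity, absent here, is a major real-world error source for bias
classification.

Note one consequence of the triad construction: members of a background
triad share their group's noise profile, so they are mutually correlated
(as real homeologs are) even though background groups are independent of
each other and of all modules. These 3-gene clusters sit far below the
minimum module size and stay in module 0.

## Problem sizes and numerical checks

The default test and acceptance runs use the 500-gene / 40-sample design
above — chosen as the smallest configuration on which module recovery,
selection and triad classification are all informative — plus: 200 random
5–8-gene adjacencies for the TOM oracle (agreement < 1e-12), all 2×2
tables with total ≤ 30 (hence all margins ≤ 30) for Fisher vs. exact
enumeration, a 10,011-point simplex grid for the centroid classifier, and
500 label permutations for the enrichment false-positive rate. On this
design, planted-module recovery reaches ARI 0.8–1.0 across seeds (the
variation comes from the soft-threshold scan occasionally choosing a high
β, which drops weak-loading genes to module 0 — the modules themselves are
recovered), and triad category recovery is ≈100% at concentration 200.

## Known limitations

- The static dendrogram cut is coarser than dynamic tree cut on real,
  nested module structure; deeply split sub-modules will not separate.
- The log2 size-factor transform under-stabilizes very low counts relative
  to a fitted VST.
- GO annotation is taken as given — no ancestor propagation over the
  ontology graph.
- Bias classification treats each tissue independently; no shrinkage
  across tissues or replicates.
- Single-block implementation: dense n × n matrices, comfortable to a few
  thousand genes, not for 60k-gene atlases.
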