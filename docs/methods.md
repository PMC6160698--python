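# Methods

`lncmetnet` annotates long noncoding RNAs (lncRNAs) with candidate
biological functions by guilt-by-association on a small paired
tumor/normal expression array, and integrates the resulting coexpression
evidence with protein–protein interactions and miRNA–target regulation.
This note records the statistical model behind each stage, the defaults
and why they were chosen, and what the synthetic-data generator does and
does not emulate.

## Expression analysis

Input is a probe × sample matrix of log2 intensities with paired
tumor/normal labels and a probe biotype (lncRNA or protein-coding).

**Quantile normalization.** Columns are forced onto a common
distribution: the reference is the per-rank mean of the sorted columns,
and ties within a column receive the mean of the reference values over
their tied ranks. This tie rule makes the transform deterministic and
independent of row order; on tie-free data it is idempotent.

**Presence filtering.** Probes are kept if flagged "expressed" in at
least `min_present` samples (default 3, i.e. half of a 6-sample design).
Detection calls are taken from a vendor flag matrix when available; a
fallback rule (intensity above the per-sample median) is provided
because array platforms differ in how they report detection.

**Differential expression.** Per probe, a two-sided two-sample t-test of
tumor vs normal on the log2 values, plus the fold change
2^(mean_tumor − mean_normal). The default test is the classic pooled
(equal-variance) t-test: at n = 3 per group it holds the nominal 5%
type-I error exactly under Gaussian noise, whereas Welch's approximation
is noticeably conservative at that size (empirical size ≈ 0.036 in our
simulations). Welch (`equal_var=False`) and a paired test on per-pair
differences (`paired=True`) are available; with three biological pairs
the unpaired group-wise test is the conventional volcano-filter default.
Rows with zero within-group variance get p = 1 (no difference) or p = 0
(nonzero difference) with a logged warning instead of NaN. Genes are
called up if fold change > 1.5 (strictly) and p < 0.05, down if fold
change < 1/1.5 and p < 0.05.

**External confirmation.** Internal calls can be intersected with a
user-supplied differential list (gene, direction); only genes confirmed
in the same direction survive. Symbols are compared case-insensitively.

**Probe collapsing and clustering.** When several probes map to one
symbol, the probe with the largest mean intensity is kept (deterministic,
ties by probe id). Hierarchical clustering uses average linkage on the
1 − Pearson r distance; zero-variance rows are rejected by name because
their correlation is undefined.

## Coexpression network

All unordered gene pairs are tested: Pearson correlation r over the n
samples, p-value from the Fisher z-transform normal approximation
(z = atanh r; z·√(n−3) ~ N(0,1) under the null), Benjamini–Hochberg
adjustment over the full family of g(g−1)/2 pairs in one batch, and
edges kept when adjusted p < 0.05, signed by the correlation sign.
|r| = 1 maps to p = 0 exactly; n < 4 is rejected because √(n−3)
degenerates. A Student-t alternative (t = r√(n−2)/√(1−r²)) sits behind
`method="t"`; the Fisher-z form is the default because it is the
standard asymptotic correlation test in coexpression toolkits. Constant
genes are dropped with a logged warning before correlation.

The BH family is deliberately *all tested pairs*, not per-gene families:
edge selection is a single multiple-testing problem. Consensus
aggregation across many edge tables keeps a pair present in at least
`min_support` datasets (default 50); edge identity is the unordered node
pair, with an optional strict mode requiring a consistent sign.

## Guilt-by-association annotation

A lncRNA with strictly more than `min_neighbors` (default 3, i.e. ≥ 4)
directly coexpressed protein-coding genes is a hub eligible for
annotation. For each hub, every GO biological-process term is scored by
the hypergeometric upper tail: with a universe of N annotatable genes of
which K carry the term, and n_draw annotated neighbors of which x carry
it, p = P(X ≥ x). The universe is the intersection of the gene-set
collection's genes with the network's tested gene space — using the
full collection would inflate K with genes the experiment never
measured. Terms with at least one annotated neighbor are tested and
BH-adjusted per lncRNA (each lncRNA's terms are one family; a pooled
global family is available via `adjust="global"`); terms with adjusted
p < 0.05 are assigned. Neighbor sign is ignored: both positively and
negatively coexpressed partners carry functional information. Top-term
ranking is by ascending p, ties broken by larger overlap x, then term
id. GO-graph propagation and semantic-similarity reduction are out of
scope; KEGG-style collections work unchanged through the GMT reader.

## Network integration

Three evidence layers merge into one typed multigraph: signed
coexpression edges, PPI edges, and miRNA→target regulations filtered to
miRNAs differentially expressed in the direction *opposite* to their
target (the expected signature of a repressive regulator). Pairs with an
unknown direction on either side are dropped with a logged count. A node
pair may carry several typed edges at once; PPI/coexpression overlap is
keyed on the unordered pair with the sign taken from the coexpression
edge. Coexpression edges may not touch miRNA nodes, mirna_target edges
have exactly one miRNA endpoint (stored miRNA→target), and self-loops
are rejected. GraphML export is lossless (round-trips nodes, typed edges
and attributes); SIF and TSV exports are provided for viewers.

## qPCR quantification

Relative expression uses the comparative threshold-cycle method:
dCq = Cq(target) − Cq(reference gene), ddCq = dCq(tumor) − dCq(normal),
fold change = 2^−ddCq. Lower dCq means higher expression — the standard
Cq convention; the package warns in documentation rather than code that
figure legends in the literature occasionally invert this. Technical
replicates are averaged per (patient, tissue, gene) before analysis.
Tumor-vs-normal comparison is a two-sided paired t-test on dCq;
association with clinical characteristics uses an equal-variance
two-sample t-test for two categories (the classic SPSS default; Welch
behind a flag) and one-way ANOVA for three or more, so the two-category
ANOVA F = t² identity holds exactly. Categories with fewer than two
patients are excluded with a warning. Amplification-efficiency
correction and survival analysis are out of scope.

## Synthetic data generator

The generator is first-class, tested code: it plants known structure so
every downstream stage can be validated without any download.

* **Expression** is simulated directly on the log2 scale as Gaussian
  noise (`noise_sd`, default 0.5 log2 units) around per-gene baselines
  (N(8, 1.5²)). The default design is 965 lncRNA and 458 protein-coding
  probes over 3 tumor/normal pairs — the scale of a metabolism-pathway
  array — with a planted effect of `log2_effect = 2` on a `de_fraction`
  of genes (tumor mean shifted by exactly ±log2_effect before noise).
* **Modules**: each planted coexpression module shares one latent factor
  per sample with loading √module_corr, giving an expected pairwise
  within-module correlation of exactly `module_corr`. Each module
  contains one lncRNA hub plus protein-coding members, so the
  guilt-by-association chain (hub → neighbors → term) is fully planted.
  DE genes are drawn disjointly from module genes by default so
  ground-truth contingencies stay unambiguous (`allow_de_in_modules`
  lifts this).
* **GO structure**: each module gets a signature term covering
  ⌈80%⌉ of its members and no outside genes; background terms annotate
  non-module genes independently at `go_background_rate` (default 0.2),
  forming the enrichment universe without contaminating the modules.
* **miRNA regulation**: planted (miRNA, target) pairs point at DE genes
  with the opposite direction; an equal number of same-direction decoys
  is emitted and recorded, so the direction filter's sensitivity and
  specificity are both measurable.
* **qPCR**: per-patient normal-tissue dCq baselines N(8, 1.5²); the
  tumor dCq adds `effect_dcq` plus N(0, sd) noise plus optional planted
  covariate effects. The reference-gene Cq (N(20, 0.5²)) carries no
  group effect.

What the generator does **not** emulate: probe-level artifacts (spatial
effects, dye bias, background), intensity-scale mean–variance trends,
patient random effects shared across genes, correlated annotation
structure of the real GO graph, and realistic amplification curves.
Passing the planted-truth tests therefore demonstrates the statistical
machinery is correct under its stated model, not that the model captures
every property of real arrays.

## Problem sizes and numerical choices

The validation suite uses sizes chosen to make Monte-Carlo error small
relative to the tolerances: 10,000 replicates for both null-calibration
checks (binomial s.e. ≈ 0.0022 at a 0.05 rate), 100 pairs for
planted-recovery (effect/s.e. = 2 / (0.5·√(2/100)) ≈ 28, so recovery is
essentially deterministic), and 100 seeded replicates of a 30-gene,
20-pair design for guilt-by-association recovery (module_corr = 0.8 and
n = 40 give per-edge p ≈ 10⁻¹¹, so hub neighborhoods are recovered
reliably). Hypergeometric tails are evaluated with scipy's stable
implementation and cross-checked against exhaustive enumeration for
N ≤ 12; BH adjustment is exact step-up arithmetic validated against an
independent O(m²) oracle. Pearson correlations are clipped to [−1, 1]
against floating-point rounding; all tabular outputs are sorted
deterministically and all randomness flows from explicit integer seeds.

## Known limitations

With only three biological pairs — the design the defaults emulate — the
t-test has low power and fold-change estimates are noisy; the planted
recovery guarantees quoted above hold for the 100-pair validation
design, not for n = 3. Coexpression p-values from 6 samples are
asymptotic approximations at the edge of their validity (n − 3 = 3);
edges from such small designs should be read as screening calls.
Enrichment treats GO terms as independent gene sets, ignoring the
ontology hierarchy, and per-lncRNA BH families do not control FDR
jointly across lncRNAs.
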