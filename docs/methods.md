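# Methods

`reggrammar` models mRNA abundance as a function of a gene's complete
regulatory structure — promoter, 5'UTR, coding sequence (through codon
usage), 3'UTR and terminator — and then interrogates the fitted model to
recover the regulatory grammar it has learned: sequence motifs, rules of
motif co-occurrence, and the engineering freedom available by
recombining promoter and terminator halves. Because genome-scale
training data cannot be shipped, the package is developed and validated
against synthetic cohorts in which the grammar is planted and therefore
known exactly. This note documents the models, the generator, the
numerical choices, and what the synthetic validation does and does not
establish.

## Expression processing

Raw counts are converted to transcripts per million
(`tpm_i = (c_i/l_i[kb]) / Σ_j(c_j/l_j[kb]) × 10⁶`; columns sum to 10⁶
exactly). Genes with median TPM < 5 are removed, then genes whose
relative standard deviation across experiments (RSD = σ/μ, sample σ)
is ≥ 1: the modelling target is the *stable* component of expression,
and genes that respond strongly to conditions have no single level to
predict. The per-gene median TPM is Box-Cox transformed (λ by maximum
likelihood on the training split only, then frozen) and the residual of
an ordinary least-squares fit on log₁₀ ORF length is taken as the
target, removing the technical coupling between fragment-based counts
and gene length. The inverse transform (add back the length term,
invert Box-Cox, floor at a configurable minimum TPM) maps model outputs
back to the TPM scale for fold-change analyses.

Two orderings were possible (length-correct then transform, or the
reverse); we fix Box-Cox → length-correction, because the length bias
arises in count space and is approximately linear on the transformed
scale. The published description of the length correction names ORF
length as the response variable, which read literally would make the
corrected quantity a length; we regress expression on length and keep
the residuals, which is the only direction that leaves an expression
target.

## Feature encoding

Regulatory sequences are one-hot encoded (rows A,C,G,T; `N` and padding
are all-zero columns). Regions are anchored at their CDS-proximal edge:
upstream regions (promoter, 5'UTR) are right-aligned and padded or
truncated on their distal (5') side, downstream regions on their distal
(3') side, because regulatory information concentrates near the
transcript boundaries. Default one-hot lengths are 1000/300/350/500 bp
(promoter/5'UTR/3'UTR/terminator; 2150 bp total) with a constricted
400/100/250/250 preset and a scaled 200/50/50/100 layout for synthetic
work. The CDS enters through 64 codon probabilities (lexicographic
codon order, `N`-containing codons skipped) plus 8 stability
covariates: lengths of 5'UTR/ORF/3'UTR, GC of both UTRs, and GC at each
codon position.

## The CNN-FC regressor

The sequence branch applies convolutional blocks
(conv → [batch-norm] → ReLU → max-pool → [dropout]) to the concatenated
one-hot regions; the flattened output is joined with the 72 numeric
features and passed through two fully connected blocks to a linear
output. Training minimizes MSE with Adam (uniform Glorot-style
initialization), keeps the checkpoint with minimal validation MSE
(early stopping, patience 10–15 epochs, plateau-triggered learning-rate
halving), and uses an 80/10/10 train/validation/test split of genes.
The engine is a small, fully tested numpy implementation with
hand-written backpropagation; gradients are verified against finite
differences in the test suite.

Two training schedules are provided. *Concurrent* training updates both
branches together. *Consecutive* training (the default for synthetic
cohorts) first trains the network sequence-only for a warmup phase,
snapshots those weights, then freezes the convolutional filters and
refits the head on sequence + numeric inputs. The consecutive schedule
exists because codon features alone already explain a large share of
the target; under concurrent training the head converges on them before
the (slower) sequence filters develop, early stopping fires, and the
conv branch is left untrained. The warmup snapshot also provides a
sequence-only predictor (`model.sequence_model()`) used for
attribution.

The scaled-cohort preset uses a single wide detector block (256 filters
of 8 bp, global max pooling — presence features, which is what a
motif grammar needs) with a (64, 32) head, no batch-norm and no
dropout; empirically, dropout in the head prevents the weak per-motif
gradients from consolidating at this data scale, and early stopping
regularizes sufficiently. The full-size preset keeps the three-block
layout (64/64/128 filters, kernels 30/10/10, pool 4).

Model quality is reported as R² = 1 − SS_res/SS_tot on the test split
(this definition can be negative), with an F-test of the
observed-on-predicted univariate regression against the intercept-only
model as the significance check; degrees of freedom for a neural
network are undefined, so the F-test is applied to that univariate fit.

Shallow baselines (linear, ridge, lasso, elastic-net, random forest,
linear SVR, kNN via scikit-learn) consume overlapping k-mer counts
(k = 4–6, region-tagged columns) and/or the numeric features;
hyperparameters are selected on the validation split.

The codon-usage model reuses the sequence branch with a 64-output
softmax head trained by MSE against the codon probability vectors;
performance is pooled R² over (gene, codon) pairs with SS_tot around
per-codon means, so predicting the average codon profile scores zero.

## Occlusion relevance

For a trained model with prediction Y on the intact input, 10-bp
windows of the one-hot sequence are zeroed (the same encoding as
N/padding) and each window's relevance is (Y − Y_occluded)/Y.
Per-position profiles average over the (stride-1) windows covering the
position; whole-region occlusion is available for region-level
analysis. Numeric features are held at their true values, isolating
sequence attribution. Because the modelling target is a length-corrected
residual centred near zero, the ratio is taken on the positive
pre-length-correction Box-Cox scale by shifting predictions with the
gene's fitted length term (`y_offset`); genes whose |Y| still falls
below 10⁻⁶ are flagged and reported unscaled.

Significance masks are cohort-level: per region, all genes' positional
relevances are pooled, z-scored, and positions with |z| ≥ 2 are
flagged. Attribution is computed on the sequence-only (warmup) network
and, by default, on an *ensemble* of two independently seeded sequence
models. Following the two-tier reproducibility practice used for peak
calling, the intersection of the per-model masks is the reproducible
significant-position set (what we report), and their union is the
candidate set passed to motif discovery, whose clustering and minimum
cluster size control the extra noise. A single 8-bp planted motif
blurs into a ~26-bp relevance bump under 10-bp window averaging, so
positional precision — not sensitivity — is the limiting quantity, and
the intersection step is what keeps it high.

For the single-block architecture an exact fast path computes occluded
predictions incrementally (only ~17 convolution columns change per
window; cached prefix/suffix maxima give the new pooled features). It
produces bit-identical results to the generic path and makes
cohort-wide and ensemble attribution routine.

Relevance profiles can be grouped by consensus clustering: partition
around medoids on 1 − Pearson r distances, 50 repeats on 80%
subsamples; consensus(i,j) is the co-clustering frequency over repeats
sampling both profiles, k is the smallest value whose relative
consensus gain falls below 10%, and final labels come from PAM on
1 − consensus.

## Motif discovery

Maximal runs of significant positions are tiled into 10-bp windows
(runs shorter than the window are centred and extended; a remainder at
the end of a long run yields a final right-aligned window). Windows are
clustered greedily in order of decreasing mean relevance: each window
joins the first cluster whose representative matches at ≥ 0.8 identity
(matches/overlap under the best ungapped offset within ±2 bp; a shared
4/5/6-mer prefilter for cutoffs 0.8/0.85/0.9 is a speed heuristic
only), else founds a new cluster; clusters below 5 members are
discarded. Cluster counts become probabilities with a 0.25 pseudocount
per base per column, information content is computed against a uniform
background, and edges below 0.2 bits are trimmed (interior columns are
never removed; fully trimmed clusters are dropped).

PWM pairs are compared by per-column Pearson correlation over ungapped
offsets with ≥ 4 overlapping columns. The offset is selected — and the
permutation null evaluated — on the *summed* column correlation, since
a mean-based statistic lets a minimal-overlap chance alignment of two
sharp columns tie a full-length match; the reported similarity is the
mean correlation at the selected offset. The null shuffles the columns
of the wider PWM (a narrow PWM has too few distinct orders to resolve
small tail areas), is computed through a precomputed column-correlation
matrix so thousands of permutations are cheap, and is corrected by
Benjamini-Hochberg by the caller. For recovery questions
(`match_references`) the statistic is the maximum over the discovered
collection and offsets, with the null permuting the reference — so the
selection is inside the null — and BH across references.

A gene carries a motif when one of the motif's member windows
originates from it (occurrences inherit the relevance evidence); a
PWM-scan occurrence mode is available for sensitivity analysis.

## Co-occurrence rules

Frequent itemsets of size 2–6 with ≥ 3 carrier genes are mined from the
gene × motif matrix by an FP-growth implementation verified set-equal
to brute-force enumeration. Each itemset gets support, confidence
(full-set support over the support of the set minus its
lexicographically last motif; all splits available), lift, and a
significance test: the 2×2 presence-table chi-squared for pairs, and
for larger sets the exact binomial tail of the observed full-set count
against its independence expectation (the chi-squared approximation is
badly anticonservative at the small expected counts typical of
triples). The literature the original analysis cites does not fix a
construction for sets, so this one is explicit and swappable. Benjamini-Hochberg across all tested itemsets at FDR 0.05
plus the ≥ 3-gene filter defines significant rules; genome coverage is
the fraction of genes carrying at least one.

Expression specificity is quantified on the raw median-TPM scale:
per item (motif or rule), carrier-gene mean, SD and SNR = μ/σ;
repurposing tables group rules sharing a motif (or differing by exactly
one) and report max/min fold ranges of carrier means; codon specificity
contrasts median pairwise Euclidean distances between carrier codon
vectors.

## Promoter/terminator swaps

A gene splits into a promoter half (promoter + 5'UTR) and a terminator
half (3'UTR + terminator). All n² recombinations are enumerated lazily;
constructs inherit the promoter-half gene's CDS-derived numeric
features, which makes the native construct the well-defined fold-change
reference (the native × native diagonal has fold change exactly 1).
Predictions are inverse-transformed to TPM. The grammar-free null
shuffles the terminator-half sequences while preserving all 16
dinucleotide counts and both terminal bases exactly (random last-exit
edges forming an arborescence into the final base, then an Euler walk;
uniform over valid shuffles); Levene's test compares native versus
shuffled log fold-change distributions.

## Ortholog substitution rates

Per-region alignments are masked (confidence ≤ 0.2 removed, gap
columns removed) and summarized by the Jukes-Cantor corrected mean
pairwise distance, rate = −(3/4)·ln(1 − 4p/3), reported as +∞ when
p ≥ 0.75. Pearson correlation of per-gene promoter versus coding rates
(non-finite rates excluded) quantifies co-evolution. This estimator
deliberately replaces Bayesian gamma-rate machinery: validation is
parameter recovery on simulation, not equality with published rate
constants.

## The synthetic generator

The generator emulates the statistical structure of a compendium-scale
RNA-seq cohort and plants a known grammar:

- **Background sequence**: per-region first-order Markov chains with
  configurable GC (UTRs AT-rich) and a mild same-base stacking
  preference, so the dinucleotide-preserving shuffle is a meaningful
  null.
- **Grammar**: 60 motifs of 8 bp (per-column dominant base 0.88),
  assigned to regions (promoter-heavy), participating in 40 rules of
  2–3 motifs; 88% of rules span ≥ 2 regions. Rule effects are additive
  on log₁₀ expression, |effect| ~ U(0.2, 0.5) with random sign.
- **Presence model**: motifs appear in a gene through sparse background
  presence (p = 0.012) or because the gene is a forced carrier of one
  of the motif's rules (p = 0.05 per rule); every rule is re-forced
  until ≥ 3 genes carry it fully. Presence is therefore dominated by
  rule context — the signature of a co-evolved grammar — which is also
  what makes the grammar statistically learnable at ~3000 genes:
  roughly 5.5 planted instances per gene.
- **Planting**: instances are sampled from the PWM, rejection-sampled
  to score ≥ 80% of the maximal log-odds (so self-recovery by scanning
  is exact), and placed uniformly without overlap, one instance per
  gene per motif, positions recorded.
- **Codon coupling**: each gene's CDS (lognormal length around 1200 bp)
  is sampled from a mixture of a biased codon table (72% of mass on 8
  preferred codons) and a uniform table; the mixture weight follows a
  *blurred* expression class, w = coupling·clip(rank + N(0, 0.15)) +
  (1−coupling)·U(0,1) with coupling 0.8. The blur is essential: exact
  rank coupling would let codon features reconstruct the whole signal
  and leave nothing for the sequence branch to learn. A small additive
  codon term (0.3·(w − mean)) feeds back into expression.
- **Expression**: latent log₁₀ level = baseline + Σ active-rule effects
  + codon term + residual noise, where the residual SD defaults to half
  the latent signal SD so the best achievable model R² is ≈ 0.8.
  Per-experiment values multiply lognormal noise (0.15 log₁₀ units for
  stable genes; a 12% condition-responsive fraction draws
  U(0.45, 0.8)), and columns are TPM-normalized. Under these defaults
  ~87% of genes have RSD < 1, median TPM spans > 4 orders of magnitude
  and the median genome-to-gene variance ratio is in the hundreds.
- **Orthologs**: star-phylogeny Jukes-Cantor simulation from each
  gene's own regions; per-gene rates are lognormal (mean 0.3, SD 0.5 on
  the log scale), with the promoter/coding log-rates drawn jointly so
  the *rate* correlation equals the requested value (the lognormal
  moment transform maps the requested Pearson r to the normal-scale
  correlation). Column confidence scores default to 1.

What the generator does **not** emulate: nucleosome structure, introns
and splicing, condition-specific regulation, binding-site energetics
beyond PWMs, phylogenetic tree structure (star only), indels and
alignment error. Passing the synthetic recovery suite therefore shows
that the pipeline's statistics and optimization recover a grammar of
this additive, presence-based form at realistic noise levels — not that
real genomes obey that form.

## Problem sizes and seeds

Default synthetic experiments use 4000 generated genes (≈ 3300 after
filters), 100 experiments, the 400-bp scaled regulatory layout, ~45
training epochs for the full model and an 80-epoch capped sequence
warmup; attribution ensembles use two models; rule mining for recovery
runs at itemset sizes ≤ 3 (planted rules have ≤ 3 motifs); swap
analyses use 40–60 genes and the coevolution analysis the full cohort
with 8 species. One global seed fans out to per-stage seeds via
`numpy.random.SeedSequence.spawn`, and identical configuration + seed
reproduces byte-identical cohorts and metrics.

## Known limitations

- The occlusion ratio is undefined near Y = 0; the length-term offset
  makes this rare but flagged genes fall back to unscaled differences.
- Identity clustering is greedy and order-dependent (by design,
  CD-HIT-like); a different window order changes cluster boundaries at
  the margins.
- The chi-squared construction for itemsets larger than pairs assumes
  per-motif independence in the expectation; strongly nested rules
  share carriers and their statistics are correlated — BH across
  itemsets does not remove that dependence (it is conservative under
  positive dependence).
- Consecutive training freezes conv filters after warmup; if numeric
  features genuinely interact with sequence features, that interaction
  is only representable in the head.
- The swap analysis inherits the model's extrapolation behaviour:
  recombined halves can produce feature combinations outside the
  training distribution, and predicted fold changes there are
  extrapolations.
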