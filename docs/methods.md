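# Methods

## Model and procedure

The unit of analysis is a pair (signature, dataset). A dataset is a
genes × samples expression matrix, assumed already normalized and on a
log-like scale; the package only mean-centers each gene within each
dataset (no unit-variance scaling — the variance-explained statistics are
the object of study, and scaling would change them; a `scale` flag exists
for sensitivity checks).

PCA runs on the submatrix restricted to the signature's genes, with
samples as observations and genes as variables; the covariance uses the
n − 1 denominator. Numerically this is an economy SVD of the centered
submatrix (never a dense gene × gene covariance), so eigenvalues beyond
min(genes, samples) are implicit zeros; the sum of the returned
eigenvalues still equals the total variance (trace identity), which the
tests verify against a dense symmetric eigendecomposition.

Two spectrum summaries are computed: L1 = λ₁/Σλᵢ (overdispersion) and
L1/L2 = λ₁/λ₂ (coordination). A rank-one submatrix has λ₂ = 0 and is
maximally coordinated; L1/L2 returns +∞ there, and the empirical p-value
handles the sentinel (an infinite observation beats every finite null
draw).

### Eigengene sign

The sign of a principal component is arbitrary, so a deterministic
orientation rule is applied: the metasample (centered samples projected on
the eigengene) must correlate non-negatively with the mean centered
expression of the signature's matched genes; exact ties are broken by
making the largest-magnitude loading positive. Downstream comparisons
(conservation, functional redundancy) additionally use absolute
correlations, so no result depends on the orientation; the rule only fixes
the reported sign of activity scores, making "up" mean "mean expression of
the set increases".

### Empirical nulls and multiple testing

For each dataset and each distinct matched set size, `n_draws` random
gene subsets of that exact size are drawn uniformly without replacement
from the dataset's genes; their L1 and L1/L2 values form the null. The
null is shared across all signatures of the same matched size in that
dataset, which makes collection-scale scoring tractable. P-values use the
upper-tail estimator with a pseudo-count, p = (1 + #{null ≥ obs})/(n + 1),
so p is never 0 (required by BH and by log-scale scores).

BH adjustment runs per dataset, separately for the L1 family and the
L1/L2 family, across all scored signatures.

`n_draws` defaults to 300. The floor of the empirical estimator is
1/(n_draws + 1), and after BH the block of signatures at the floor
receives adjusted p = m/(k(n_draws + 1)) for k floor signatures among m
tested. At level α = 0.05 this clears the threshold only when
k/m ≥ 20/(n_draws + 1): 100 draws would require ≥ 20% of the tested
collection to be truly informative, whereas 300 draws support fractions
down to ~7%. The count is configurable; it trades runtime for the
smallest detectable informative fraction, not for accuracy of the
statistics themselves.

### Informative calls and the selection FDR

A signature is informative when both adjusted p-values are < α (default
0.05) in at least `k_min` datasets. `k_min` defaults to 2 — the operative
reading of the selection rule; datasets where a signature matched fewer
than `min_genes` genes (default 10) count as non-significant, not as
missing.

The false-discovery rate of the whole procedure is estimated on random
signatures that mimic the input collection: sizes are sampled by
percentile stratification (100 quantile bins of the empirical size
distribution; a bin is chosen proportionally to its occupancy, then a
size uniformly among the observed sizes in the bin), and genes are drawn,
distinct within a signature, with probability proportional to their
occurrence count across the collection — a gene present in 100 signatures
is 100× as likely, preserving between-signature dependence to some
extent. A requested size exceeding the distinct-gene count is resampled
(reported). The FDR estimate is the fraction of random signatures called
informative.

### Conservation

For each signature scored in ≥ 2 datasets, eigengenes from every dataset
pair are restricted to their shared genes (pairs with < `min_overlap`,
default 10, shared genes are skipped) and compared by Pearson
correlation. The absolute r is used, because the per-dataset PCA sign is
arbitrary; the two-sided t-distribution p-value is symmetric in the sign
of r, so |r| leaves it unchanged. The conservation score is
−mean(log₁₀ pᵢ) over the retained pairs, i.e. |log₁₀| of the geometric
mean p-value; base 10 makes the conserved rule read directly as
"geometric-mean p < 10⁻⁶ ⇔ score > 6" (strict inequality at the
boundary). P-values are floored at 10⁻³⁰⁰ to keep logs finite. A constant
loading vector (degenerate, essentially impossible on continuous data)
contributes r = 0, p = 1.

### Redundancy

Compositional redundancy is the Jaccard index of the two gene sets, with
a one-sided hypergeometric upper-tail test for the overlap; the universe
is the set of genes appearing anywhere in the scored collection, and the
test is BH-corrected across all evaluated pairs (α = 0.05). Functional
redundancy is the arithmetic mean, over the datasets where both
signatures were scored (at least `min_shared_datasets`, default 2), of the
absolute Pearson correlation between their metasamples. Datasets where
either signature is unscored are excluded from the mean rather than
zero-filled.

### The network

Nodes are the selected signatures, annotated with category,
informativeness, conservation status and gene count (the attributes a
renderer maps to color, shape and size). An edge exists iff functional
redundancy strictly exceeds `edge_threshold` (default 0.7); its weight is
the unweighted average of the two redundancy measures (Jaccard and
functional redundancy — equal weights, configurable in principle by
editing the combination), and its class is "functional-plus-JI" when the
overlap test is significant, "functional-only" otherwise. Layout is not
computed: the graph is exported with full attributes (GraphML, SIF, JSON)
and spatial arrangement is delegated to the visualization tool.

### Differential activity

Per signature, the metasample (PCA fitted on all samples pooled, so both
groups share one component) is compared between two groups with the
equal-variance Student's t-test (Welch behind a flag). The reported
"fold change" is the difference of group means: activity scores are
centered projections whose sign is conventional, so a ratio is
ill-defined; no ratio mode is offered. Significance is the raw p < 0.05
cut used for map coloring — deliberately uncorrected at this step, since
the selection stage already controls the reliability of the signature
list. Zero variance in both groups with equal means yields t = 0, p = 1.

## The synthetic generator

Data follow a Gaussian linear factor model: value(g, s) =
Σ_f w(g, f)·a(f, s) + ε, with per-sample latent activities a ~ N(0, 1),
noise ε ~ N(0, noise_sd²), and loadings of constant magnitude
`loading_scale` with random signs, nonzero only on the genes of the
modules attached to the factor. This is the minimal structure exhibiting
a distinguishable principal axis for a planted gene set: the module's
covariance is w wᵀ + σ²I, with dominant eigenvalue ≈ m·w² + σ² for m
genes — a closed form the tests check. The global sign of each loading
vector is flipped so its mean is positive; since (w, a) and (−w, −a) give
identical data distributions this is a pure convention, and it aligns
each module's activity score with increasing mean expression so that
"upregulation" is well-defined in two-condition simulations.

Planted structure (all gene sets pairwise disjoint): modules with one
factor each, the first `n_conserved` of which reuse a single loading
vector in every dataset (conserved eigengenes) while the rest redraw
loadings per dataset; redundant pairs — two disjoint sets on one shared
factor (functional redundancy without overlap); background signatures —
random sets over the unassigned, noise-only genes, with sizes uniform
between 20 and 3× the module size. Two-condition data shift the latent
activity of designated factors by `group_shift` in the second half of the
samples.

Defaults — 4 datasets, 5000 genes × 100 samples, 20 modules of 50 genes
(10 conserved), 5 redundant pairs, 200 background signatures,
loading_scale 1, noise_sd 1 — give per-gene signal-to-noise of 1, a
regime where a 50-gene module carries λ₁ ≈ 51 versus a noise spectrum
near 1, detectable but not trivial with 100 samples. The generator does
**not** model count noise, heavy tails, batch effects, gene–gene
correlation outside planted modules, overlapping programs, or realistic
expression marginals; passing tests therefore demonstrate correctness of
the procedure under its own model assumptions (linear factor structure,
near-Gaussian data), not performance on real tumor compendia.

## Problem sizes used in the checks

The test suite runs the full pipeline on compendia of 3–4 datasets with
400–5000 genes and 50–100 samples; the null-model FDR computation uses
the full 4 × (5000 × 100) no-signal compendium with 1000 random
signatures and 100-draw nulls (~1 minute); calibration checks use 40–60
independent planted modules. These sizes were chosen so each statistical
assertion has enough replicates for 3σ tolerances while a complete run
stays in the minutes range on a single CPU.

## Known limitations

* The empirical p-value resolution bounds the detectable informative
  fraction (see the n_draws discussion above); very sparse collections
  need more draws.
* Null sharing per (dataset, size) means p-values of equal-size
  signatures in one dataset are computed against the same draws and are
  therefore correlated; the BH adjustment treats them as if independent.
* Only the first principal component is used; gene sets whose activity is
  intrinsically multi-dimensional (two or more coupled programs) are
  summarized by their dominant axis alone.
* Gene identifiers are matched case-sensitively with no synonym
  resolution; missing values in expression input are rejected, not
  imputed.
* The hypergeometric overlap test assumes sampling from a common finite
  universe (the scored collection's genes); for collections probing very
  different gene spaces its p-values are conservative.
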