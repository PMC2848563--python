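# Methods

This note documents the statistical models implemented in
`sarcoma-reclass`, the defaults and why they were chosen, what the
synthetic cohort generator does and does not emulate, and the numerical
conventions that matter for reproducibility.

## Expression data model

All computation operates on log2-scale gene×sample matrices with a
per-sample class label (one of LEIO, LIPO, FIBRO, RHAB, MPNST, SYN, or
UNKNOWN for histologically unclassifiable tumors) and a dataset/platform
tag. Normalization is per-sample median centering (median over
non-missing genes becomes exactly 0; idempotent). Missing cells (a cDNA
two-channel artifact) are imputed with the per-gene median; genes missing
in more than half the samples are dropped and reported. Probe-level rows
are collapsed to gene symbols by unweighted averaging of log values —
symmetric and order-free — and cross-platform merging intersects gene
sets in the first dataset's row order. Whether values are log scale is a
flag, never auto-detected, to avoid silent double-logging.

## Two-step nearest-centroid classifier

A single 6-class model is ill-posed when two classes (MPNST, SYN) share
expression; the classifier therefore works in two stages:

1. **Step 1** relabels MPNST and SYN as COMPOSITE, selects genes by
   one-way ANOVA F-test across the 5 classes at p ≤ 4×10⁻⁷ (the cutoff
   used with this classifier family on real cohorts), and stores
   per-class centroids (class means over selected genes).
2. **Step 2** selects genes by the same F-test (equivalently t² for two
   classes) among MPNST+SYN samples only, at p ≤ 10⁻⁴ — more lenient
   because this comparison has far fewer samples — and fits a 2-class
   centroid model. Samples assigned COMPOSITE in step 1 are re-predicted
   by step 2.

Prediction assigns the class with minimal distance, by default
1 − centered Pearson correlation over the model genes (scale-free and
invariant to per-sample affine transforms; Euclidean available by
config). Exact distance ties break alphabetically and are flagged;
on real-valued data they have probability ~0. Fewer than 3 shared model
genes is an error (correlation is degenerate). Selections smaller than
3 genes are either an error or, when `fallback_n_genes` is set, padded
with the top genes by p-value; the fallback exists so that
cross-validation remains defined on data where nothing passes the strict
thresholds (null data, permuted labels).

**Cross-validation** is leave-one-out with full gene re-selection inside
every fold, so the held-out sample never influences the gene list used to
predict it (the alternative, a fixed gene list with per-fold centroid
refits, is available behind `reselect_in_cv=False` and is optimistic).
The inner loop is a numpy-only fast path; a 115-sample, 2000-gene LOOCV
takes ~0.25 s on one CPU.

**Permutation significance**: class labels are permuted `n_perm` times
(default 100), the full LOOCV is re-run per permutation, and
p = (1 + #{perm ≥ observed}) / (n_perm + 1). Permutation replicates
always use the top-gene fallback (default 10) because permuted labels
typically select nothing at the strict thresholds, which would leave the
null statistic undefined. The observed statistic uses the caller's
configuration unchanged.

**Cross-platform porting** keeps the intersection of model genes with the
target platform (losses reported), then refits centroids on the target's
labeled samples without re-selection — the "modified predictor" used when
platforms only partially share gene content. Fewer than 10 surviving
step-1 genes is an error.

## Empirical-Bayes batch adjustment

The parametric location/scale model: standardize each gene by its grand
mean α_g (batch-size-weighted mean of batch means) and pooled residual
variance σ_g²; estimate per-batch additive effects γ̂_ig (batch means of
the standardized data) and multiplicative effects δ̂²_ig (batch
variances, ddof 1); shrink them toward batch-level priors — normal for γ
(moments ḡ_i, τ²_i across genes) and inverse-gamma for δ² (moments →
shape/scale a_i, b_i) — by the standard iterative conditional update
(relative change < 10⁻⁶, cap 500 iterations). The adjusted value is
y* = σ_g/√δ²* · (z − γ*) + α_g. With shrinkage disabled the procedure
reduces exactly (< 10⁻¹⁰) to per-batch standardization rescaled to pooled
moments, which the tests verify analytically; the full mode is verified
against Bioconductor `sva::ComBat` (< 10⁻⁴; the residual is the two
convergence tolerances). No biological covariates enter the
standardization because labels are partly UNKNOWN in the intended use.
Zero-variance genes get a 10⁻⁸ variance floor with a warning.

## Co-clustering "molecular match"

Validation of a reclassified (UNKNOWN) tumor within its dataset:
complete-linkage clustering of all samples on 1 − r over the top-third
most variant genes (the wide gene set deliberately avoids circularity
with the optimized predictor genes), then, from the query's leaf, walk up
to the smallest enclosing cluster with at least `min_reference` (default
3) conventionally labeled samples; the plurality label among those
references is the matched class (plurality tie → NONE), and a match means
it equals the predicted class. This rule is deterministic, needs no tree
cut, and is invariant to monotone height transformations. Queries
participate in the clustering, as they do in the real analyses.

## Subclass mapping

Cross-dataset correspondence cannot rely on absolute values; it relies on
within-dataset rankings. For candidate subclasses (≥ 10% of a dataset's
samples) of datasets A and B: markers(a_i) = top 100 genes by
signal-to-noise ratio (m_in − m_out)/(s_in + s_out), with each sd floored
at 0.2·|mean|; the enrichment of markers(a_i) near the top of B's
b_j-vs-rest ranking is the unweighted KS running sum (hit +1/|hits|,
miss −1/(N−|hits|); score = signed maximum deviation, magnitude ties
positive); its p-value comes from permuting B's group labels (1000
permutations, +1-corrected). The two directions are combined
conservatively as their maximum ("mutual enrichment"; Fisher combination
available), Bonferroni-corrected across the matrix, and thresholded:
strong < 0.05 ≤ weak < 0.10 ≤ none. A fixed marker count (not a
threshold) is used because ranks are cross-platform comparable and
absolute values are not.

## Bayesian probit metagene scoring

A two-class training set (pathway ON vs control in vitro, or resistant vs
sensitive lines) defines a signature: genes are standardized by training
mean/sd, the top k = 100 by |t| are kept, and the leading left singular
vector of the standardized submatrix is the metagene (n_factors
configurable, default 1). A probit regression of class on the factor
score(s), with independent N(0, 10²) priors, is sampled by the
Albert–Chib latent-variable Gibbs sampler (5000 iterations, 1000
burn-in, seeded; truncated-normal draws by inverse CDF). A new sample's
activation probability is the posterior mean of Φ(β₀ + β·score); > 0.5
calls the pathway active. When training arrays and tumors come from
different experiments, both are pooled and batch-adjusted
(train-vs-test as the batch) before the standardization is re-derived
from the adjusted training half.

With completely separated training classes the posterior is intentionally
diffuse inside the between-class gap, so samples scoring there get
honestly intermediate probabilities; crisp tumor probabilities therefore
require a training set large enough that the metagene does not overfit
training noise (see generator defaults below).

## Association statistics and functional class scoring

Kruskal–Wallis (tie-corrected, χ² p) and Mann–Whitney compare activation
or resistance probabilities between subtypes or clusters. Mann–Whitney
is exact by full enumeration for combined n ≤ 12 (ties get half-credit
U; two-sided by deviation from n₁n₂/2) and the tie/continuity-corrected
normal approximation otherwise. Activation-probability profiles are
clustered by complete linkage on Euclidean distance and cut at k = 7
pattern clusters by default (the count is config; a silhouette scan over
k = 2…10 is provided for transparency).

Functional class scoring: per-gene two-class t-test p-values; per set,
LS = mean of −ln p over members (natural log) and KS = max deviation of
member p-values from Uniform(0,1); both referred to `n_random` = 10 000
random same-size gene sets (+1-corrected). Sets with fewer than 2 mapped
genes are skipped with a warning.

## Synthetic cohort generator

One generated dataset contains, per sample: a subtype drawn from the
class-size table (default mirrors the largest real training cohort —
SYN 16, LEIO 17, LIPO 33, MPNST 6, FIBRO 7, RHAB 6 — plus 30 UNKNOWNs);
a disjoint 40-gene marker block per class shifted by the marker effect;
a 40-gene block shared by MPNST and SYN (making a one-step 6-class model
ill-posed by construction); three independent Bernoulli(0.5) pathway
states each shifting a 30-gene block by 1.5 log2 units, with the second
pathway also down-shifting a 50-gene "responsive" block (the
miRNA-target analogue used as the planted enriched gene set); i.i.d.
N(0, 1) noise; and, per dataset, additive N(0, 0.5²) and multiplicative
log-normal(0, 0.25²) per-gene batch effects. UNKNOWN samples draw a
latent subtype but have their subtype shifts multiplied by the
attenuation a ∈ [0,1] (default 0.5) — the simplest mechanism consistent
with reading unclassifiable tumors as partial dedifferentiation.
Per-drug resistance probabilities follow the probit link
Φ(α_d + Σ w_dp z_p) on the pathway states (the adriamycin analogue loads
on all three pathways), and binary resistance indicators are sampled
from them. Everything is reproducible from a single seed.

**Calibration of effect sizes.** The marker effect defaults to 3.5 log2
(~11-fold) over unit noise. This was set by an a-priori noncentral-F
power calculation, not by simulation tuning: with the table's class
sizes (smallest class n = 6 of N = 85) and the p ≤ 4×10⁻⁷ step-1 cutoff,
per-gene selection power is ≥ 0.95 for every block at δ = 3.5, whereas at
δ = 1.5 it is as low as 0.008 — no classifier could recover the planted
markers through a threshold that strict. Markers of tissue
differentiation (the genes such predictors actually select) are
routinely in the 8–15-fold range, so the default is biologically
reasonable as well as statistically necessary. Pathway blocks use
1.5 log2 in both the in-vitro training arms and the tumors, and the
in-vitro arms default to 35 arrays each: at 15 per arm the metagene
direction measurably overfits training noise, tumor scores land inside
the separable-training posterior gap, and posterior probabilities
flatten toward 0.5.

**What the generator does not emulate:** probe-level noise physics (dye
bias, spatial artifacts), correlated gene-gene structure beyond the
planted blocks, non-Gaussian heavy tails, class-dependent batch
composition, or copy-number/fusion events. Passing tests therefore show
that the algorithms recover the structure they assume, at realistic
sizes and batch magnitudes — not that the pipeline is robust to every
artifact of real microarray data.

## Problem sizes used in the checks

The self-checks run at the generator's default scale (2000 genes,
115 samples per dataset, two datasets for cross-dataset analyses;
100-permutation significance tests; 1000-permutation subclass mapping;
10 000 random sets for FCS). Null-calibration studies use a reduced
no-signal cohort (300 genes, six classes of 6, 39 permutations,
50 replicates) and, for the FCS type-I check, 200 random sets spread
over 10 independently generated null cohorts — independent cohorts
because p-values of sets evaluated on one realized gene-p landscape are
strongly correlated and a single-cohort estimate of the type-I rate
would be dominated by that shared randomness.

## Known limitations

- The co-clustering match rule is one explicit operationalization of
  "clusters together"; real studies have used informal visual criteria,
  so absolute match fractions are not directly comparable.
- The subclass-mapping internals (SNR ranking, unweighted KS, max
  combination) follow the published methodology's principles but are not
  a bit-for-bit reimplementation of any particular software.
- Probit probabilities are posterior means under a single-factor
  metagene; multi-factor signatures are supported but untested beyond
  smoke level.
- The permutation test's fallback selection makes the null statistic
  defined but slightly conservative relative to an oracle that could
  skip undefined permutations.
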