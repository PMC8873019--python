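# Methods

This note documents the statistical models, the synthetic-data generator
that stands in for the deposited study data, the numerical choices, and
the known limitations of each component.

## Study design and data model

The design is nested: genotype (CTRL / DEL / DUP, copy numbers 2 / 1 / 3
at a focal ~29-gene locus) → individual (3 per genotype) → iPSC clone
(2 per individual) → replicate (2 per clone), profiled at three stages
(iPSC, 1-month and 3-month organoids) by RNA-seq and, for the organoid
stages, TMT proteomics — 108 transcriptomes and 72 proteomes in the
default configuration. All mixed models in the package condition on this
hierarchy: repeated samples from one individual are not independent, and
treating them as such (pseudo-replication) is the main statistical hazard
the pipeline is built to avoid.

## Synthetic data generator

`cnvomics.simulate` emulates the study inputs with known ground truth.

RNA counts: for gene *g* in sample *s*,
`log2 μ_gs = b_g + cis_g(genotype) + Σ_m λ_g F_ms + u_ind + u_clone + ε`,
with gene baselines `b_g ~ N(8, 1.5²)` log2 counts, cis fold changes
0.5× (DEL) and 1.5× (DUP) on locus genes, latent per-sample module
activities `F_ms` driving within-module correlation (loadings
λ ~ U(0.5, 1)), and log-normal individual / clone / residual effects whose
variances are parameterized as fractions (`icc_individual`,
`clone_var_frac`; defaults 0.2 / 0.1, residual log2 SD 0.3). Counts are
gamma–Poisson (negative binomial) with dispersion 0.1 — the standard
generative model for bulk RNA-seq — and TPM is computed from counts and
gene lengths (`1e6·(c/l)/Σ(c/l)`; columns sum to 10⁶ exactly). The
baseline of 2⁸ counts for a median gene matches the per-gene depth of a
typical 25–30M-read library spread over ~15k expressed genes. Defaults
are the study conditions; tests that state their own conditions (e.g. a
pure planted-signal configuration) construct a `SimTruth` explicitly.

Proteomics: peptide log2 intensity = protein baseline + the same per-gene
genotype effect (proteins are named `P_<gene>` so cross-omics fold
changes are comparable) + a peptide random intercept (SD 0.5) + a run
offset + residual noise. Samples are assigned round-robin to TMT runs of
at most 8 biological channels; every run carries duplicate pooled
reference channels (131N/131C) holding the grand-mean signal plus the run
offset, which is exactly what multi-run normalization removes. Reference
channels are noise-free by default (`ref_noise_sd` exposes the knob); a
real pooled channel has measurement noise, which slightly degrades
normalization in practice.

What the generator does **not** emulate: read-level artifacts (GC bias,
mapping multi-modality), compositional library effects, missingness
patterns of data-dependent MS acquisition, isotopic impurity, and
outlier samples with structured (batch-like) failure modes. Passing
tests therefore demonstrate correctness of the statistical machinery
under the declared generative model, not robustness to every artifact of
real data.

## CNV post-processing

Coordinates are 1-based inclusive (size = end − start + 1). Stitching
joins two same-chromosome, same-type calls when the number of array
markers strictly between them is `< 0.5 × max(n_markers)` of the pair,
recursively to a fixed point; the merged call spans both, sums the two
marker counts (gap markers supported neither call) and keeps the maximum
confidence. Filters: size strictly over 100 kb, ≥ 8 markers, confidence
≥ 20, and at most 50% overlap with confounding regions (retained at
exactly 50%, per the "over 50%" reading). Burden selection uses the
fibroblast burden as the reference mean and the sample SD (ddof = 1)
across the patient's clone burdens; clones with Z strictly above 1.5 are
discarded, and a zero SD (all clones identical) retains everything with
a warning. Focal-CNV confirmation uses 50% reciprocal overlap, the
standard CNV-concordance convention. Whether the stitching gap should be
measured in markers or base pairs is ambiguous in the field; the marker
reading is implemented because the comparator ("markers within the
larger call") is itself a marker count.

## Expression QC and covariates

- Expressed genes: TPM strictly above 0.5 in at least 80% of the samples
  of **at least one** genotype group by default (preserves
  genotype-specific expression); an all-groups mode is available.
- Outliers: connectivity `k_i = Σ_{j≠i} cor(x_i, x_j)` standardized over
  samples; flag at `z < −2`, single pass. Pearson by default, bicor by
  flag. Zero-variance samples are auto-flagged.
- Clone-variance filter: per-gene nested ANOVA
  (individual / clone-in-individual / residual) by method of moments —
  exact for the balanced 2-clone × 2-replicate design and vectorized over
  genes; negative moment estimates clip to zero; a constant gene has
  clone fraction 0. Genes with clone fraction > 0.5 (configurable; the
  threshold is not a published value) are removed. Unreplicated clones
  or individuals left unusable by outlier removal are dropped from the
  decomposition with a warning.
- Surrogate variables: expression is residualized on the protected
  design (genotype); SVs are the leading residual principal components
  that survive permutation parallel analysis (20 permutations, 95th
  percentile, compared on variance *proportions* — comparing raw
  eigenvalues is biased because re-residualizing the permuted matrix
  shrinks total variance). This is a reduced re-implementation of
  surrogate-variable analysis: no iterative reweighting.
- Covariate selection: a reduced multivariate-adaptive-regression-splines
  forward pass. The basis pool per covariate is the linear term plus
  hinge pairs at quartile knots; bases are added greedily by total RSS
  reduction across genes while `GCV = RSS/(n(1−C/n)²)`,
  `C = M + 3(M−1)`, improves. A covariate is selected if any of its
  bases survives. No backward pruning pass.

## Differential expression (RNA)

The limma-voom strategy. Library-size-normalized `log2-CPM` with a
0.5-count offset; per-gene OLS residual SDs lowess-smoothed
(span 0.5) against mean log2-count on the quarter-root-variance scale;
per-observation weights = trend⁻⁴ at the fitted log2-count. The
consensus intra-individual correlation profiles the restricted
likelihood of a block-exchangeable correlation on a common ρ grid
(vectorized across genes; the per-gene REML maximizer is then combined
by a 10%-trimmed mean on the atanh scale and clipped to [−0.3, 0.99]).
Gene-wise estimates come from GLS after whitening with the Cholesky
factor of the block correlation and the gene's precision weights.
Residual variances are shrunk by moment-matching a scaled
inverse-chi-square prior on the log scale (digamma/trigamma equations;
the trigamma inverse by Newton iteration); moderated t uses `d₀ + d_g`
degrees of freedom. Contrasts are DEL−CTRL, DUP−CTRL, DUP−DEL; BH FDR at
10%. Locus genes are *not* excluded — the cis effect is a positive
control. The implementation was cross-checked against the R
limma/voom/duplicateCorrelation stack on identical input and agrees to
numerical precision (same ρ, fold changes, prior df and discovery set).
Known property shared with that stack: with only 9 individuals the
estimated ρ is noisy, and single-dataset type-I error at p < 0.05
fluctuates a few tenths of a percent around nominal because the
moderation hyperparameters couple all genes.

## Differential expression (protein)

Log2 transform precedes normalization and collapse (the median commutes
with monotone transforms, so collapse order does not change results;
normalizing on the log scale makes run offsets additive). Per run and
peptide the mean reference-channel log2 intensity is divided out and the
grand mean across runs restored — within-run contrasts are conserved
exactly, and equal sample/reference ratios across runs normalize to
equal values to floating precision. Repeated measurements of a subject
collapse to the median; the subject (individual) is then the
experimental unit, so the per-protein model needs no subject random
effect: `y_ps = μ + β·genotype_s + u_p + ε`, `u_p ~ N(0, σ_u²)` a peptide
random intercept, fitted by REML (statsmodels MixedLM). Contrast
p-values are likelihood-ratio tests from ML refits against the
constrained coding (χ²₁); measured null type-I at 9 subjects is ~0.05.
Single-peptide proteins and non-converging fits fall back to OLS and are
flagged. Missing peptide–subject cells are dropped, not imputed.

## Co-expression networks

Biweight midcorrelation (median/MAD weights `(1−u²)²`, `u = (x−med)/(9·mad)`,
Pearson fallback for zero-MAD genes), signed adjacency
`a_ij = ((1+cor_ij)/2)^β`. β is the smallest power whose scale-free fit
index — signed R² of `log10 p(k)` vs `log10 k` over 10 equal-width
connectivity bins, empty bins dropped — reaches 0.8, else the best power
with a warning. Topological overlap
`TOM_ij = (ΣA_iuA_uj + a_ij)/(min(k_i,k_j)+1−a_ij)` is clustered by
average linkage. Module detection is a **static cut**: candidate heights
(quantiles of the merge heights) are scanned and the cut producing the
most clusters of at least the minimum module size — ties broken toward
assigning more genes — is kept; weakly connected members (kME < 0.3) are
pruned; modules with eigengene dissimilarity below 0.1 merge
iteratively. A fixed single-quantile cut was tried first and discarded:
on planted three-module data it returns one giant module. The dynamic
hybrid tree cut's deep-split parameter is recorded in `NetworkParams`
for provenance but inert; planted-structure recovery, not label-level
parity with any specific cut heuristic, is the fidelity criterion.
Eigengenes are the unit-norm first PC of the standardized member
expression, sign-oriented to positive mean member kME.

Eigengene–genotype association fits `ME ~ genotype + (1 | individual)`
by REML; contrast p-values use a Wald t on between-individual degrees of
freedom (n_individuals − 3) — exact for the balanced nested design in
which genotype is constant within individual, and equivalent to a
Satterthwaite approximation here. A χ²₁ likelihood-ratio reference was
measured at type-I 0.14 with 9 individuals (the classic small-sample
anticonservativeness) and rejected. BH across modules per contrast,
significance at 10% FDR.

Preservation: for each reference module restricted to genes shared with
the test layer, the observed test-layer density (mean off-diagonal
signed adjacency) and connectivity preservation (correlation of
intramodular connectivities between layers) are compared with random
same-size gene sets (default 100 permutations);
`Z-summary = median(Z_density, Z_connectivity)`, with the usual
semantics Z > 2 evidence, Z > 10 strong. Two statistics rather than the
full multi-statistic battery; the connectivity statistic is only
informative when modules have hub structure (heterogeneous loadings),
and its permutation null is contaminated when a single module dominates
a small gene universe — density then carries the signal.

## Enrichment

Gene-set tests draw 1000 null lists matched to the target on the joint
10×10 decile grid of log gene length × GC fraction over the expressed
universe (joint, not marginal, binning — length and GC covary);
each target gene is replaced by a non-target gene from the same bin,
without replacement within a list, falling back to the Manhattan-nearest
bin when exhausted (fallbacks are counted). Empirical
`p = (1 + #{null ≥ obs})/(1 + N)` is never zero; BH across sets.
Focal-locus genes can be excluded from target, sets and nulls. The
matched null removes the length/GC confounding that makes uniform nulls
call any length-correlated set "enriched". Because overlaps are small
integers, the empirical p is discrete and slightly conservative for
small sets.

Cell-type enrichment: specificity `s_gc = m_gc/Σ_c m_gc` from a mean
expression matrix (all-zero genes dropped); the target's mean
specificity is compared with uniform random same-size gene sets
(default 10⁴ bootstrap replicates) giving a Z and empirical p, BH across
cell types. The bootstrap samples uniformly (the cited method's
non-length-corrected mode); the "Neuron" category in the reference
combines excitatory and interneurons.

## Phenotype computations

RNA–protein correlation: Pearson r of matched log2 fold changes, over
all shared identifiers, the union of RNA/protein discoveries
(q < 0.1 at either level), or excluding locus genes. Organoid sizes:
within each batch, large/small are diameters strictly beyond ±1 SD of
the batch mean (the Methods-text convention; a ±1 SEM variant is a flag
since the source figure legend disagrees with its methods text), medium
the rest; per-batch proportions are averaged across batches. ΔΔCt:
`ΔCt = Ct_target − mean(Ct_housekeeping)` per sample, `ΔΔCt` subtracts
the reference-group mean, fold change `2^(−ΔΔCt)`; samples missing a
housekeeping Ct are dropped with a warning.

## Pipeline

Stages (synth → cnv → qc → de → dep → net → enrich → integrate)
communicate only through declared files in the run directory; each stage
derives its own seed from the master seed and its name, so toggling a
stage does not shift another stage's random stream. The manifest records
a SHA-256 per output plus row counts; identical configs reproduce
identical hashes. Analyses are run per timepoint (default the 1-month
organoid stage), mirroring the per-dataset structure of the study design.
Default synthetic scale is 2000 genes and 300 proteins per run; tests
use smaller universes (400–600 genes) chosen so the full suite completes
in a few minutes on one CPU while keeping every planted-signal recovery
well-powered.

## Known limitations

- The consensus correlation ignores per-gene precision weights (it is a
  trimmed consensus across thousands of genes; the effect is
  negligible), and its grid resolution is ~0.03 in ρ.
- The method-of-moments variance decomposition assumes near-balance;
  strong imbalance after outlier removal uses average group sizes.
- The protein LRT relies on χ² asymptotics; with very few subjects a
  df-corrected test would be preferable (the eigengene association
  already uses one).
- Static-cut module detection does not reproduce dynamic-tree-cut labels
  on real data; it targets planted-structure recovery.
- The enrichment nulls match length and GC only; other covariates of
  detectability (expression level, mappability) are not matched.
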