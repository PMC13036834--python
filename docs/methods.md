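# Methods

This note documents the models, the default parameters and the numerical
choices behind `trisomics`, and states what the synthetic study generator
does and does not emulate.

## The synthetic trisomy study

`simulate_study` generates a paired bulk RNA-seq + methylation-array study
on a toy genome of 24 chromosomes (chr1..chr22, chrX, chrY) with
non-overlapping gene spans of 2 kb spaced 12 kb apart. Defaults describe a
fetal-thyroid-like cohort: 6 trisomic (DS) and 6 control samples, plus 2
DS-labelled contaminant samples and 1 deviant control appended as extra
columns, so that after quality control the analyzed set is exactly 6 vs 6.

**Expression.** Per-gene relative abundances are log-normal(0, 1); thyroid
marker genes (TPO, TG, TSHR, SLC5A5) are scaled ×50 and muscle markers
(MYH1, MYOD1) ×0.02, so a thyroid sample expresses the former and barely the
latter. Expected counts are `rel_g · L_s · 2^shift`, with per-sample library
sizes L uniform in [4, 6] million — the cohort-depth regime of a deeply
sequenced bulk study, scaled to the 2000-gene toy genome. Shifts (log2):

* **dosage**: +log2(1.5) for every chr21 gene in DS samples
  (`frac_chr21_dosage_affected = 1`: trisomy triplicates the whole
  chromosome; which genes *test* significant is a power outcome);
* **planted DE**: 130 non-chr21 genes at |log2FC| uniform in [0.32, 1.75]
  (fold changes 1.25–3.37×), random signs;
* **sex and batch**: per-gene N(0, 0.2) log2 coefficients for male samples
  and for a random half of samples (the surrogate-batch target);
* **quality factor**: every sample carries a score (sd 0.05) on a shared
  degradation-like gene profile; the outlier sample sits at score ±2.5 and
  additionally receives i.i.d. N(0, 1) per-gene log2 noise. A deviant
  sample must be deviant along a *shared* axis to be visible to a robust
  score distance — an isotropic pure-noise outlier is exactly what a
  MAD-maximising subspace is designed not to chase;
* **contamination**: contaminant samples swap the thyroid- and
  muscle-marker weights (expression side only; their methylation is
  unchanged).

Counts are negative-binomial with dispersion 0.02 (typical of deeply
sequenced bulk tissue; with 6 vs 6 samples this puts single-gene power for
a 1.5× effect near 80%, so that the mean fold change among *significant*
dosage genes stays close to 1.5 rather than being inflated by
selection on significance).

**Methylation.** 10 000 CpGs: 20 planted DMRs of 5 CpGs spaced 100 bp inside
the strand-aware promoters of 20 non-chr21 genes, the rest scattered around
genes with a bimodal Beta(0.4, 0.4) baseline; ~9% of background probes carry
one of the four exclusion flags (allosomal, chr21, polymorphic,
cross-reactive). DMR CpGs shift the group mean by ±0.15 on the β scale in
DS. Noise is logit-normal: N(0, 0.3) on logit(β), back-transformed, which
respects β ∈ [0,1]; each DMR also carries a per-sample random effect
(sd 0.1 on the logit scale, shared across its CpGs), giving regions
realistic sample-to-sample coherence. Sex and batch act on the logit scale
with sd 0.2.

**cis couplings.** The first 6 planted DMRs drive their host gene's
expression: the gene's log2 abundance moves by `6 · sign · (median latent
β − mean)`, with signs alternating so both repressive and activating
couplings exist. The truth ledger records every planted gene, region,
coupling and sample role.

All randomness flows from one root `SeedSequence`; identical configurations
give bit-identical studies.

**What the generator does not emulate:** read-level data, probe chemistry,
genomic correlation of expression, cell-type mixtures, copy-number events
other than whole-chr21 trisomy, and realistic between-gene covariance.
Passing the recovery tests therefore demonstrates that the estimators are
correct and calibrated under their assumed models — not that those models
capture every property of real tissue.

## Sample QC

The marker check flags a sample when its median log2-CPM over muscle
markers is ≥ the thyroid-marker median (ties flag — conservative). The
robust PCA then runs on the survivors only, using log2-CPM of *expressed*
genes (the ≥10-counts-in-≥4-samples prefilter; near-zero-count genes have
discrete log2-CPM values whose MAD would dominate the search) residualized
for condition and sex, so outlyingness is judged against within-group
variation. Grid projection pursuit: start from the coordinate axis with the
largest robust projection scale; sweep 10 angles per plane spanned with
each axis, keep the argmax of 1.4826·MAD, halve the aperture, 25 sweeps;
deflate and repeat for k = 2 components. A sample is an outlier when
`sqrt(Σ_j (score_j/scale_j)²) > sqrt(χ²_{k,0.975})`. The MAD objective has
appreciable sampling noise at n ≈ 10–150: its argmax direction typically
sits 5–15° from classical PC1 on clean data while attaining an equal or
higher robust scale, so tests compare achieved objective values, not tight
angles.

## Differential expression

Median-of-ratios size factors (genes with any zero excluded from the
reference; no pseudo-reference fallback). Per gene, an NB log-link GLM with
offsets log(sf) and design intercept + condition + sex (control is the
reference level: positive log2FC = up in DS), fitted by iteratively
reweighted least squares with expected-information weights `μ/(1+αμ)`.

**Dispersion** is *trended*: per-gene method-of-moments values
`(s²_resid − μ̄)/μ̄²` — computed from design-residual variance, so modelled
group structure is not counted as dispersion — are used only to fit
`α(μ) = a₀ + a₁/μ` by 30%-trimmed least squares; the trend supplies the
working dispersion for every gene. Plugging per-gene MoM values in directly
(or taking a max with the trend) is far too noisy at ~9 residual degrees of
freedom and destroys the calibration of the Wald test: the trend-only
estimator holds null type-I error at 0.045–0.069 across simulation seeds at
nominal 0.05 with a standard-normal reference.

Shrinkage: an empirical-Bayes normal prior N(0, τ²) with
τ² = Var(log2FC) − mean(se²) (moment matching; fallback median(se²) when
non-positive); the posterior mean `log2fc · τ²/(τ²+se²)` contracts noisy
estimates toward zero.

Chromosome enrichment: Pearson χ² without continuity correction on the 2×2
DEG × chr21 table; goodness-of-fit of per-chromosome DEG counts against the
expressed-gene distribution with chr21 excluded and expected cells < 5
pooled; and a homogeneity χ² of up/down counts across chromosomes (chr21
excluded, small rows pooled).

## Differential methylation

DMPs: per-CpG OLS of M-values on condition + sex + surrogate covariates,
t test with residual df. The surrogate is the first principal component of
the M matrix residualized on the *nuisance* design (intercept + sex) only:
estimating it from full-design residuals would force it orthogonal to
condition and leave any batch component chance-correlated with condition
(|r| ≈ 0.3 is routine at n = 12) inside the condition coefficient,
inflating type-I error. Δβ is reported as the raw group-mean difference on
the β scale.

DMRs: per-CpG condition coefficients on the β scale (covariate-adjusted
OLS), smoothed by a window-3 running mean within clusters of CpGs ≤ 500 bp
apart; candidates are maximal single-sign runs of ≥ 3 CpGs with smoothed
|coefficient| ≥ 0.05, scored by area = Σ|coefficient|. The null pools the
areas of all candidate regions over 100 *balanced* permutations of the
condition labels (pseudo-groups draw equally from each true condition, so
real effects cannot leak into the null; covariates stay attached to their
samples); p = (1 + #null ≥ area)/(1 + #null), BH-adjusted, significant at
FDR < 0.01. The pipeline runs bump hunting with condition + sex only: with
strong covariate adjustment the permutation null can become so sparse that
its p floor 1/(1+N_null) exceeds the calling level — a resolution limit of
the pooled-area null, not evidence — while unmodelled batch structure
enters the null conservatively.

## eQTM integration

Significant DMRs are paired with genes whose span ±2000 bp overlaps the
region; category promoter ([TSS−2000, TSS], strand-aware; wins ties),
gene body, or flanking. "Last-exon" style annotations require exon models
the package deliberately does not carry and fold into gene body. Per pair:
Pearson r between per-sample DMR median β and log2(count/sf + 1); 95% CI
from percentile bootstrap over paired resamples (degenerate zero-variance
resamples redrawn); two-sided permutation p by shuffling expression,
floor 1/(n_perm+1). The percentile bootstrap's true coverage at n = 9,
ρ = 0.6 is ≈ 0.904 — the expected small-n undercoverage of percentile
intervals. Scope is switchable: `deg-pairs` (DMRs × significant DEGs — the
cis DMR–DEG analysis) or `all-dmr-genes` (DMRs × every gene in the window),
because the former entangles eQTM recovery with the DEG threshold. Raw
p < 0.05 defines significance (matching the small number of tested pairs);
a BH column is provided as a convenience.

## Preranked GSEA

Ranking metric: Wald z (descending, ties broken by gene id; switchable to
shrunken log2FC). ES: weighted KS running sum with weight exponent 1. Null:
gene-label permutations (random same-size subsets of the ranked universe)
— appropriate for the preranked setting; a ~10-sample cohort is too small
for sample permutation. NES divides ES by the mean |null ES| of matching
sign, and p uses the sign-matched null tail with a +1/+1 correction.
Set-size bounds 15–500. Collapsing is greedy by ascending p at Jaccard ≥
0.5 (the clustering threshold 0.25 is a separate, looser notion used for
the connected-component clusters whose representative is the lowest-p
member).

## Pipeline

`run_pipeline` executes QC → DE (+ chromosome enrichment) → DMP → DMR →
eQTM → GSEA, derives independent child seeds for every randomized stage
from one root seed, writes each intermediate TSV plus a BED export of
significant DMRs, and records a manifest (parameters, seeds, input
checksums, per-stage counts). The pipeline is a pure function of (inputs,
config, seed); reruns are byte-identical.

## Problem sizes used in the test suite

Recovery and calibration tests run at the generator defaults (2000 genes /
10 000 CpGs / 15 samples); type-I checks use ≥ 2000 null features, 1000
null eQTM pairs and 500 null gene sets; DMR null specificity uses 20
effect-free studies of 3000 CpGs at 100 permutations each; bootstrap
coverage uses 2000 bivariate-normal replicates at n_boot = 2000. Bootstrap
and permutation counts are reduced from the production defaults (100 000 /
10 000) in tests; the estimators are identical.

## Known limitations

* The NB Wald test assumes the trended dispersion is shared by genes of
  equal abundance; strongly gene-specific overdispersion would be
  under-served (the classic trade-off of trended estimators at small n).
* Bump hunting reports no effect-size uncertainty for regions, and the
  pooled permutation p has a floor of 1/(1+N_null).
* The eQTM permutation null assumes exchangeability of samples; shared
  group structure between methylation and expression (two real effects on
  the same contrast, rather than a cis coupling) can produce significant
  correlations — an interpretive caveat inherent to the design, not a bug.
* The surrogate-variable estimate is a single residual principal component;
  multiple independent batch factors need `n_sv > 1`, which costs residual
  degrees of freedom quickly at n ≈ 10.
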