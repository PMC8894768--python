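# Methods

`aleuro` implements the computational analysis used to nominate candidate
regulators of microautophagy in the maize aleurone: consensus differential
expression between aleurone (AL) and starchy endosperm (ST), tissue-preference
scoring, co-immunoprecipitation (co-IP) confidence tiering against a
pre-immune control, GO enrichment, tonoplast-imaging statistics, and
comparative-Ct qPCR. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Expression summaries

TPM is computed from gene-level counts and annotated transcript lengths:
`TPM_gi = 1e6 (c_gi / L_g) / Σ_h (c_hi / L_h)`. This is a deliberate
simplification of alignment-level abundance estimation (effective lengths,
EM over multi-mapping reads); the package's input boundary is a count
matrix, so within-sample length normalization is all that remains.

Per (tissue, timepoint), a gene's summary TPM is the mean over biological
replicates **if and only if every replicate has TPM > 0**; otherwise the
gene is treated as not expressed (mean TPM = 0). This replicate-consistency
rule deliberately discards genes detected in only a subset of replicates.

The Compartment Correlation (CS) score of a gene is its summed mean-TPM
share attributable to one tissue over the analyzed timepoints:
`CS(ST) = Σ_t TPM_ST,t / Σ_t (TPM_ST,t + TPM_AL,t)`, so `CS(ST) + CS(AL) = 1`
whenever the gene is expressed at all; 0.5 marks tissue symmetry and is the
catalog boundary. The default uses post-rule per-timepoint means summed over
all four timepoints (8, 15, 18, 22 DAP); raw per-replicate sums are an
available alternative reading, selectable by summarizing without the rule.
Cross-tissue Pearson correlations use log10 of mean TPM and drop genes with
zero mean TPM in either tissue (log of 0 is undefined); base and
zero-handling are exposed as arguments.

## Consensus differential expression

Two independently implemented testing paths run per timepoint on the paired
design (each replicate block pairs one AL with one ST sample; design matrix
= intercept + block dummies + tissue indicator, AL = 1):

**NB-GLM path.** Counts are modeled as negative binomial with a quadratic
mean-variance relationship, Var = μ + φμ². Library-size offsets use
trimmed-mean-of-M-values (TMM) normalization: reference = column whose
upper quartile of scaled counts is closest to the mean upper quartile; 30%
two-sided trim on M, 5% on A; precision-weighted mean of the surviving M
values; factors rescaled to geometric mean 1 (verified against edgeR's
`calcNormFactors` to 1e-4 on fixtures). Dispersion is estimated in three
stages from the Cox-Reid adjusted profile likelihood (APL = NB log
likelihood at the IRLS-fitted means minus ½ log det X′WX), evaluated on a
25-point log-spaced grid with parabolic refinement: a *common* value
maximizing the summed APL; a *trend* (lowess, span 0.5) of per-gene
maximizers against average log-CPM; and *tagwise* values maximizing
`APL_g + (prior_df / residual_df) × APL_shared`, where APL_shared is a
moving average of neighbours' APL over the abundance ranking (window = 10%
of genes, minimum 5) and prior_df = 10 — a fixed-prior squeeze toward the
local trend. Gene-wise GLMs are fitted by vectorized IRLS (log link,
dispersion held fixed, max 50 iterations, relative deviance tolerance
1e-8, linear predictor clipped at offset ± 30); the tissue effect is tested
by a likelihood-ratio test against χ²(1), and log2 fold change is the
tissue coefficient / ln 2. Non-converged genes get p = NA and are excluded
downstream.

**Precision-weighted path.** log-CPM = log2((count + 0.5) /
(effective libsize + 1) × 1e6). Gene-wise unweighted linear fits give
residual standard deviations; a lowess (span 0.5) of √sd against average
log2 count is the mean-variance trend, and each observation's weight is the
inverse fourth power of the trend value at its fitted log-count. Weighted
least squares is followed by empirical-Bayes moderation: prior df d₀ and
prior variance s₀² come from a closed-form method of moments on the log
residual variances (digamma/trigamma moment equations; trigamma inverted
by Newton iteration); the posterior variance is
`(d₀s₀² + d s²)/(d₀ + d)` and the moderated t has d₀ + d df. When the
moments imply no excess spread, d₀ = ∞ and every posterior variance equals
the prior (normal reference distribution).

Both paths feed Benjamini-Hochberg step-up FDR control (implemented
directly; exact against a brute-force oracle). BH is used everywhere; it is
reproducible without tuning and conservative relative to q-value
approaches. A gene is a **consensus DEG** when both paths give FDR ≤ α
(default 0.05), both |log2FC| exceed log2(min_fold) (default fold 2) on
each path's own estimate, and the signs agree. Consensus genes whose mean
TPM is 0 in either tissue at the tested timepoint are then eliminated
(`eliminated_zero_tpm`); the stricter any-replicate-zero reading is
available via `elimination="any_replicate"`.

Genes too sparse to test (fewer than 10 reads in fewer samples than the
smallest tissue group) are removed before testing; calibration statements
refer to tested genes.

## Co-IP tiering and tonoplast enrichment

One is added to every abundance before dividing, so per-replicate fold
differences `(a_IP + 1)/(a_PI + 1)` are always defined and positive. Tiers
follow the three-replicate rule exactly: *high* = fold difference ≥ 2 in at
least two of three replicates; *medium* = exactly one replicate ≥ 2 and
never detected (abundance 0 in all replicates) in pre-immune serum; *low* =
everything else. Fold differences are per-replicate, not
replicate-averaged — the tier rule's "two out of three biological
replicates" reads most naturally per replicate; averaging first is a
one-line sensitivity variant.

Enrichment of predicted tonoplast proteins among detected proteins is a
one-sided (greater) Fisher's exact test on the 2×2 detection × prediction
table. The headline fold-enrichment statistic is the sample odds ratio
a·d/(b·c): on the study-scale counts (39,465 genes, 2% predicted, 881
detected, 166 overlap) it evaluates to ≈ 14.1, matching the "~14-fold"
framing, whereas the raw proportion ratio (18%/2%) gives 9. The conditional
MLE odds ratio is reported as a secondary field. The predicted-tonoplast
background is an input list, never a constant.

## GO enrichment

Annotations obey the true-path rule (bottom-up union over the child→parent
DAG; cycles are an input error). *classic* mode scores each term with the
hypergeometric upper tail. *weight01* decorrelates nested terms: processing
children before parents (lexicographic tie order, so runs are
deterministic), a term's provisional p is computed from pseudocount-free
weighted counts; any child already more significant down-weights its genes
by the log-p ratio `log p_parent / log p_child ∈ (0, 1)` before the parent's
p is recomputed. Leaves therefore coincide with classic, and a parent whose
signal lives in one enriched child cannot out-rank that child. Only is_a
edges and a single aspect (cellular component in the motivating study) are
modeled. BH FDR is applied over all returned terms.

## Imaging

The fold enrichment of a tagged protein at the engulfment domain is the
mean intensity over unsaturated engulfment positions divided by the mean
over unsaturated positions elsewhere on the traced tonoplast. Because the
engulfing domain consists of two closely apposed membranes, an evenly
distributed protein yields an expected ratio of exactly 2 — the analytic
null; genuine per-membrane enrichment by a factor E yields 2E. Saturated
positions (≥ a configurable ceiling, default 4095 = 12-bit) are excluded;
a domain with no unsaturated positions makes the ratio undefined (error
naming the domain). Background is not subtracted by default (the ratio is
not background-invariant, so a constant-background parameter is exposed).
Domain boundaries are supplied labels, as in manual tracing; the 2-D path
samples a supplied polyline trace with nearest-pixel lookup and reduces to
the 1-D case. Ratios are computed per vacuole and pooled by median.

Bulb frequency is the percent of protoplasts showing rounded tonoplast
invaginations per construct, with fold change against a control construct
(undefined and flagged when the control has none). ROI co-localization is
plain Pearson correlation over mask pixels.

## qPCR

Comparative-Ct with the reference gene (Ubc9 in the motivating study):
technical replicates averaged per (gene, tissue, biological replicate);
ΔCt = Ct_target − Ct_reference; ΔΔCt across tissues; fold = E^(−ΔΔCt) with
amplification efficiency E = 2 by default (primers verified at 90-110%
efficiency justify the perfect-doubling default; E is a parameter). The
summary is the mean of per-biological-replicate folds, matching a
mean-of-three-replicates protocol; the fold of the mean ΔΔCt is reported
alongside.

## Synthetic data: what it emulates and what it does not

The generators are first-class, tested code and define the study
conditions:

* **RNA-seq**: NB counts (Var = μ + φμ², φ default 0.1, φ = 0 gives
  Poisson), log-normal relative abundances (sdlog 1.5 — heavy tail, as in a
  storage-protein-dominated transcriptome), paired design with a
  gene-specific block effect (sd 0.1 on log2 mean) shared by each AL/ST
  pair, library sizes uniform in 0.8-1.2 million, planted DE genes
  (fraction 0.1, |log2FC| 2, random signs, effect applied in AL against a
  fixed composition denominator so planted ratios are exact), and a planted
  storage-protein class whose ST share compounds 8× per timepoint step
  (AL at the 0.75 power — growing but more modest), echoing the rise of
  storage-protein transcripts across 8→22 DAP. Replicate counts are
  configurable (the source datasets mix 3 external and 2 in-house
  replicates; the default is 3 per tissue per timepoint).
* **Co-IP**: log-normal baselines (meanlog 4, sdlog 1), IP abundance =
  enrichment factor (default 10) × baseline for planted tonoplast proteins
  (default 20% of the universe), multiplicative log-normal noise (sdlog
  0.2), independent Bernoulli dropout (rate 0.1) of every measurement —
  dropout rates reproduce two-or-more-replicate detection percentages in
  the observed 72-85% regime.
* **GO**: a rooted, layered DAG (50 terms, depth 4, 1-2 parents per term),
  every gene annotated to ≥ 1 leaf, two planted enriched leaves whose
  members make up ~2/3 of the study set.
* **Imaging**: 1-D profiles with constant per-membrane baseline (100 a.u.),
  an engulfment span at 2 × factor × baseline, Gaussian noise (sd 5),
  saturation clipping; an optional 2-D ring renderer for the trace-sampling
  path.
* **qPCR**: Ct = base − log2(expression) + noise (sd 0.2 cycles), reference
  gene expressed equally in both tissues, 3 biological × 3 technical
  replicates.

Real data differ in ways the generators do not model: GC and length biases,
correlated (not independent) proteomics dropout, batch structure beyond a
single block effect, optics (no PSF in image synthesis), and spectral-level
MS noise. Passing the recovery tests demonstrates the estimators are
correct under the stated models, not that they are robust to artifacts
outside them.

The end-to-end simulation couples the two omics layers: planted tonoplast
proteins are mapped onto AL-up DE genes, so their CS(AL) ground truth is
`2^effect / (2^effect + 1)` = 0.8 at the default effect, and funnel
sensitivity is measurable against the planted set.

## Numerical choices and degenerate inputs

Seeding is hierarchical (`default_rng([seed, stream])` per generator), so
datasets are independent but jointly reproducible; identical (seed, config)
pairs give byte-identical outputs, including the full pipeline's written
tree. Ties in BH and in the weight01 term order are broken stably
(mergesort; lexicographic ids). All-zero samples yield zero TPM with a
warning; all-zero genes are excluded from dispersion estimation; an
all-saturated imaging domain, an empty study set, a missing reference gene,
a non-paired block, and a cyclic ontology each raise a specific error
rather than propagating NaNs.

## Problem sizes

The shipped tests run the calibration and recovery studies at 5,000 genes
(null) and 2,000 genes (planted) with 3 paired blocks, 300-protein co-IP
universes, 50-term ontologies and 20-25 imaging profiles per condition;
the full pipeline example runs at 600 genes × 24 samples. These sizes give
stable statistics (KS at the 1% level, FDR/sensitivity margins) while the
whole suite completes in well under a minute of compute.

## Known limitations

Isoform-level quantification, batch correction, alignment, spectral search,
amplification-curve fitting, and segmentation are all outside the input
boundary. The dispersion squeeze uses a fixed prior df (10) rather than
estimating it; the weight01 variant implements the ratio rule only (no
elim cutoff parameter); Fisher enrichment assumes a well-defined universe
size supplied by the caller.
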