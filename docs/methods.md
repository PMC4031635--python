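# Methods

`locusscan` implements the statistical core of a deep-resequencing study
of a single genomic region: a few thousand SNPs typed in case-control
cohorts, analysed for single-variant association, aggregate rare-variant
burden, within-family co-segregation, and saturation of variant
discovery. This note records the models, the defaults and why, the
numerical choices, and what the bundled synthetic-locus generator does
and does not emulate.

## Data model

Variants are biallelic SNPs. Dosages are stored oriented to the VCF ALT
allele; every statistic operates on *minor*-allele dosages, with the
orientation fixed once per variant from the full-sample allele frequency
(`minor_is_alt`, ties at f = 0.5 resolved to ALT so orientation is
deterministic). "Common" means MAF ≥ 0.01 exactly; "rare" is MAF < 0.01.
Functional membership is seven boolean classes (exon incl. UTR, coding,
non-synonymous, conserved, regulatory potential, conserved TFBS, CpG
island) assigned by interval overlap against BED tracks: a 1-based
position p is inside a 0-based half-open interval (start, end] iff
start < p ≤ end. Consequence labels (non-synonymous, coding) are
consumed as input; the hierarchy nonsyn ⇒ coding ⇒ exonic is enforced
after track overlap. An optional exclusion track (e.g. repeat-masked
regions) drops variants with the same overlap rule before analysis.

## Single-variant association

Case-control tests are allelic: the 2×2 table of minor/major allele
counts in cases vs controls, tested with the two-sided Fisher exact test
(point-probability definition: sum of hypergeometric point probabilities
not exceeding the observed one, with the conventional 1 + 1e-7 relative
slack for float ties). A genotypic test is deliberately not the default;
the allelic table is the form whose counts the results report. Odds
ratios carry Woolf confidence intervals,
exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); a zero cell triggers the
Haldane-Anscombe +0.5 correction and is flagged.

Region-wide significance is max-T permutation: case/control labels are
permuted R times preserving group totals ("all cases" pools the three
diagnoses against controls without preserving subgroup sizes), the
minimum raw p across the region is recorded per permutation, and
p_regionwide(v) = (1 + #{r : min_p_r ≤ p_raw(v)}) / (R + 1). The
plus-one correction keeps empirical p-values off zero and makes the test
exactly valid. Empirical 5%/1% thresholds are the lower empirical
quantiles of the min-p distribution, i.e. values actually attained by
permutations. Implementation detail: because the total minor-allele
count and the per-variant missingness pattern are fixed under label
permutation, the Fisher p for a permuted dataset depends only on
(a, case-alleles); p-values are read from cached hypergeometric tables
(built by sorted cumulative sums, O(K log K) per margin set), which the
tests verify agree with the direct Fisher computation.

Quantitative traits use two-stage least squares: the trait is
residualised once on age + sex (with intercept, via OLS), then residuals
are regressed on dosage per variant. Permutation shuffles the residual
vector — stage-2 exchangeability is valid because the covariate design
is fixed across permutations — and compares dosage-residual correlations
(monotone-equivalent to the t statistic at fixed n, so the permutation p
is identical). Two-sided mode compares |corr|, one-sided modes the
signed value; the two-sided empirical p is invariant to affine
transformations of the trait.

LD between two sites is the squared Pearson correlation of dosage
vectors on jointly non-missing samples; undefined (error) if either
vector is constant.

Pedigree co-segregation is a descriptive count: members with known
carrier status and diagnosis are cross-classified, "perfect" means all
affected are carriers and all unaffected are non-carriers with at least
one affected carrier, and consistency is the diagonal fraction. The
affected-label set is an argument because diagnostic boundaries (e.g.
whether an anxiety-spectrum diagnosis counts) are an analysis choice.

## Burden and variable-threshold tests

The per-individual score at threshold T is s_i(T) = Σ over subset
variants with MAF ≤ T of the minor-allele dosage (missing contributes
0). MAF for thresholding is computed on the combined analysis sample.
BURDEN fixes T (default 0.5 = all frequencies); its reported effect is
the *average excess*: mean s in cases minus mean s in controls (or the
regression slope of residualised trait on score in quantitative mode).
VT scans all distinct subset MAFs, maximising a correlation-form score
statistic z(T) = corr(phenotype, s(T))·√(n−1); any statistic monotone in
the centred cross-product gives the same permutation p, so the form is
presentation-level. Ties at the maximum resolve to the smallest
threshold (most parsimonious subset). Each permutation re-maximises over
all thresholds — that re-maximisation is the multiple-threshold
correction, and with a single distinct MAF the VT test reduces exactly
to BURDEN (identical statistic and p at the same seed). All burden
p-values are one-sided: excess in cases, or the configured tail for
traits (default hypothesis: more minor alleles worsen symptom scores,
"upper", and lower cognitive scores, "lower"). No correction is applied
across the subset × diagnosis grid; results are nominal and the grid
runner logs the grid size as a caveat.

## Mark-recapture pool estimation

Discovery by two independent studies is treated as two capture
occasions. Lincoln-Petersen is N̂ = n1·n2/m (undefined at m = 0, raising
a zero-overlap error); Chapman's modification
N̂ = (n1+1)(n2+1)/(m+1) − 1 with variance
(n1+1)(n2+1)(n1−m)(n2−m)/((m+1)²(m+2)) is the default, defined at m = 0
and never exceeding Lincoln-Petersen. The 95% CI is the normal
approximation N̂ ± 1.96·SE, truncated below at the observed union; a
log-scale CI on the undetected count is available for small m.
Estimation is per MAF stratum (default ≥1% vs <1%) because catchability
differs sharply with frequency; stratum totals and variances are summed
under an independence assumption — correlation induced by shared samples
is a known limitation of that total. The undiscovered fraction is
max(0, 1 − known/N̂), clamped with a warning if the estimator
undershoots the observed union.

## QC calibration

The quality-threshold calibrator takes validated records (site quality,
confirmed/refuted) and returns the smallest observed quality whose
retained set meets a target false-call rate — scanning ascending
qualities maximises retention; infeasibility raises an error carrying
the best achievable rate. The original multi-variable filters (depth,
strand balance, mapping quality) are not recoverable from a published
analysis, so the single scalar axis is the documented abstraction and a
grid search over arbitrary per-site feature columns is provided for
richer spaces. Differential missingness is screened per variant by
Fisher's exact test on (called, missing) × (case, control), flagged at a
Bonferroni-corrected 0.05 (conservative by design; the threshold is an
argument).

## Synthetic-locus generator

The generator is a stated world, fixed up front, providing ground truth
for every downstream stage.

* **Frequencies.** `neutral`: allele count i on 2N chromosomes with
  P(i) ∝ 1/i, f = i/(2N); its singleton fraction has the closed form
  1/H_{2N−1}, used as a test oracle. `beta`: f ~ Beta(a, b).
  `disc1_like`: a two-component log-uniform mixture with 2010/2718 ≈ 74%
  of sites below 1% MAF — a rare fraction that a small-2N neutral
  spectrum cannot produce, so the empirical mixture is used when the
  locus-scale rare:common split matters.
* **Cohorts.** Genotypes are Hardy-Weinberg Binomial(2, f_v). Affection
  follows logit P(case) = α + Σ log(OR_v)·g_iv with α = −2.2
  (≈10% pooled lifetime prevalence); case/control quotas (default
  240/221/192 cases and 889 controls) are filled by rejection sampling —
  exact case-control ascertainment — with a draw budget that raises an
  ascertainment error when quotas are unreachable. A case is assigned
  uniformly at random among unfilled diagnosis groups (the generator
  models one liability, not diagnosis-specific architectures). Traits
  are y = Σ β_v g_iv + γ_age·age + γ_sex·sex + ε, ε ~ N(0, σ²), ages
  uniform on 69–71 years (a single-year birth cohort at assessment age),
  sex Bernoulli(1/2) coded M=0/F=1.
* **Capture.** A study detects a site iff ≥1 minor allele appears among
  Binomial(2n, f) sampled alleles *and* an independent
  Bernoulli(sensitivity) call succeeds. Stratum membership uses the
  study-A sample frequency (folded), since true frequencies are
  unobservable; the choice only matters near the 1% boundary.
* **Pedigrees.** Nuclear families: founders Hardy-Weinberg, children
  inherit one uniformly chosen allele per parent, affection
  Bernoulli(penetrance[genotype]).
* **Seeding.** One master seed; per-stage streams derived with fixed
  `SeedSequence` spawn keys, so every generator is bit-reproducible and
  stages are independently reproducible.

What the generator does *not* emulate: linkage disequilibrium between
sites (sites are independent), population structure and relatedness,
genotyping error and quality-dependent missingness (missingness is
injected directly where tested), diagnosis-specific genetic
architectures, and catchability variation beyond the binomial sampling
model. A green calibration test therefore establishes correctness of
the statistical machinery under exchangeability and HWE, not robustness
to structure or LD.

The capture-coverage simulation draws frequencies from a neutral
spectrum with 2N = 400 reference chromosomes (the scale of a sequenced
European reference panel of a few hundred diploids). This keeps
per-site detection probability near-homogeneous within strata, which is
the model under which the Chapman CI is derived; with strongly
heterogeneous catchability (ultra-rare variants at large 2N) Chapman is
biased downward and its CI undercovers — the known caveat for real
rare-variant pools, and the reason the rare-stratum pool estimate should
be read as a lower bound.

## Numerical choices

* Permutation counts R ≥ 100 are enforced for region-wide scans;
  empirical p-values always use the (1+b)/(R+1) form.
* Permutation exceedance comparisons use a 1e-12 absolute guard so that
  float noise cannot flip exact ties.
* Degenerate inputs: all-missing sites raise; monomorphic sites yield
  p = 1 with an undefined-OR flag (scan) or NA with a reason (trait
  scan, burden); constant burden scores at every threshold yield NA;
  zero-margin 2×2 tables return p = 1 with a warning.
* Multi-allelic and indel VCF records are skipped with a warning by
  default; strict mode raises.
* Reference-panel overlap matching is by (chrom, pos, ref, alt) when
  panels are merged externally; the bundled VCF flag (`PANEL`) is
  consumed as given, with position-only matching left to the caller.

## Known limitations

Stratified totals assume independent strata; the capture model has no
per-site sensitivity variation beyond the global Bernoulli; the burden
engine's quantitative mode residualises on age and sex only (other
covariates require pre-residualised traits); and the generator's
liability model is single-trait logistic, so it cannot express
cross-diagnosis genetic correlation.
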