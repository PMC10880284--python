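# Methods

## The analysis model

The package treats a small number of genetic variants as instruments
for a standardized exposure and composes five summary-data analyses
around them.

**Instrumental assumptions.** Each instrument must associate with the
exposure, share no confounder with the outcome, and affect the outcome
only through the exposure. The package does not test the second
assumption; the third is probed indirectly by the stratified check
(an effect driven by the exposure should vanish in a stratum where the
exposure pathway is inactive) and by colocalization (a shared causal
variant argues against confounding by linkage disequilibrium).

**IVW estimator.** With harmonized per-variant effects
(β̂_exp,j, β̂_out,j), the Wald ratio r_j = β̂_out,j/β̂_exp,j estimates the
causal effect per SD exposure. The inverse-variance weighted estimate
uses first-order weights w_j = β̂²_exp,j/se²_out,j, which ignore
exposure-side sampling error (the NOME approximation — adequate when
instrument F-statistics are large; at the default regime F ≈ 60–80 the
residual weak-instrument bias is ≈ 1% of the effect). Heterogeneity is
summarised by Cochran's Q = Σ w_j (r_j − θ̂)², χ²(J−1) under
homogeneity. The reported standard error is multiplicative
random-effects: the fixed-effect SE inflated by max(1, √(Q/(J−1))), so
under-dispersion never shrinks it below fixed effects. With a single
instrument the estimate and SE are exactly the Wald ratio's. P-values
use the normal reference throughout, the summary-data convention. For
two-instrument analyses both the fixed-effect and random-effects SEs
are carried in the result, since with one degree of freedom the
distinction is material.

**Harmonization.** Outcome records are re-expressed on the exposure's
effect allele: swapped allele order negates the outcome beta and
complements its frequency; when neither orientation matches, the strand
complement is tried. Palindromic variants (A/T, C/G) carry no strand
information in their allele labels, so they are resolved by effect-
allele frequency — kept only when both frequencies are present and both
minor-allele frequencies are below 0.42, otherwise excluded with reason
`palindromic_ambiguous`. The 0.42 ceiling leaves a margin before
frequencies become uninformative at 0.5; neither default instrument is
palindromic, so this matters only for general inputs. The test suite
asserts that no sequence of relabellings can move an IVW estimate by
more than 1e-12 — allele bookkeeping must be pure bookkeeping.

**PheWAS.** The weighted GRS sums trait-increasing-allele dosages
weighted by the exposure GWAS betas, then is standardized. Each binary
phenotype with at least 200 cases is fit by logistic regression on the
GRS plus age, sex and 10 principal components. Benjamini–Hochberg is
the FDR procedure (the field default where only "5% FDR" is specified),
computed over exactly the eligible, converged fits; non-converged or
separated fits are flagged and excluded from the multiplicity set
rather than assigned p = 1, which would deflate the q-values of real
signals. The logistic solver is a Newton–Raphson IRLS written for the
scan regime (thousands of fits sharing one design matrix); it is
verified against an independent GLM implementation to 1e-8 on fixtures.
Phecode-system control-exclusion ranges are not modelled; an optional
per-phecode sex filter is accepted as input but never inferred.

**Mediation.** Two-step network MR: a = exposure→mediator (exposure's
instruments), b = mediator→outcome (the mediator's instruments, clumped
at p < 5×10⁻⁸ and pairwise r² < 0.01), t = exposure→outcome. Indirect
effect a·b with SE √(a²se_b² + b²se_a²); proportion mediated a·b/t with
the ratio delta-method SE; all three estimates treated as independent
(distinct samples), hence no covariance terms. The proportion's CI is
symmetric and untruncated — values outside [0, 1] are informative. Both
SE variants (propagating denominator uncertainty or not) are computed;
the default propagates both and the output labels which was used. The
exposure's own instruments are excluded from the mediator-instrument
candidate set: they associate with the mediator through the exposure
itself, and using them in step 2 would fold the exposure's direct path
into the mediator→outcome estimate. The delta-method intervals are
accurate when the denominator's coefficient of variation is below
about 0.2; the generator's default scales respect that regime, and the
tests verify 5% agreement with Monte-Carlo oracles inside it.

**Colocalization.** Per-SNP evidence is the Wakefield approximate Bayes
factor, log ABF = ½[log(1−r) + r z²] with r = W/(V+W); prior effect SDs
default to 0.15 (per-SD units) for quantitative traits and 0.2 (log-OR)
for case-control, with per-SNP causal priors p1 = p2 = 1e-4,
p12 = 1e-5 — the conventional defaults of the standard coloc software,
all overridable. Hypothesis evidences are accumulated in log space; the
H3 (distinct causal variants) term is computed as a pairwise
log-sum-exp over j ≠ k rather than the algebraically equivalent
log-space subtraction, because the subtraction degenerates when one SNP
carries essentially all evidence for both traits. This costs O(m²) but
is exact; regions beyond a few thousand SNPs would want the subtraction
form. A single-SNP region has PP3 = 0 structurally. The enumeration
oracle recomputes all five evidences by explicit configuration loops in
plain extended-precision (80-bit) arithmetic and must agree with the
log-space path to 1e-10; it is restricted to m ≤ 20. All five
posteriors are always reported — no single "colocalization probability"
is privileged, though PP4 is the shared-variant hypothesis.

## The synthetic generator

`SimConfig` fixes the generative model; the defaults are the study
conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| instrument EAFs | 0.27, 0.37 | placeholders (not published for the design's variants); configurable |
| instrument R² | 0.76%, 0.56% | the exposure variance explained by the two instruments |
| exposure GWAS n | 10,000 | the plasma-caffeine GWAS scale (~9,876) |
| direct effect θ | −0.07 log-OR/SD | with γ·δ gives total −0.105 (OR ≈ 0.90/SD) |
| exposure→mediator γ | −0.20 SD/SD | mediation-chain step 1 |
| mediator→outcome δ | 0.175 log-OR/SD | step 2; makes the mediated share exactly 1/3 |
| outcome GWAS n, case fraction | 800,000, 0.21 | the osteoarthritis meta-analysis scale; keeps the total-effect CV ≈ 0.2, inside the ratio-delta validity regime |
| mediator GWAS n | 806,834 | the BMI meta-analysis scale |
| omics panel n | 35,000 | protein-panel scale; panel sizes 4,907/249 configurable |
| consumer fraction | 0.8 | roughly the share of consumers in a European-ancestry cohort |
| abstainer attenuation | 0.0 | the genotype→exposure path is fully disabled in abstainers (clean stratified truth); partial attenuation is a config option |
| region LD | AR-1, decay 0.9, m = 200 | one-parameter, positive semi-definite by construction |
| causal |z| | 8 | a clearly genome-wide-significant regional signal |

Instrument per-allele effects are derived from the target R² via
β = √(R²/2f(1−f)). Binary outcomes are logistic draws, so configured
log-ORs are exactly the estimands of the scan (a liability-threshold
model would have made them attenuated versions). Cohort covariates
(age, sex, PCs) are drawn independent of genotype — they exist to
exercise the adjustment machinery, not to create confounding. H3
regions place their two causal variants subject to r² < 0.2 between
them; with AR-1 decay 0.9 an unconstrained draw would often put them in
near-perfect LD, which is the shared-variant scenario in all but name.
Omics-panel and mediation-chain estimates are generated directly at the
summary level (β̂ ~ Normal(truth, SE(n))), the exact sampling model of
two-sample MR; LD-tagged mediator instruments share scaled effects but
their sampling errors are drawn independently, a simplification that
does not disturb the step-2 ratios.

What the generator does **not** emulate: real phenotype prevalences and
their phecode hierarchy, real LD panels or allele-frequency spectra,
sample overlap between GWAS sources, population stratification, or
assortative mating. Passing tests therefore demonstrate that the
estimators have their advertised operating characteristics under the
stated model — not that any real-data finding is reproduced.

## Numerical choices

Logistic IRLS starts at the intercept-only solution, converges on a
1e-10 step norm within 50 Newton iterations, and declares separation on
a singular information matrix mid-path or coefficient magnitudes above
50 on the log-odds scale. A rank-deficient design at the first
iteration is an error, not a flag. Zero-variance raw scores are
detected by exact range (a constant vector's floating-point standard
deviation can be ~1e-17, not 0). LD matrices are symmetrised and their
diagonals pinned to 1 after an 1e-8 tolerance check. BH q-values come
from statsmodels' `fdr_bh`, which the tests cross-check against a
textbook step-up implementation. All report files serialise floats at
fixed precision and carry no timestamps, so fixed-seed reruns are
byte-identical; the provenance block records the config hash (output
paths excluded — a location is not a scientific input), seed and
library versions. Randomness flows from a single integer seed through
named `SeedSequence` sub-streams per generated product, and replicate
studies derive one child seed per replicate.

## Study sizes

The calibration studies (`mendelscan.calibration`, also behind
`scripts/acceptance.py`) run at desk scale, chosen so the full battery
completes in a few minutes on one CPU: 1,000 replicates for IVW bias
and coverage, 2,000 for Q calibration, 500 for mediation recovery,
100 random small regions for oracle agreement, 200 each for
colocalization discrimination, stratified attenuation and the
bidirectional null, and 25 all-null PheWAS scans of 300 phecodes at
n = 20,000 (≈ 6,000 logistic fits). One PheWAS subtlety: with every
phecode null, each scan's false-discovery proportion is a 0/1 indicator
whose expectation equals the BH target, so the test compares the event
count to that bound with an exact binomial test rather than comparing a
noisy mean to its own expectation.

## Known limitations

Only the multiplicative random-effects IVW is provided — no MR-Egger,
weighted median, or correlated-instrument generalisation, and no
Steiger filtering; with two instruments those diagnostics would be
uninformative anyway. Colocalization assumes at most one causal variant
per trait per region. The mediation decomposition is a single-mediator
product-of-coefficients with independent-sample error propagation; no
multivariable MR adjustment is attempted. The PheWAS treats phecodes as
exchangeable binary outcomes. GWAS-VCF, BGEN and liftover are out of
scope: inputs are plain TSVs in the documented schemas.
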