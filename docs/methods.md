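# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Synthetic cohort

The generator (`ldridge.simulate`) emulates a biobank-style case/control
cohort in which a binary drinking status and a quantitative serum enzyme
(γ-GT, U/L) share genetic causes inside one LD-dense block.

**Genotypes.** A `HaplotypePool` specifies two focal loci by their four
haplotype frequencies (h11, h12, h21, h22) = (ref-ref, ref-alt, alt-ref,
alt-alt), so D = h22 − p_A p_B, D′ and r² = D²/(p_A q_A p_B q_B) are known
in closed form before any sampling. The default focal pair
(0.7079, 0.0021, 0.0021, 0.2879) gives alt-allele frequencies 0.29 at both
loci and r² = 0.9797. Flanking proxy loci copy their nearest focal allele
with probability ρ^d (d = distance in locus steps) and are otherwise
redrawn from the focal allele frequency, so haplotype correlation with the
focal locus is exactly ρ^d and decays monotonically. (A copy-or-*flip*
mechanism was rejected: for ρ^d < 0.5 it anti-correlates the flank and at
large distance approaches a deterministic flip, i.e. |r| → 1 rather than
0.) Individuals receive two independent haplotypes per block, so
Hardy–Weinberg holds marginally by construction; null SNPs are independent
binomial(2, maf) draws. For calibration studies there are two auxiliary
samplers: independent SNPs, and a first-order Markov haplotype process
(allele copies its left neighbour with probability equal to the decay
parameter) that yields LD blocks with correlation falling off roughly
geometrically.

**Phenotypes.** Drinking status follows a logistic model in age (centered),
male sex and per-alt-copy variant effects; the intercept is found by
bisection so the expected prevalence matches the target (default 10.6%)
within 1e-6 — a closed form is unavailable once covariates enter. Defaults:
age ~ normal(49, 11) truncated to [30, 70], male proportion 0.495, male
log-odds 2.2 (cases come out ≈ 88% male). γ-GT is log-normal: baseline log
mean 2.770 and log SD 0.885 reproduce the control-group moments
(mean ≈ 23.6, SD ≈ 25.7 U/L) via the log-normal moment equations, and the
case shift 0.671 = log(46.15/23.60) raises the case mean to ≈ 46 U/L while
keeping the right skew and positivity that serum enzymes show. Variant
effects act additively on the log scale.

**What the generator does not emulate:** population stratification and
admixture, genotyping batch effects, missingness patterns, imputation
uncertainty, X-chromosome dosages, multi-allelic sites, age–genotype
interactions. Green tests therefore certify the estimators' behaviour under
a clean, exchangeable cohort, not robustness to those artefacts.

## QC

Variant filters: call rate ≥ 0.95, MAF ≥ 1e-3, exact Hardy–Weinberg test
p ≥ 1e-6. The HWE test is the Levene–Haldane exact conditional test (sum of
probabilities of all heterozygote configurations no more probable than the
observed one), which is correct at the low MAFs where the χ² approximation
breaks. Sample filters: call rate ≥ 0.95, then a duplicate/relatedness
screen at identity ceiling 0.4. The screen uses allele-frequency-centered
relatedness (the genomic-relationship off-diagonal), which is ≈ 0 for
unrelated pairs and ≈ 1 for duplicates; raw allele sharing is ≈ 0.7 for any
two unrelated people at common SNPs, so a 0.4 ceiling on the raw proportion
would discard everyone. Because the estimator's noise scales as 1/√M, the
screen is skipped (with a warning) below 400 variants; with fewer markers a
0.4 ceiling would flag unrelated pairs by chance, and removing samples by a
genotype-dependent rule then distorts downstream Hardy–Weinberg statistics.

## Association scans

The drinking scan fits per-variant logistic regressions (intercept,
genotype 0/1/2, age, sex, top principal components) by Newton/IRLS to
score-norm 1e-8 (cap 100 iterations), reporting the Wald p, exp(β) as the
OR, and a separation flag when probabilities pin at 0/1 with diverging
coefficients. The γ-GT scan is per-variant OLS on log γ-GT (the trait is
strictly positive and right-skewed; the log transform is a documented
default, not prescribed by the protocol being emulated), computed by
Frisch–Waugh residualization against the covariates for speed — this equals
the full OLS fit exactly. Principal components are computed on
column-standardized genotypes (randomized SVD when wide, seeded), each
component's sign fixed so its largest-magnitude loading is positive.
PCA input is LD-pruned (greedy r² < 0.2 within a 100-SNP window) by
default: at desk scale a tight LD block otherwise dominates the top
components and the PC adjustment absorbs the association signal itself.
BH-FDR is the standard step-up. λ_GC is the median Wald χ² over 0.4549364
(the χ²₁ median).

**Simplified LD-score regression.** ℓ_j = 1 + Σ r̂²_jk over a ±window of
100 SNPs, with each r̂² replaced by the unbiased r̂² − (1 − r̂²)/(n − 2)
(without it every score is inflated by ≈ 2·window/n). The intercept comes
from an *unweighted* OLS of χ² on ℓ — a desk-scale diagnostic analog of
LD-score regression, labelled simplified in every output; it is not the
reference-panel tool. Two calibration studies are packaged
(`ldridge.studies`): a confounding-free null over independent SNPs for
λ_GC, and a null over a *mixed* genome (independent SNPs plus LD blocks)
for the intercept. The mixture matters: the intercept of an unweighted fit
is identified only when LD scores span a range with a mass near ℓ = 1.
Measured at n = 5,000: with the mixed genome the per-seed intercept SD is
≈ 0.04; with a genome made only of uniform LD blocks it is ≈ 0.3 (all
scores cluster far from 1, making the intercept an ~8× extrapolation, and
within-block χ² are strongly correlated); with independent SNPs only it is
≈ 5 (no ℓ spread at all). The polygenic all-block study is still provided
and is what `scripts/acceptance.py` reports as the polygenic intercept;
its three-seed average should be read with that ≈ 0.17 Monte-Carlo SD in
mind.

## Dual capture and coding filter

A variant is captured when drinking p < 5×10⁻⁸ and γ-GT BH q < 0.05
(a both-FDR mode exists). The coding filter keeps {missense,
coding-synonymous, utr5, utr3-ncRNA, cds-indel, frameshift} and drops
intronic/intergenic; cds-indel and frameshift are annotation labels only —
all simulated variants are point substitutions. Gene summaries report span,
minimum drinking p and SNP count per gene; a variant annotated to several
'|'-separated genes counts once per gene.

## Two-locus haplotype analysis

EM on the 3×3 genotype table: only the double heterozygote is
phase-ambiguous and is split between coupling and repulsion in proportion
to the current frequency estimates; initialization at linkage equilibrium;
convergence when the log-likelihood gain is below 1e-10 (cap 1,000
iterations; the trace is retained and is non-decreasing). Because EM
preserves the observed allele frequencies, the likelihood has a single free
parameter given the margins — the test suite exploits this with a profile
grid search as an independent maximizer. Case/control odds ratios use
expected (fractional) haplotype counts in a 2×2 table with Woolf log-SE
CIs and a Haldane–Anscombe 0.5 correction when any expected cell is below
0.5; fractional counts avoid the information loss of integer best-guess
assignment. For the trait contrast, individuals get their
maximum-posterior diplotype under pooled EM frequencies (deterministic;
ties resolved toward coupling — at r² near 1 phase is nearly certain
anyway), and exclusive carrier groups (A-not-B vs B-not-A) are compared
with Welch's t.

## Ridge trace and stability selection

Predictors are standardized and the 0/1 outcome centered, which makes the
penalized intercept exactly zero, matching a loss whose penalty formally
includes β₀. Squared-error loss is used for the binary outcome
deliberately — fidelity to the method being reproduced — with the
coefficients read as linear-probability effects. β̂(λ) is computed from one
economy SVD reused across the grid (β̂ = V diag(d/(d²+λ)) Uᵀy), equal to
the direct solve to 1e-8 and to OLS as λ → 0 on full-rank designs;
‖β̂(λ)‖₂ is strictly decreasing in λ. Default grid: 64 log-spaced points
over [1e-3, 1e3] × mean diagonal of XᵀX, spanning the OLS and null limits.

Selection quantifies "the trace is large and flat": for each predictor,
over the window λ ∈ [0.08, 0.2] × mean diag(XᵀX),

* stability s_j = (max|β̂_j| − min|β̂_j|) / max|β̂_j|  (flat ⇔ small),
* magnitude g_j = mean |β̂_j|,

and j is selected when s_j ≤ τ (default 0.2), g_j ≥ mult × median g
(default 3; waived below 5 predictors, where a predictor can never be 3×
its own median), and g_j ≥ z_min × se_j (default 4), where se_j is the
ridge estimator's sampling SE at the window's mid-λ with the conservative
σ̂ = sd(y). The window is the part of the trace that actually
discriminates: below it, the near-singular contrasts between tightly
linked predictors are still noise-dominated (the OLS end of a collinear
pair's trace wobbles); above it, ridge shrinks all directions roughly
uniformly, so every trace is trivially "unstable" relative to its own
maximum. The noise floor z_min·se is what keeps pure-noise panels empty:
with 48 correlated predictors the median-magnitude rule alone passes
chance-flat noise traces. All three knobs (τ, mult, z_min) are exposed.
Under the packaged replicate study (r² ≈ 0.98 causal pair with equal
per-alt-copy effects riding the coupling haplotypes, one independent
causal, 45 proxies/nulls at ρ = 0.7, n = 5,000), the rule recovers the
three causals in ≥ 90% of replicates and selects nothing from pure noise
in ≥ 90%. Two caveats measured during design: a collinear pair with
*unequal* true coefficients cannot have two flat traces (ridge pulls both
to their average mid-path, so the weaker member's trace always drifts),
and proxies tighter than r² ≈ 0.8 become statistically interchangeable
with the causal at this sample size — no trace statistic can separate
them.

## Conditional models

OLS with QR factorization, t-based 95% CIs, exact rank-deficiency errors
naming the collinear columns. The partial F-test is
F = ((SSE_r − SSE_f)/(df_r − df_f)) / (SSE_f/df_f). Forward conditional
selection residualizes outcome and candidates against the current model
(updated by Gram–Schmidt), enters the candidate with the smallest
conditional p (ties: larger |t|, then smaller index), and stops at
p ≥ α (default 1e-4). Candidates collinear with the current model are
skipped, so an r² = 1 duplicate can never enter twice. The conditional
outcome defaults to log γ-GT with covariates, switchable to the binary
trait.

## Enrichment

Per category: expected = |study|·|category ∩ background|/|background|,
fold = observed/expected, direction "+" iff observed ≥ expected, p = the
hypergeometric tail in the observed direction (a doubled-smaller-tail
two-sided value is a separate column), a binomial test as secondary
column, and BH-FDR across categories with a 0.05 significance cutoff.
The background is an explicit required input; no ontology is fetched. A
flat two-column (gene, category) reader and a GAF 2.x reader are provided.
No GO-graph propagation is performed.

## Pipeline

Stages communicate via files under the run directory (independently
inspectable and re-runnable); the manifest and run log record counts in
and out of every stage, and a rerun with the same config is byte-identical
(modulo the config echo, which embeds the output path). Default problem
sizes in the tests are chosen to exercise every stage at desk scale —
simulated cohorts of 600–5,000 individuals and 50–8,000 variants, 30–200
replicate calibration loops — with the two scan-diagnostic studies run at
n = 5,000 with M = 2,000–8,000 SNPs.

## Known limitations

* The simplified LDSC intercept is a diagnostic, not an estimate of
  confounding at biobank scale; its unweighted fit is noisy whenever LD
  scores lack low-ℓ anchoring (quantified above).
* Perfect separation in the logistic scan is flagged, not rescued by
  penalized likelihood.
* Ridge-logistic (binomial loss) is not implemented; squared loss on the
  centered 0/1 outcome is the documented default.
* The haplotype module handles exactly two loci; no multi-locus phasing.
* Cross-validated λ selection is deliberately absent — the method under
  study reads the whole trace rather than picking one λ.
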