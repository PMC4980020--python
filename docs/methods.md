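# Methods

## Case/control derivation from billing codes

Billing rows are counted per (person, exact ICD-9 code); a person is a case
for a code when their count is at least `case_min_instances` (default 4,
i.e. "more than three instances"), and a control otherwise. We deliberately
use *no exclusion zone*: persons with 1–3 instances are controls. Many
PheWAS tools instead exclude such persons or use a ≥ 3 rule; both thresholds
are exposed (`case_min_instances`, `min_cases`) so either convention is one
flag away. Duplicate same-day rows count as separate instances, and the
optional `event_date` column is ignored by the default counting rule — the
package counts rows, not distinct encounter dates. Codes are retained as
phenotypes when they have at least `min_cases` cases (default 11). The
3-digit category of a code is the substring before the decimal point, so
V- and E-prefixed codes keep their prefix (V70.0 → V70) rather than being
cut at a fixed character count.

## Genotype QC

Filters run in a fixed order so removal counts are auditable: (1) info
score > 0.9; (2) SNP call rate ≥ 0.99; (3) sample call rate ≥ 0.99; (4) MAF
≥ 0.01, recomputed after sample removal. The order is a package convention
(the thresholds, not the order, are the established ones); the stepwise QC
report makes any alternative accounting reconstructible.

**Relatedness.** π̂ is the method-of-moments IBS-based estimate of the IBD
proportion: per pair, observed identity-by-state counts are matched to
their expectations under IBD state 0/1/2 given allele frequencies, and
π̂ = P(IBD=1)/2 + P(IBD=2). Two numerical points matter. First, expectations
use unbiased factorial moments of the allele *counts* rather than powers of
p̂ — the finite-sample correction without which unrelated pairs in small
panels acquire a positive π̂ bias. Second, the three state estimates are
left unclipped before combination so their multinomial sampling noise
cancels; only the final π̂ is clipped to [0, 1]. Removal is greedy: while
any retained pair exceeds the threshold (default 0.1875, midway between
2nd- and 3rd-degree relatives), drop the member with the lower call rate,
ties broken toward the lexicographically larger id — deterministic and
guaranteed to leave no retained pair above threshold. In the pipeline
driver, removal only runs when at least 2,000 post-QC SNPs are available:
below that the π̂ sampling noise (sd ≳ 0.05) would remove many unrelated
samples, so the stage is skipped and flagged in the manifest.

**LD pruning** is a sliding-window greedy scan (window 50 SNPs, step 5,
PLINK-conventional defaults): within each window, for each pair of still-kept
SNPs with hard-call r² above the ceiling (default 0.3), the later SNP in
position order is dropped. Input must be (chrom, pos)-sorted, which makes the
result deterministic and independent of sample order. The surviving count is
the Bonferroni denominator: threshold = α / (pruned SNPs × phenotypes).

**PCA** operates on the column-standardized, mean-imputed dosage matrix of
the pruned SNPs; the sign of each component is fixed by making its
largest-magnitude loading positive. Five components are used as covariates
by default. Dosages are rounded to hard calls for IBD and r² computations;
raw (possibly fractional) dosages enter the regression.

**Coordinates.** BED intervals are 0-based half-open, VCF and internal
positions 1-based; conversion happens at the reader boundary only, so a SNP
at 1-based position p lies in BED [start, end) iff start < p ≤ end.

## Association model

Each (SNP, code) pair is fitted by maximum-likelihood logistic regression
with additive dosage coding and covariates age (years, untransformed), sex
(0/1) and the principal components. Fitting is plain IRLS initialized at
the marginal log-odds, declared converged when the largest coefficient
update relative to (1 + |coefficient|) falls below 1e-8 within 50
iterations. The reported test is the two-sided Wald test on the dosage
coefficient. Separation is detected as |β| > 15 (or non-convergence); such
fits are marked `converged = False` and excluded downstream rather than
penalized — no Firth correction is applied by default. Rows with missing
dosage are dropped pairwise per fit, so per-SNP sample counts may vary.
Collinearity among the covariates raises a rank-deficiency error naming the
offending columns (checked once per scan); a degenerate dosage column
surfaces as a non-converged fit. Scan output is optionally capped at
p < 0.01, the working set that feeds replication.

## Replication and pooled analysis

Cross-site matching happens on (SNP, exact code) or (SNP, 3-digit
category); category matching truncates the *result* codes rather than
re-deriving category-level case/control status (re-derivation changes the
phenotype definition; truncation keeps the per-site fits untouched). Site
B's coded allele is harmonized to site A's: swapped alleles flip the sign
of β, strand flips complement the labels first, and strand-ambiguous (A/T,
C/G) SNPs are excluded as unresolvable. A pair replicates when both sites
show p below the replication threshold (default 0.01) with the same sign.
When several sub-codes of one category pair up for a SNP, every cross pair
is emitted and the (min p per site) pair is flagged as the representative
used for meta-analysis — multiplicity within a category is otherwise left
to the consumer.

Pooling is the sample-size-weighted signed-Z scheme: Zᵢ = sign(βᵢ)·
Φ⁻¹(1 − pᵢ/2), Z_meta = Σ wᵢZᵢ / √(Σ wᵢ²) with wᵢ = √(casesᵢ + controlsᵢ)
(total N, which reproduces the published worked examples), and
p_meta = 2·Φ(−|Z_meta|). Tail quantities use scipy's log-space inverse
(`ndtri_exp`), keeping the p → Z → p round trip accurate to 1e-10 relative
down to p ≈ 1e-250. Note that adding a weakly concordant study can
legitimately *decrease* |Z_meta| under this scheme (weighted dilution);
monotonicity only holds when the added study is at least as significant.

## Downstream summaries

Pleiotropy: a SNP is flagged when its replicated results span ≥ 2 distinct
categories. Gene assignment: a SNP maps to every gene whose interval,
extended by 50 kb on both sides, contains it (nearest-gene mode available);
unassigned SNPs are labelled "unmapped". Network edges: phenotype–gene
edges weighted by the number of distinct supporting SNPs, gene–pathway
edges from GMT membership. Catalog matching uses a strict p < 1e-5 on the
reported association and requires an explicit category↔trait mapping table;
no fuzzy text matching is attempted, mirroring the fact that judging "same
trait" is a curation decision, not a string metric.

## Synthetic two-site generator

The generator emulates the statistical structure the analysis assumes, not
any particular biology. Genotypes: a shared panel of SNPs with ancestral
MAF uniform on `maf_range` (default [0.01, 0.5]); haplotypes are blockwise
Gaussian copulas — within each block of `ld_block_size` SNPs (default 10)
the latent Gaussians follow an AR(1) with correlation `ld_rho` (default
0.7) and are thresholded at the allele frequency. Each SNP is therefore
exactly Hardy–Weinberg while adjacent SNPs are correlated; the realized
allele-level r is below the latent ρ (thresholding attenuates
correlation), which is acceptable because ρ is a structure knob, not a
calibration target. With `n_subpops > 1`, subpopulation frequencies come
from the Balding–Nichols Beta construction at the configured FST and
samples are assigned to subpopulations round-robin. Per-SNP info scores are
Beta(8, 1) by default — mean 0.89 with ~57% of mass below 0.9, so the info
filter has real work to do.

Phenotypes: each code carries a baseline prevalence drawn log-uniformly
from `baseline_prevalence_range` (default [0.005, 0.6], spanning roughly a
dozen to ~1,800 cases at n = 3,000, matching the case-count span the
analysis must handle). Disease status is Bernoulli with
logit p = logit(prevalence) + β·dosage + 0.01·(age − 55) + 0.25·(sex − ½),
with age ~ Normal(55, 12) clipped to [18, 95] and sex ~ Bernoulli(½); the
small fixed covariate coefficients exist to exercise covariate adjustment.
Affected persons bill 4 + Poisson(`lambda_case`) instances, so the
"more than three" case rule captures every truly affected person and the
rule itself is the binding case definition; unaffected persons bill a
zero-inflated Poisson(`lambda_background`) count (zero with probability
0.7), creating controls who hold 1–3 stray instances. The background tail
above 3 is *not* truncated: at the defaults it misclassifies ~5e-4 of
unaffected persons as cases, negligible against Monte-Carlo tolerances,
and keeps the generative story simple.

Two sites share the SNP panel (identical metadata and info scores) but draw
genotypes, covariates and events independently. Code vocabularies are built
from disjoint category pools so the requested overlap is exact: a
configurable number of identical codes, plus codes sharing only their
3-digit category (distinct sub-codes), plus site-private categories. The
default overlap (50 exact, 186 category-only) and site size (3,000) mirror
the two-cohort setting this pipeline is designed for; the default panel of
1,000 SNPs is a deliberately scaled-down stand-in for a genome-wide
post-imputation panel, chosen so end-to-end runs complete in seconds to
minutes on one CPU. An optional `site_b_prevalence_shift` (logit units,
default 0 = off) can skew one site's prevalences to emulate targeted
recruitment. Everything is deterministic given `seed`: panel, vocabularies
and per-site draws use independent, tagged RNG streams.

What the generator does *not* emulate — and hence what passing tests do not
establish about real EHR data: phased haplotype realism beyond AR(1)
blocks, genotyping or imputation error (info scores are labels, not error
processes), longitudinal visit structure, code co-occurrence and comorbidity
correlation (codes are conditionally independent given covariates), coding
drift between institutions beyond the vocabulary overlap, and
ascertainment/censoring.

## Problem sizes used by the test suite

Tests run the generator at reduced sizes chosen to keep the full suite in
the minutes range on one CPU while preserving each check's statistical
power: null calibration pools 10,000 scan p-values (n = 1,000 persons, 100
SNPs × 100 codes) and one million directly simulated summary pairs for the
compound replication rate; planted-effect recovery uses the full study-size
n = 3,000 per site over 100 replicates with a 12-SNP panel; structure
recovery uses 1,000 samples × 2,000 SNPs.

## Known limitations

* The Wald test is anti-conservative for very rare phenotypes (few cases);
  the scan relies on the ≥ 11-case inclusion rule rather than small-sample
  corrections. A likelihood-ratio or Firth option would be the natural
  extension.
* π̂ needs thousands of informative SNPs; the pipeline refuses to remove
  samples below that regime rather than guessing.
* Meta-analysis offers only the fixed-direction sample-size scheme: no
  inverse-variance weighting, heterogeneity statistics or random effects.
* Catalog annotation is exact-identifier matching plus a user mapping
  table; synonym resolution is out of scope.
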