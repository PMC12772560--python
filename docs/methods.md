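# Methods

This note records the statistical model behind each module, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing a
run exactly.

## Two-sample MR model

The package works entirely on GWAS summary statistics. For instrument j,
the observed exposure effect β̂_Xj and outcome effect β̂_Yj are treated as
independent normal draws around their true values (the two GWAS are assumed
to come from non-overlapping or effectively non-overlapping samples). Under
the instrumental-variable assumptions the Wald ratio b_j = β̂_Yj/β̂_Xj
estimates the causal effect θ; its first-order SE se_Yj/|β̂_Xj| ignores the
uncertainty in β̂_Xj (NOME approximation). The second-order correction is
deliberately omitted: at the instrument strengths the pipeline enforces
(mean F > 10, typically ≫ 10) the correction is negligible, and the
first-order weights keep the IVW estimator identical to the through-origin
weighted regression, which is what the independent WLS oracle in the test
suite checks against.

**IVW.** The headline estimator is the multiplicative random-effects IVW:
the fixed-effects SE is scaled by max(1, √(Q/(J−1))). The truncation at 1
means overdispersion widens the interval but underdispersion never narrows
it — the conventional conservative choice; the model itself does not fix
the truncation convention.

**Egger.** Exposure effects are oriented non-negative before fitting (the
estimator is only defined up to allele relabelling); the intercept
estimates the average directional pleiotropic effect and the slope the
causal effect, valid when pleiotropy is independent of instrument strength.
SEs are scaled by max(1, residual SE), mirroring the IVW convention.

**Weighted median.** The inverse-variance-weighted 50% quantile of the
ordered ratios, interpolated linearly between cumulative-weight midpoints
s_j = Σ_{k≤j} ŵ_k − ŵ_j/2. Consistent while valid instruments carry more
than half the weight. The SE comes from a parametric bootstrap (default
1000 replicates) resampling β̂_Xj and β̂_Yj from their sampling
distributions; the bootstrap seed is mandatory in the pipeline
configuration so runs are bit-reproducible.

**Weighted mode.** The maximiser of a weighted normal-kernel density over
the ratios, bandwidth h = φ·0.9·min(SD, IQR/1.349)·J^(−1/5) with φ = 1 by
default; the density is evaluated on a dense grid (2001 points across the
ratio range ± 3h) and ties resolve to the smallest mode. When every ratio
is identical the bandwidth degenerates; the common ratio is returned with
SE 0 rather than failing.

**P-values** for all estimators use the normal reference distribution, the
summary-data MR convention at typical instrument counts (tens of SNPs); a
t reference would differ visibly only below ~10 instruments, where the
robust estimators are anyway unreliable.

**Heterogeneity.** Cochran's Q on the ratio scale with df = J−1, its χ²
p-value, I² = max(0, (Q−df)/Q), and additionally I²_GX computed from the
dispersion of the exposure effects themselves (the NOME-violation
diagnostic). Both are reported because a single printed "I²" is ambiguous
between the two in published tables.

**Radial screen.** Each SNP's contribution Q_j = w_j (b_j − θ̂)² is
referred to χ²(1) at α = 0.05 without multiplicity correction; the default
is a single screening pass (iterative removal is available behind a flag,
capped at 10 passes). Published outlier counts are generally single-pass,
and a single pass avoids the well-known over-pruning of iterated screens.
Because removing outliers before reporting is itself a contested choice,
the pipeline reports estimates both before and after removal.

## Selection funnel conventions

* Instrument significance is strict: p < threshold; a SNP at exactly the
  threshold is excluded.
* Clumping is greedy: repeatedly retain the remaining SNP with the lowest
  p (ties broken lexicographically on SNP id), discard same-chromosome
  SNPs within the window (pairwise distance ≤ 10 kb by default) with
  r² > 0.001. Retention is therefore r² ≤ 0.001 inclusive.
* Harmonization compares alleles literally and, for non-palindromic pairs,
  under reverse complement. Palindromic pairs (A/T, C/G) are dropped when
  MAF > 0.42 in either dataset (equality kept), since strand cannot be
  resolved near 0.5; at or below the cutoff they are oriented so both
  effect-allele frequencies fall on the same side of 0.5, and the
  orientation is flagged in the audit log. A palindromic SNP missing a
  frequency in either dataset cannot be oriented and is dropped with its
  own reason code. Dropping on either dataset's MAF is the conservative
  reading where practice varies.
* Proxies require r² ≥ 0.9 (inclusive); the highest-r² candidate wins,
  ties lexicographic. The proxy's effect is oriented by the LD table's
  phase column when present, else by frequency agreement, and flagged when
  neither is available.
* The pleiotropy filter removes SNPs whose outcome association p is
  strictly below their exposure association p — a variant more strongly
  tied to the outcome than to the exposure likely violates the exclusion
  restriction.
* Mean F must strictly exceed 10 to escape the weak-instrument flag, and
  the same strict rule applies per exposure to the conditional F in
  multivariable MR.
* Every SNP entering a funnel ends in exactly one audited disposition
  (kept / dropped with reason / unmatched), written as a TSV per analysis.

## Multivariable MR

β̂_Y is regressed jointly on the L exposures' effect columns (no intercept,
weights se_Y⁻²); coefficients are direct effects. Covariance between the
SNP-exposure effect estimates is set to zero, valid when the exposure GWAS
come from independent cohorts. Instruments significant for either exposure
at its own threshold are pooled and clumped jointly (index p = the smaller
of the exposure p-values); exposure 1's allele designation is the reference
frame onto which the outcome and exposure 2 are both re-signed, so the
three effect columns always agree per SNP. Conditional instrument strength
for exposure k is the weighted residual sum of squares of its effect column
regressed on the other exposures' columns, divided by J − L.

## Recessive burden test

Qualifying variants must be protein-altering (missense, stop-gained,
frameshift, splice by default) and strictly rarer than 5×10⁻⁴ in both the
analysis cohort and the external reference; a variant with no reference
frequency cannot be shown rare in both and is conservatively excluded.
Collapse is recessive without phase: homozygous for one qualifying variant,
or heterozygous for two or more distinct ones (a compound heterozygote
called from unphased genotypes; true cis pairs are counted, the price of
unphased biobank data). Missing genotypes count as reference. The VCF
FILTER column is the quality gate — upstream coverage/mapping/genotype
quality and Hardy–Weinberg filters are assumed already applied, and only
PASS records are read.

The test is the standard two-sided Fisher's exact test (sum of
hypergeometric point probabilities not exceeding the observed table's,
with 1e−7 relative tolerance for ties — verified against exhaustive
integer enumeration on all tables with N ≤ 40). The effect estimate is the
sample odds ratio ad/bc with the Woolf logit 95% CI; the Haldane–Anscombe
0.5 correction is applied to OR and CI (never to the p-value) only when a
cell is zero. The conditional-MLE odds ratio was considered and not used:
the sample OR is what published carrier tables reproduce exactly.

## Positive-control threshold calibration

When a relaxed instrument threshold is needed (an exposure with few
genome-wide-significant hits), the pipeline calibrates it on a positive
control — an outcome with an accepted causal link to the exposure. Every
grid threshold (default decade steps 5×10⁻⁸ … 5×10⁻⁴) runs through the
full funnel and IVW fit; the chosen threshold minimises the
positive-control IVW p among thresholds leaving ≥ 3 instruments with mean
F > 10. "Most significant positive control" is encoded literally as the
objective; the full per-threshold table is always returned and written so
the choice can be audited rather than trusted.

## Synthetic-data generator

**Summary statistics.** True exposure effects are drawn
N(0.1, 0.02²) on a standardised scale for J = 50 SNPs by default; SEs are
1/√n with n = 100 000 per GWAS (allele-frequency-dependent SEs are a
documented non-goal of the default: estimator behaviour, not GWAS realism,
is what downstream tests need); observed effects add normal noise; the
outcome effect is θ·β_Xj(true) plus an optional pleiotropic α_j — zero,
balanced (mean 0), directional (mean μ_α), or proportional to the true
exposure effect, which shifts the affected SNPs' Wald ratios by a constant
and is the exact regime in which the weighted median's 50%-breakdown
property is meaningful. Positions are laid out in LD blocks ≥ 1 Mb apart
with a constant within-block r² and zero between blocks, so clumping tests
have a closed-form answer. P-values are two-sided normal, clipped at
1e−300 to stay within the (0, 1] contract.

**Cohorts.** N = 300 000 individuals and 50 qualifying variants by
default, with a shared per-variant allele frequency solved numerically so
the recessive carrier-genotype frequency hits its target (3×10⁻⁴ by
default, which keeps each variant below the 5×10⁻⁴ qualifying ceiling);
genotypes are Hardy–Weinberg, sampled sparsely (per-variant multinomial
carrier counts assigned to distinct individuals — the same joint law as
independent Binomial(2, f) draws, but linear in carrier count); disease
follows logit P(case) = logit(base rate) + ln(ψ)·1[carrier genotype] with
base rate 10⁻³ and carrier odds ratio ψ = 20. The generator writes a
plain-text VCF (GT only, PASS filters), a phenotype TSV and an annotation
TSV that include decoy variants the qualifying filter must reject, so the
burden arm is exercised end to end from files.

What the generator does **not** emulate: realistic LD maps, population
stratification, sample overlap between GWAS, imputation error,
allele-frequency-dependent power, phasing, or sequencing artefacts.
Passing tests therefore demonstrate correctness of the estimators and the
selection logic under the stated sampling models — not robustness to the
failure modes of real cohort data.

## Validation design and problem sizes

Oracle equivalence uses independent routes: statsmodels WLS for the
IVW/Egger/MVMR regressions (10⁻¹⁰ relative), integer hypergeometric
enumeration for Fisher's p (all 2×2 tables with N ≤ 40), a re-derived
brute-force greedy for clumping (random instances, J ≤ 12), and dense-grid
or interpolation oracles for the median and mode. Calibration and recovery
use 1000 null replicates (J = 50) for type-I error and Q-uniformity, 200
replicates (J = 100) for causal-effect and Egger-intercept recovery, 100
replicates for the multivariable fits, and 300 replicate cohorts for the
burden odds-ratio median — that many because the expected carrier-case
count per cohort is ~1.8, so per-cohort odds ratios are nearly discrete
and the sample median needs replicates to stabilise near the distribution
median (~20). In the 40%-invalid-instrument regime the weighted median
retains a small positive finite-sample bias (the population weighted
median sits at the 83rd percentile of the valid-ratio cluster, ≈ 0.03
here); the robustness check therefore compares each estimator's replicate
mean against three of its own Monte-Carlo (bootstrap) SEs — the weighted
median stays inside that band, IVW misses its own by a wide margin.

## Known limitations

* No MR-PRESSO, contamination-mixture, Steiger or CAUSE estimators; the
  reverse-causation check is a role-swapped MR run.
* Proxy search consults a user-supplied LD table; the package never
  computes LD from reference genotypes.
* INDELs, genome-build liftover and GWAS-VCF ingestion are out of scope.
* The burden arm requires biallelic records and calls compound
  heterozygotes without phase: two distinct qualifying heterozygous calls
  suffice, so true cis pairs are (rarely, at these frequencies) counted
  as carriers. Phase-aware calling is not implemented.
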