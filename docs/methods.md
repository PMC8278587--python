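# Methods

This note documents the models, procedures and numerical choices behind
`bbdburden`, and what the synthetic-data experiments do and do not
demonstrate.

## Data model

The atomic observation is one (sample, site, alternate allele) call with an
alternate-allele fraction (AAF), a unique-molecular-tag (UMT) depth,
optional rsID, gene / functional-impact / population-allele-frequency /
trinucleotide-context annotations, and a set of upstream technical failure
flags. Single-nucleotide variants are classified into seven categories on
the pyrimidine strand — C>A, C>G, C>T, C>T at CpG, T>A, T>C, T>G — with
purine-reference calls reverse-complemented first; a strand-normalized C>T
whose 3′ neighbour is G is the CpG subtype. Indels are carried through
filtering and prioritization (their impact classes include frameshift and
in-frame indels) but are excluded from category-based machinery: no
substitution category, FDR weight factor 1, and no contribution to
signature spectra. Coordinates are 1-based as in VCF; multi-allelic records
are split per ALT. AAF is read from a configurable FORMAT field (default
`VAF`), falling back to `AD`-derived alt/(ref+alt). htslib stores VCF
floats in 32 bits; on reading, values are restored to the shortest decimal
identifying the float32, so fractions printed with up to seven significant
digits round-trip exactly.

## QC chain

* **Sample acceptance.** Fail when mean UMT coverage < 20× or when the SNP
  genotyping call rate — the fraction of known SNP positions whose AAF
  falls in one of the genotype bins [0, 0.2] (hom-ref), [0.4, 0.6] (het),
  [0.8, 1.0] (hom-alt), endpoints inclusive — is below 80%. An absent call
  at a known SNP counts as AAF 0.
* **Replicate identity.** Spearman correlation (average ranks) of
  known-SNP AAF profiles between all sample pairs; same-source iff
  correlation > 0.85. Raw AAF by default, with a fold-to-minor flag.
* **FFPE FDR.** From paired FFPE/fresh-frozen samples, per category
  (optionally per AAF bin): FDR = (FFPE calls absent from the paired
  frozen sample) / (FFPE calls), matching on (pair, chrom, pos, ref, alt).
  Cells with no FFPE calls are missing, not zero.
* **AAF filtering.** Liberal drops calls with AAF < 0.05; classical drops
  C>T calls (both subtypes, unless rsID-annotated) below 0.1 and all
  others below 0.05; strict drops everything below 0.1. Thresholds are
  strict inequalities, making the three survivor sets nested and each
  filter idempotent. The CpG subtype inherits the classical C>T rule since
  it is a C>T; the rsID exception applies only in the classical strategy.
* **Prioritization.** Site-wise removal when population AF > 0.005, when
  the mean AAF over the cohort's controls (absent call = 0, denominator =
  all passing controls) exceeds 0.05, or when the impact is outside the
  medium/high set (essential splice, stop gain, frameshift, nonsynonymous,
  in-frame indel, start codon, stop loss, exon end). Calls with missing
  impact are retained with a warning by default (configurable to remove).
  The processing order is technical filter → AAF strategy → prioritization.

## Gene-level association

Per contrast (all cases, ER+, or ER− versus controls), covariates are
epithelial percentage, histology indicators against the non-proliferative
baseline, age, biopsy year centered at 1992, a post-1992 indicator, their
interaction (an FFPE processing change motivates the breakpoint) and SNP
call rate; aliased columns are dropped to full rank and logged. When a
subject has technical replicates, the lexicographically first sample of the
replicate set represents it.

**Logistic burden.** `B_ig = Σ_v w_v·AAF_iv` over the gene's retained
variants; maximum-likelihood logistic fit by iteratively reweighted least
squares with internal column standardization (a near-constant covariate
such as an SNP call rate hugging 1.0 otherwise wrecks the Newton system),
a ridge jitter of 1e-10 on the standardized scale and step-halving on the
log-likelihood. Convergence is declared on log-likelihood stabilization, so
a separating *nuisance* direction does not fail the whole fit; the test is
marked non-converged when the burden coefficient itself misbehaves
(|beta| > 25 or SE > 50 on the per-unit scale). The reported OR is per
1 unit of summed AAF, unstandardized.

**SKAT-O.** On the binary presence matrix, the grid statistic
`Q_ρ = r'(GW)R_ρ(WG')r` with `R_ρ = (1−ρ)I + ρ11'` and null-model
residuals r; default grid {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}, with
ρ capped at 0.999 internally. Per-ρ tail probabilities come from the
chi-square mixture with eigenvalues of `R_ρ^{1/2} WG'P₀GW R_ρ^{1/2}`
(P₀ the projected variance of the null logistic model), evaluated by
Imhof's characteristic-function inversion — a vectorized midpoint rule
sampling the fastest phase component 16 times per cycle, truncated where
Imhof's tail bound falls below 1e-6 (checked against high-accuracy adaptive
quadrature to ~1e-5 and against Monte Carlo) — with Liu-type moment
matching as prescreen and fallback. The omnibus p integrates the minimum-p
event over the shared chi-square(1) component on Gauss–Hermite nodes,
following the published one-dimensional decomposition, and is capped by
the Bonferroni bound over the grid and floored at the minimal per-ρ p.
A single variant collapses to the closed-form score test.

**Small-sample adjustment.** With n ≈ 120 binary outcomes and a handful of
carriers per variant, the asymptotic mixture moments are visibly off (the
leading error is an n/(n−1)-type variance factor). Each grid statistic is
therefore standardized by its *exact* first two moments under permutation
of the null residuals before the mixture tail is applied. The permutation
moments of a quadratic form r'Ar have closed forms (verified in the test
suite against exhaustive enumeration at n = 7), and because
`A(ρ) = (1−ρ)GWG'W' + ρcc'` every invariant is polynomial in ρ, the whole
grid costs O(nm²). The adjustment is on by default and disabled for the
single-variant collapse, which is specified to reproduce the classical
score test exactly.

**Known accuracy limits.** After adjustment, per-ρ analytic p-values track
a permutation oracle to roughly ±0.005–0.01 at n = 60; the omnibus
combination adds the published decomposition's cross-term approximation,
for a total analytic-versus-permutation gap with median ≈ 0.013 and worst
case ≈ 0.05 at moderate-to-large p on small instances (agreement near the
0.05 decision region is typically ~1e-3). This is a property of the asymptotic
method class, shared with reference implementations; analyses needing
finite-sample exactness should use the permutation machinery directly.
Under the unconditional null the 12 combinations are calibrated: across
50 synthetic null cohorts the per-combination rejection rates at p < 0.05
fall within the 95% binomial band around 0.05 (measured in the test suite).

**Weights.** SKAT-O uses the rare-variant convention Beta(1, 25) density
evaluated at the variant's observed cohort AAF (mean AAF over analysis
samples, absent = 0); cohort rather than population frequency because the
somatic setting has no population frequency for most retained variants.
The logistic burden uses unit base weights. FDR down-weighting multiplies
the base weight by (1 − FDR) of the variant's category — linear in FDR,
chosen for boundedness, the identity at FDR 0 and equivalence of weight 0
with removal (asserted for both tests).

## Consensus and permutation significance

`n_nominal` counts, per gene, combinations with p strictly below 0.05
(untestable combinations are non-significant); the consensus set requires
at least 4 of 12. The protective flag marks p < 0.05 with OR < 1 under
FDR-weighted logistic regression with classical filtering. Two global
statistics are tested by permutation: S1, the number of consensus genes
(two-sided, doubling the smaller tail on the discrete null, capped at 1);
S2, the number of protective genes (one-sided enrichment). A permutation
reassigns genomic profiles to subjects while each subject keeps their own
(group, covariates) tuple — the only scheme that preserves the
covariate–outcome relationship exactly. The empirical p uses the plus-one
estimator (1 + #extreme)/(1 + n_perm) by default; the raw estimator is a
flag. Because S2 depends only on one combination, its permutation loop
recomputes just that combination via a precomputed AAF matrix (verified
identical to the chained pipeline in the tests); S1 re-runs all 12.

## Mutational signatures

Spectra are per-sample counts over the 7 substitution categories (default)
or the 96 trinucleotide classes. Extraction minimizes generalized
Kullback–Leibler divergence by multiplicative updates (objective
non-increasing, asserted numerically; Frobenius available in principle via
the same scaffold), with `n_restarts` random initializations; pooled
per-restart signatures are clustered by average-linkage on cosine distance
and cut at k; each cluster's renormalized centroid is a consensus
signature, its stability the mean member-to-centroid cosine; exposures are
refit per sample by non-negative least squares. Rank selection is by the
user, guided by stability and reconstruction error across k. Reference
catalogs (e.g. COSMIC profiles) are supplied as TSV and compared by cosine
similarity; no catalog is redistributed. Exposure associations use the
Wilcoxon rank-sum (average ranks, asymptotic normal with tie correction)
or Kruskal–Wallis tests.

## Cohort and IHC statistics

Group comparisons use Pearson chi-square without continuity correction
(required to reproduce the published characteristic-table p-values of
0.026 for histologic impression, 0.086 for atrophy with missing subjects
excluded, and 0.416 for age category, all verified in the tests) and
one-way ANOVA. Per-sample mutational burden is the count of calls
surviving classical filtering plus prioritization. CD45 H-scores are
compared between pooled cases and controls by rank-sum and related to
burden by Spearman correlation, overall and within groups; Ki67 is
ingested and summarized only.

## The synthetic cohort generator

Defaults are the study conditions: 42 controls, 42 future ER+, 36 future
ER−, a 93-gene panel, and covariate margins drawn from the published
characteristic tables. Per sample the generator emits:

* **Germline.** 150 common panel SNPs (population AF uniform on
  [0.05, 0.5], all rsID-annotated) with Hardy–Weinberg genotypes and AAF
  noise around {0, 0.5, 1} (SDs 0.01/0.03/0.015); plus 2 rare germline
  sites per gene (AF < 0.005). Genotype-bin concordance exceeds 99% at
  these SDs. AAF deviations are split into an aliquot component shared by
  technical replicates and a smaller per-replicate measurement term
  (SD 0.003), reflecting that allelic imbalance is a property of the DNA
  aliquot; this is what separates replicate rank correlations (~0.94+)
  from unrelated pairs (max ~0.45) around the 0.85 decision margin.
* **Somatic.** Six recurrent candidate sites per gene, carrier probability
  0.05 per sample per site, AAF uniform on [0.08, 0.3] — low clonal
  fractions typical of somatic mosaicism in benign tissue. Planted effects
  multiply the carrier rate for one group in named genes. Keeping somatic
  AAFs low also keeps planted *protective* signal below the control-common
  prioritization cutoff: with higher clonal fractions the mean control AAF
  at effect sites crosses 0.05 and the pipeline itself removes the
  planted signal — a real interaction between the control-common rule and
  protective effects worth knowing about when interpreting that filter.
* **Artifacts.** Category rates per sample (C>T 12, C>T at CpG 6, others
  1 each) spread over recurrent artifact-prone sites (25 sites per unit
  rate, so per-site carrier probability 0.04), AAF from a Beta(1.5, 4)
  law rescaled to (0, 0.2) so the three filter strategies have distinct,
  non-trivial effects. About 30% of sites are emitted on the purine strand
  to exercise strand normalization. A 2% technical-flag rate exercises the
  technical filter.
* **Paired FFPE/frozen sets** plant per-category artifact fractions
  (defaults 0.6 for C>T, 0.25 for C>T at CpG, 0.1 elsewhere — the
  C>T-dominated pattern of formalin fixation); the frozen member carries
  only the true calls, so the estimand equals the planted fraction.
* **Signature cohorts** draw per-sample category counts multinomially from
  exposure-weighted mixtures of column-stochastic profiles.

What passing on this generator shows: the pipeline's statistics are
calibrated and its estimators recover planted truth under the assumed
generative structure (independent samples, site-independent artifacts,
logistic effects on carrier rates). What it does not show: robustness to
properties real FFPE data can have and the generator does not emulate —
context-dependent artifact hotspots correlated across samples, depth- and
age-dependent AAF error, population stratification, linkage between panel
SNPs, or mis-annotation of impact and population frequency.

## Problem sizes

The test suite runs the calibration study at 50 seeded cohorts of full
study size (42/42/36, 93 genes), the planted-effect study at 10 seeded
runs with 100 label permutations each, the oracle comparison at 20
instances with 100,000 permutation draws, and the signature recovery at
100 samples × 2,000 mutations — sizes chosen so every experiment's
Monte-Carlo error is small against the property it checks while the whole
suite stays desk-scale.
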