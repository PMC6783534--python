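# Methods

`fluorosig` implements the computational chain by which a chemotherapy
mutational signature — the fluoropyrimidine (5-FU) signature, equivalent to
COSMIC signature 17 — is extracted from somatic mutation catalogs,
attributed to individual mutations, timed against clonal structure, tested
for replication-strand asymmetry, detected in serial biopsies, and
translated into an oncogenic-risk estimate. This note records the models,
conventions and numerical choices, and what the synthetic study conditions
do and do not establish.

## Mutation catalogs and filters

Somatic single-base substitutions are classified into the 96
pyrimidine-centered trinucleotide classes. The canonical ordering is the
COSMIC convention: substitutions C>A, C>G, C>T, T>A, T>C, T>G outermost,
with the 5' then 3' flanking bases alphabetical within each substitution;
every matrix in the package indexes against this fixed order.
Purine-reference substitutions are reverse-complemented (substitution and
context together) onto the pyrimidine strand, which makes classification
strand-involutive: a substitution and its full reverse complement map to
the same class. Coordinates are 1-based inclusive throughout (VCF native);
soft-masked reference bases are uppercased before classification, and any
N inside a context window skips the variant with a tally. Contig names are
normalized by stripping a `chr` prefix on ingest.

Study filters: the clonal VAF window keeps variants with allele fraction
in the closed interval [0.3, 0.7] ("between" read inclusively; exclusions
are tallied); the autosome filter keeps chromosomes 1–22; tumor mutational
burden is the SBS count divided by 2,858,674,662/10⁶ — the number of
mappable (ACGT) bases of the GRCh37 reference, taken as given and
overridable since the exact contig set behind it is not derivable;
hypermutant samples are dropped when TMB exceeds 10 mutations/Mbp strictly.
Extended-context matrices (default 11 bases) accumulate per-offset base
frequencies on the pyrimidine-normalized strand, mirroring offsets for
purine-reference variants, so A/T-richness at offsets −4..−2 of C[T>G]T
mutations is measured in a fixed frame.

## Signature extraction (NMF)

A catalog V (96 × S counts) is factorized as V ≈ W·H with W, H ≥ 0, W
column-stochastic (signatures) and H the absolute exposures. The objective
is the generalized Kullback–Leibler divergence

D(V‖WH) = Σᵢⱼ ( Vᵢⱼ log(Vᵢⱼ/(WH)ᵢⱼ) − Vᵢⱼ + (WH)ᵢⱼ ),

minimized by Brunet-style multiplicative updates — the default of the
classic NMF implementation used across the signature literature; a
Frobenius variant is available behind a flag. Initialization is seeded
uniform(0, 1] per run; convergence is a relative objective change below
1e-6 or 10,000 iterations; the objective is non-increasing at every step
(a tested invariant). After convergence W is normalized column-wise with
the compensating scale moved into H, leaving W·H unchanged.

Rank selection follows consensus clustering over random restarts (the
"100 iterations" of the original NMF recipe are restarts, not update
steps): consensus[i,j] is the fraction of restarts in which samples i and
j share the same argmax-exposure signature (ties broken toward the lowest
signature index), and the cophenetic correlation coefficient compares the
(1 − consensus) distances with the cophenetic distances of their
average-linkage dendrogram. The suggested rank is the largest rank with
cophenetic ≥ 0.95 before the first drop > 0.05. The suggestion is
advisory: with strongly separated planted structure the consensus stays
stable well past the true rank, so headline analyses take an explicit
rank, as was done in the original cohort analysis (rank 16 by inspection).

Refitting solves, per sample, min‖v − P·e‖₂ over e ≥ 0 with P the 96 × K
signature probability matrix (scipy's active-set NNLS; KKT conditions are
asserted in tests). Relative contributions divide exposures by the sample
total, with zero-total samples reported as missing rather than 0/0.
Cohort contrasts use the two-sided Wilcoxon rank-sum test: exact
enumeration for combined n ≤ 25 without ties, normal approximation with
tie correction otherwise.

## Per-mutation attribution

For a mutation of class c in a sample with exposures e, the likelihood
that signature x generated it is eₓ·pₓ(c) / Σₛ eₛ·pₛ(c) — the
exposure-weighted share of x among the sample's expected mutations of
that class. Likelihoods sum to 1 whenever the denominator is positive and
are invariant to rescaling all exposures. Classes on which no active
signature places mass are unattributable (reported missing). A mutation
is assigned an origin when one signature's likelihood strictly exceeds
0.5; at most one signature can qualify, and the assignment count is
non-increasing in the threshold.

## Clonality timing

Variant ploidy = purity-adjusted VAF × local total copy number; a fully
clonal heterozygous diploid variant scores 1. Variants above 1 are clonal
unconditionally. The ploidy distribution is scanned with a Gaussian KDE
of absolute bandwidth 0.05 (the kernel SD in ploidy units — the reason
this KDE is computed directly rather than with a data-SD-scaled
bandwidth) on a grid of step 0.01 over [0, max + 3·bandwidth]. Strict
local maxima below 1 − bandwidth are subclonal peaks; sub-unity variants
go to their nearest peak (subclonal peak → subclonal, main peak →
clonal). The nearest-peak rule operationalizes "present in the peaks",
which the source procedure leaves informal; all detected peaks are
reported rather than only the largest. The peak search requires at least
10 sub-unity variants. Samples enter the subclonal contrast when they
have ≥ 500 subclonal mutations and ≥ 5% overall focal-signature
contribution (both inclusive); the contrast refits the clonal and
subclonal compartment catalogs separately by NNLS and reports the ratio
of focal relative contributions.

## Strand bias

Sample selection requires a focal-signature absolute contribution
strictly above 2,000 mutations and relative contribution strictly above
25%; the informative context is C[N>N]T (pyrimidine-normalized flanks
C_T). Replication regions carry the role of the reference plus strand
(leading/lagging) over 1-Mbp spans flanking origins; a variant takes the
region's plus-strand role when its pyrimidine base lies on the plus
strand (pyrimidine VCF reference) and the opposite role otherwise. For
transcription, a pyrimidine on the strand complementary to the gene
strand (the template) is "transcribed", on the gene strand
"untranscribed"; intergenic positions and opposite-strand gene overlaps
are unassigned. The published labeling convention relative to the
pyrimidine strand is not stated, so the assignment here is documented and
covered by a symmetry test (flipping the annotation flips the
assignment); the absolute leading/lagging orientation could be mirrored
relative to the original figures without affecting any test of asymmetry.

Asymmetry per substitution class is the exact conditional test of two
Poisson rates: given N = n₁ + n₂, n₁ ~ Binomial(N, ½) under the null, and
the two-sided p doubles the smaller tail, capped at 1 (a Wald rate-ratio
variant is available behind a flag). Per-class p-values are reported raw,
matching per-class asterisks in the source analysis, with
Benjamini-Hochberg values emitted alongside.

## Paired biopsies

Per patient, the two biopsies' 96-type count vectors are normalized with
the median-of-ratios (DESeq2) size-factor estimator — factors come from
types non-zero in every sample of the pair and are standardized to
geometric mean 1, which makes normalization exactly idempotent. Each
type is then tested with a linear mixed model: normalized count ~ drug
indicators + exposure dose + exposure time, with a patient random
intercept. Drugs enter the model only when administered to ≥ 3 patients.
Dose and time are structurally collinear with their drug indicator (they
are non-zero only in exposed intervals), so they are centered within
exposed rows; the drug coefficient then estimates the effect at the
average administered dose and time rather than an extrapolation to zero.

The default p-value is the conditional ANOVA test of the fitted model:
REML estimation and a Wald t on the focal coefficient with the
within-group denominator degrees of freedom N − #patients − #within
fixed terms (the nlme convention). At the 8–20 patient scale this test
holds its size (empirical type-I error ≈ 0.03–0.06 at nominal 0.05 in the
package's own calibration simulations), whereas the maximum-likelihood
likelihood-ratio alternative (available as `method="lrt"`) is mildly
anticonservative (≈ 0.08). A patient random intercept with fixed
dose/time covariates was chosen over random slopes because it remains
identifiable with two biopsies per patient; random-slope structures are
not fitted by default. The scan iterates over all 96 types in canonical
order, reporting raw p-values with BH-adjusted values alongside.

## Driver risk model

Expected driver-activating mutations in N cells accumulating μ mutations
each with spectrum P:

M_active = f_coding · dp · N · μ · Σ_c P_c · n_c / L

with f_coding = 0.015 (exon-coding genome fraction), dp = 0.3094464
(coding-sequence mutational depletion), L = 22,563,618 bp (CDS length),
and n_c the number of distinct genomic positions where a class-c
substitution activates a driver (duplicates collapse; unclassifiable
entries are tallied). μ is parameterized as annual rate × duration in
years because the published account uses both a per-year reading (rates
2000 vs 40 per year give the 50-fold risk ratio) and a per-treatment
reading (a 24-week course at 2000/yr equals ≈ 23.1 years of baseline
accumulation, printed as "about 20 years"); both are reproducible by
choosing the duration. The germline-predisposition scenario re-evaluates
both arms with n restricted to the predisposition gene's inactivating
positions — a documented modeling assumption, since no formula is given
for it. With matched tables the fold reduces exactly to the exposure
ratio. The absolute cohort-scale estimate (~300 oncogenic mutations per
10⁸ colon stem cells per treatment course) requires the external
reference signature-17 spectrum and the validated ~10,000-variant driver
list; the package computes it when given those inputs but ships no copy
of them, so its own tests verify the formula against independent
arithmetic at worked-example values instead.

## Synthetic study conditions

The generators plant every structure the pipeline must detect, at fixed
defaults chosen once as realistic study conditions:

- **Signatures**: a signature-17-like profile (36% C[T>G]T, 15% C[T>C]T,
  9% G[T>G]T, uniform floor), a flat profile, and seeded Dirichlet
  profiles. Signature-recovery runs use 50 samples × 5,000 mutations.
- **Reference + VCF emission**: one trinucleotide per mutation event,
  concatenated into a toy contig, with ~half the events written in the
  purine-strand representation; catalog construction on the emitted files
  reproduces the generating catalog exactly (a construction guarantee,
  tested as the round-trip identity).
- **Clonality**: 70% Normal(1.0, 0.05) + 30% Normal(0.4, 0.05), n = 2,000,
  truncated at 0.
- **Strand bias**: per-variant single-triplet regions oriented so the
  realized assignment is lagging with 3:1 odds for the enriched classes
  (n = 400 mutations from a signature-17-like sample).
- **Paired cohort**: 20 patients, 8 treated (the serial-biopsy cohort had
  8 treated patients), ~3,000 mutations per biopsy, Poisson counts with
  patient-level (σ = 0.15) and per-biopsy (σ = 0.2) lognormal depth
  factors, and a planted +3 Poisson-SD increase on C[T>G]T in treated
  second biopsies.

What passing these conditions does not show: the generators draw
independent multinomial/Poisson counts with clean planted structure —
real catalogs have correlated signature activity, copy-number-driven VAF
distortions, mapping artifacts, flat-signature bleed between similar
reference profiles, and cohort sizes fixed by the clinic, none of which
are emulated. Recovery statistics here bound the method's behavior under
its own assumptions, not its field performance. One measured consequence
of the chosen signature trio: the flat profile and the sig17like uniform
floor are partially collinear, so refit proportion estimates show a
worst-entry deviation of 0.03–0.05 even at 5,000 mutations/sample
(mean deviation ≈ 0.01, Pearson ≥ 0.95).

## Numerical choices and degenerate inputs

- NMF guards denominators with 1e-12; all-zero catalogs and ranks above
  min(96, S) are rejected; a degenerate (constant) consensus reports a
  cophenetic of 1 with a warning.
- Signature columns must sum to 1 within 1e-9; table readers renormalize.
- KDE grid step 0.01; peaks are strict local maxima (plateaus do not
  qualify).
- Empty clonal or subclonal compartments skip the sample with a warning;
  variants missing purity-adjusted VAF or copy number are unassigned.
- Wilcoxon switches from exact to asymptotic at combined n > 25 or on
  ties; mixed-model failures (singular designs, non-convergence) are
  flagged with missing p-values and the scan continues; a flat response
  returns effect 0, p 1.
- Zero-total attribution exposures are an error; zero-denominator classes
  are missing, not zero.

## Known limitations

- The NMF rank heuristic is advisory only (see above); cohort-scale rank
  choices need inspection.
- The paired-biopsy model treats dose and time as fixed covariates; true
  per-drug random-effect structures are not identifiable at this cohort
  size and are not fitted.
- Replication-origin and gene annotations are consumed pre-labeled;
  deriving them from Repli-Seq or annotation databases is out of scope,
  as are read alignment, somatic calling and purity/copy-number
  inference, whose outputs the package consumes.
- The strand-labeling orientation may be mirrored relative to the
  original figures (the convention is internal and symmetric).
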