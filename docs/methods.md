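# Methods

## Scope and data model

The package partitions the additive genetic variance of a trait between
SNP-derived and CNV-derived genomic relationship matrices (GRMs) and
jointly maps SNP/CNV associations with a relaxed LASSO. It starts from
called genotypes and per-animal CNV calls: CNV calling from intensity
data, GC-bias correction, EBV deregression and effective-record
computation are upstream of the pipeline and are consumed as inputs.
Genotypes are held as 0/1/2 dosages with NaN for missing; copy classes
are stored as the integer copy number (0 double-deletion … 4
double-duplication, 2 normal).

## Quality control

Edits run in a fixed order — animal call-rate, SNP call-rate, positional
completeness, Mendelian consistency, ERC — with every threshold strict
("less than 95%", "more than 2%", "ERC < 1" drop; values exactly at a
threshold are retained). SNP call rates are computed over the animals
that survive the animal filter, since the animal edit is applied first.
A Mendelian conflict is an opposing-homozygote duo (parent 0 with
progeny 2 or vice versa); heterozygote-involving duos never conflict,
and duos with a missing genotype leave that SNP's denominator. The
ordered stage counts are recorded in a QC report whose removed+retained
totals reconcile at every stage.

## CNV consensus

Two callers' calls for the same animal and direction are one event iff
both endpoints agree within one SNP, measured in SNP-index space (both
callers operate on the same array, so index distance is the natural
metric; bp distance would depend on local SNP spacing). Matched pairs
are kept once with the first caller's span — a deterministic convention;
the union of both callers' calls with ≥3 SNPs is retained. Loci are the
transitive closure of the same tolerance rule across animals,
irrespective of direction, so a locus carrying both deletions and
duplications is typed "mixed". Loci need ≥3 carriers within some breed.
Copy-class conflicts at one locus resolve to the call covering more
SNPs, deletion winning exact ties. When neither deletion class of a
locus reaches 5 carriers the two deletion classes collapse into one
(duplications symmetrically), mirroring how sparse double classes are
handled before association coding.

## Relationship matrices

G = (M−P)(M−P)ᵀ / 2Σpᵢ(1−pᵢ) with pᵢ the observed frequency of the
+1-coded allele; monomorphic markers leave both numerator and
denominator (the formula is undefined for them). Missing genotypes are
imputed with the within-breed per-SNP mean before coding — at the <5%
missingness guaranteed by QC, the perturbation of G is negligible, and
fractional dosages are legal downstream. The combined SNP+CNV matrix
concatenates coded columns under a single shared denominator, which
makes it exactly the denominator-weighted average of the two GRMs (an
identity the tests assert numerically).

A caution discovered while validating the variance components: under
procedure-2 coding (deletion −1 / normal 0 / duplication +1) a rare CNV
has an implied +1-allele frequency near 0.5, so 2p(1−p) overstates the
column variance by an order of magnitude and the GRM's mean diagonal
falls far below 1. The variance component attached to such a matrix is
nearly unidentified (flat likelihood ridge) at desk scale; the
procedure-1 (carrier-dosage) coding is scale-consistent (mean diagonal
≈ 1) and is the default CNV GRM for variance-component work here. The
two codings give the same boundary conclusion, as the product σc²·G is
what the likelihood sees.

GRM PCA orders eigenpairs by descending eigenvalue, reports scores as
eigenvector·√λ, floors negative eigenvalues at zero for the percentage
shares (raw eigenvalues are also returned).

## Weights and REML

Garrick weights w = (1−h²)/([c+(1−r²)/r²]h²) with c = 0.9 by default
(the fraction of genetic variance not captured by markers); h² is a
required per-trait input. The mixed models premultiply by D^{1/2}
internally, which leaves every variance component unchanged and makes
the residual identity; the reported restricted log-likelihood is that of
the transformed model, so likelihood differences between models on the
same data and weights are exact. The maximizer is average-information
REML: an AI step whose candidate leaves the non-negative orthant is
re-solved with the offending components clamped at the floor
(10⁻⁸·var(y)), step-halved if it would decrease the likelihood, and
replaced by the (monotone) EM update as a last resort; the trace is
asserted non-decreasing. Tolerance 10⁻⁸ on the relative likelihood
change, 200 iterations maximum, non-convergence flagged rather than
silent. GRMs whose smallest eigenvalue is below 10⁻⁸ get 10⁻⁶ added to
the diagonal (logged).

Variance proportions are reported with two denominators, since which the
original analysis used is ambiguous: Σσ²random + σe²·n/Σw (the harmonic
mean of 1/w scales the residual to the average animal) and the plain
unweighted sum.

The likelihood-ratio test for the CNV component uses the ½χ²₀ + ½χ²₁
mixture appropriate for one variance tested on its boundary (plain χ²₁
available by flag). The two-step procedure forms E = y − BLUP(a) from
the SNP-only fit (equivalently residual + intercept) and refits E on the
CNV GRM with the same weights; with unit weights mean(E) equals the
step-1 intercept exactly.

## Association

The selection design premultiplies y and every column by √wᵢ, so the
smooth part of the LASSO objective is the weighted least-squares
criterion; marker columns are then standardized (parameters kept for the
back-transform) while the intercept and the top GRM principal components
(default 10 per GRM) are unpenalized — they are adjustments, not
selection candidates. The penalty is L1: the selection behaviour that
defines the method requires it (a ridge penalty never zeroes
coefficients). Collapsed CNV loci enter as 0/1 carrier indicator
columns; mixed loci contribute one deletion and one duplication column,
consistent with GRM procedure 1.

The solver is cyclic coordinate descent (soft-thresholding penalized
coordinates, exact minimization for unpenalized ones), JIT-compiled when
numba is available, warm-started down a λ path from λ_max (computed
after profiling out the unpenalized columns) over two decades; λ is
chosen by seeded k-fold cross-validation at the minimum mean prediction
error, with a one-standard-error option. KKT conditions are verified at
the returned solution (|xⱼᵀr/N| ≤ λ + 10⁻⁶ for zero penalized
coefficients) and the fit is re-polished if they fail.

The relaxed refit is ordinary least squares on intercept + PCs + the
selected markers jointly; aliased columns are dropped via pivoted QR
(logged) and a ridge-stabilized solve is the fallback when the selected
set is not smaller than n. Effects are reported on the original marker
scale. The per-CNV variance fraction 2pᵢ(1−pᵢ)aᵢ²/σg² takes pᵢ as the
carrier proportion of the collapsed class (the natural reading of a
population frequency for a collapsed indicator) and requires σg² as an
input — synthetic runs pass the simulated truth. Note the formula's
2p(1−p) is the variance of a Hardy–Weinberg dosage, not of a 0/1
indicator (p(1−p)), so fractions for indicator-coded CNVs run high by up
to a factor of two; the formula is kept as the method defines it.

Single-variant re-analysis whitens [1, marker] and y by the Cholesky
factor of V̂ = G_SNP σ̂g² + D⁻¹σ̂e², then runs OLS with the residual
dispersion estimated from the whitened residuals — so with an identity
GRM and unit weights the t-test reduces exactly to ordinary regression.
Null-model components are estimated once and reused across markers
(population parameters previously determined); per-marker REML is
available by refitting.

## QTLs

Each associated variant defines a ±50 kb window; variants of the same
type within 50 kb (inclusive, measured between a SNP's position or a
CNV's span edges) merge by single linkage, and the merged window extends
50 kb past the outermost members, floored at 1 bp. SNP-QTLs and
CNV-QTLs that overlap are cross-referenced as a shared region without
re-merging, so per-type counts are preserved. Gene overlap is ≥1 bp
against a user-supplied BED (converted from 0-based half-open) or GFF3
(1-based) annotation, on the caller's responsibility that coordinates
share an assembly.

## Synthetic populations

The generator emulates the study conditions end to end: per-breed allele
frequencies drift around shared ancestral frequencies via a
Balding–Nichols Beta with Fst 0.05; genotypes are independent
binomial(2, p) draws by default (an optional block-copying mode adds LD
blocks); parent–progeny pairs are generated by true inheritance (one
transmitted parental allele) so opposing-homozygote conflicts occur only
where injected. CNV loci are placed as non-overlapping spans of 5–12
SNPs (≥5 so a 1-SNP inward jitter can never defeat the 3-SNP filter)
with carrier frequencies of 1–5%, directions deletion/duplication/mixed
(45/45/10%), and a 10% chance of a double class per carrier. True
breeding values are a SNP polygenic part plus a CNV part, each rescaled
to its configured sample variance exactly (defaults 0.95 and 0.05 of a
unit σg²); deregressed EBVs add noise of variance σg²(1−r²)/r² for a
reliability drawn from (0.5, 0.95), so the nominal reliability holds by
construction. Caller files jitter each endpoint by ±1 SNP with
probability 0.2 per caller and append 10% two-SNP decoy calls; exact
round-trip recovery can fail only if no call at a locus retains an exact
endpoint while both ±1 shifts occur — probability on the order of
jitter^(2·carriers) per endpoint, negligible at these settings.

What the generator does not emulate: linkage disequilibrium between
CNVs and flanking SNPs (loci are placed independently of causal SNPs),
intensity-level caller behaviour, multi-generation pedigrees, selection,
and sex chromosomes. Passing tests therefore demonstrate correctness of
the estimators and filters under their stated models, not robustness to
array artefacts or to LD structure in real cattle data.

## Problem sizes and numerical choices

Replicate-based checks use populations scaled to the method, chosen as a
compromise a single workstation handles comfortably: REML recovery at
n = 500 with 1000-SNP GRMs (20 replicates), null-CNV runs with 40 CNV
loci at 3% carriers, LRT calibration over 200 replicates at n = 200,
and LASSO recovery at n = 1000 with 250 SNPs. Seeds are fixed
everywhere; identical configurations reproduce byte-identical generator
output. Known limitations: the CNV variance component is weakly
identified when the CNV GRM is badly scaled (see above) or when loci
are very few; variance fractions from indicator-coded CNVs inherit the
factor-two caveat; and the boundary-mixture LRT is mildly conservative
at these sample sizes (empirical type-I error ≈ 0.025 at nominal 0.05).
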