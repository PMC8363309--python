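# Methods

`stepblup` implements a complete genetic-evaluation workflow for a
multi-trait beef-cattle breeding scheme: pedigree and genomic
relationship matrices, single- and multi-trait animal-model BLUP and
single-step GBLUP (ssGBLUP), Bayesian variance-component estimation by
Gibbs sampling, and validation of evaluations with the LR
(partial/whole) method.  Because the motivating data (a Korean beef
progeny-testing scheme) are access-restricted, the package ships a
synthetic generator that reproduces the statistical structure of such a
scheme, and every claim the test suite makes is made on that generator's
output.

## Model

For trait k, records follow the animal model

    y_k = X_k b_k + Z_k u_k + e_k

with fixed effects b_k (contemporary groups, covariates), breeding
values u over all pedigree animals with Var(u) = G0 ⊗ K, and residuals
with Var(e) = R0 ⊗ I applied per animal over its observed traits.  G0
and R0 are the t×t additive-genetic and residual covariance matrices.
K is the pedigree numerator relationship matrix A for BLUP; for ssGBLUP
its inverse is replaced by

    H⁻¹ = A⁻¹ + [0 0; 0 (0.95 G + 0.05 A22)⁻¹ − A22⁻¹]

where G is VanRaden's (method 1) genomic relationship matrix
(`Z Zᵀ / 2Σp_j(1−p_j)`, dosages centred at twice the observed allele
frequencies) and A22 the pedigree block of the genotyped animals.  The
5% blend with A22 guarantees an invertible genomic block; no further
scaling of the H⁻¹ correction is applied, and no compatibility tuning of
G towards A22 beyond the blend (small level differences between genomic
and pedigree EBVs can remain and show up as per-trait LR bias; the
calibration checks therefore assess the bias averaged over carcass
traits).

Single-trait (ST) variants fix all genetic and residual covariances at
zero; multi-trait (MT) variants use the full matrices.  Four evaluators
result: ST-BLUP, MT-BLUP, ST-ssGBLUP, MT-ssGBLUP.

## Pedigree machinery

Pedigrees are validated (no cycles, no dangling parents) and stored
topologically ordered with unknown parents as founders (unrelated,
non-inbred; no genetic groups).  Inbreeding uses Meuwissen & Luo-style
back-tracing; A comes from the tabular method (dense for ≤ 4,000
animals, otherwise blocks are extracted by sparse solves with A⁻¹); A⁻¹
uses Henderson's rules with inbreeding-aware Mendelian-sampling
variances d_i = 0.5 − 0.25(F_s + F_d).

## Mixed-model equations and solvers

The MME are assembled with residual weights equal to the inverse of the
observed-trait submatrix of R0 per animal (the standard multivariate
treatment of trait-wise missing records; each animal has at most one
record per trait).  Identifiability uses drop-first-level reference
coding plus an intercept.  The random block G0⁻¹ ⊗ K⁻¹ is kept implicit:
small systems are solved by sparse LU on the materialized matrix
(≤ 2×10⁶ estimated non-zeros and ≤ 6,000 equations — multi-trait
Kronecker systems suffer severe LU fill-in, so the direct path is
reserved for compact systems); larger ones by conjugate gradients with a
Jacobi preconditioner and a matvec that applies K⁻¹ per trait and mixes
traits through G0⁻¹ (cost t·nnz(K⁻¹) instead of t²·nnz).  Solutions are
accepted only if the relative residual passes the requested tolerance
(default 1e-10 for single solves; the study pipeline uses 1e-8, and the
replicated validation studies 1e-6 — LR statistics are insensitive at
that level).

## Gibbs sampler

Variance components are estimated under the pedigree-based multi-trait
model by a systematic-scan Gibbs sampler in the gibbsf90 tradition:

* location effects by single-site Gauss-Seidel sampling from their
  scalar full conditionals, one sweep per iteration (numba-compiled; the
  coefficient structures are stored once in CSR form with per-entry
  trait-pair labels, so iterations only rescale by the current R0⁻¹ and
  G0⁻¹ entries);
* trait-wise missing records by data augmentation: missing residuals are
  drawn from their conditional normal given the animal's observed
  residuals, restoring complete-data conjugacy.  Augmented records carry
  a fixed intercept-only design row; because the augmented data are
  integrated out, this choice does not affect the observed-data
  posterior;
* G0 ~ IW(ν0 + N, S0 + Uᵀ A⁻¹ U) and R0 ~ IW(ν0 + n_rec, S0 + EᵀE).

Priors default to minimal degrees of freedom ν0 = t + 1 with scale
S0 = 0.5 × the observed (pairwise-complete, PD-clipped) phenotypic
covariance matrix — near-flat against thousands of records.  The full
matrix matters: a diagonal scale centres the implied prior correlation
at zero and was measured to shrink weakly identified genetic
correlations by several hundredths, an artifact the matrix scale
avoids.  Chains also start at that matrix.  The default desk-scale chain is 20,000 iterations
with 5,000 burn-in and thinning 10 (a scaled-down analogue of the
550,000 / 50,000 / 50 production settings, which remain plain
configuration).  Chains are seed-reproducible; effective sample size and
a Geweke-style first/last-segment Z for the heritability traces are
logged but never gated on.  Convergence was checked during development
by comparing window means over a 100,000-iteration chain.

The equilibrium genetic variance σ²_u,∞ used by the LR accuracy
denominator is operationalized as: per retained draw, the empirical
variance (n−1) of the sampled breeding values across the focal animals;
the posterior mean of that quantity.  Under truncation selection it
falls below the base additive variance, as it should.

## LR validation

For a focal cohort (by default the last two birth-year cohorts), the
partial dataset masks focal phenotypes — all of them at the *birth*
stage, only the carcass traits at the *yearling* stage (yearling weight
and ultrasound records are already available then).  Comparing focal
EBVs from partial (û_p) and whole (û_w) evaluations gives

    accuracy   ρ = cov(û_w, û_p) / ((1 + F̄ + 2f̄) σ²_u,∞)
    bias       μ = mean(û_p) − mean(û_w)         (expected 0)
    dispersion b = cov(û_w, û_p) / var(û_p)      (expected 1)

with F̄ and 2f̄ the cohort's mean inbreeding and mean pairwise
relationship from the A block.  As printed, ρ is a covariance over a
variance and thus lives on a squared-accuracy scale; the square root is
also reported (`rho_sqrt`), and the sign of the 2f̄ term is switchable
because published forms of the method differ.  All covariances use the
n−1 divisor (b is divisor-invariant; ρ is not).  Relative gain between
models is the accuracy ratio minus one.  Variance components are
estimated once (or supplied) and held fixed across whole and partial
runs.

## Synthetic data generator

The generator emulates a male progeny-testing station: discrete
generations; each generation mates a small set of sires (default 5% of
the male cohort) to the previous generation's females; each mating
produces male and female offspring in a configurable ratio
(`offspring_per_mating`, default one male + one female).  Males are
performance-tested; a fixed fraction (36%) are castrated (steers).
Recording mirrors the reference scheme: yearling weight on every tested
male, ultrasound traits on the latest-born 56.6% (the "genotyped era"),
carcass traits on steers only (98.9% coverage).  The genotyped subset
fills steer and bull quotas latest-born first with sires prioritized.
At scale 1.0 the counts anchor to 15,796 / 8,945 / 5,622 records, 6,616
genotyped animals and 43,949 SNPs; any scale keeps the proportions.  The
simulated pedigree is shallower than a 20-year production pedigree
(founders are a single unrecorded layer), so absolute accuracies at
desk scale are lower than production values; ordering comparisons
between models are the meaningful quantity.

Generating parameters of the 8-trait preset (YW, UBFT, UEMA, UIMF, BFT,
CW, EMA, MS): heritabilities 0.33 / 0.28 / 0.25 / 0.19 / 0.48 / 0.42 /
0.50 / 0.59; phenotypic means and SDs from the reference population's
descriptive table (e.g. CW 370.5 ± 42.8 kg); genetic correlations
UIMF–MS 0.78, UBFT–BFT 0.63, UEMA–EMA 0.65, YW–CW 0.84, YW–EMA 0.43,
all unreported pairs 0.1; residual correlations derived from the four
reported phenotypic correlations (e.g. YW–CW r_p 0.78 → r_e 0.75),
unreported pairs 0.05.  Both correlation matrices are checked positive
definite at construction.  Phenotypic SDs are interpreted as the
within-contemporary-group SD; contemporary-group effects (SD 0.3 σ_p)
and covariate slopes (0.2 σ_p per SD) sit on top.  Contemporary-group
level counts scale from the reference levels (87–274).

Two genetic architectures: *pedigree* (infinitesimal; BVs flow down the
pedigree with Mendelian-sampling covariance 0.5(1−(F_s+F_d)/2)G0;
markers are neutral) and *marker* (BVs are sums of centred-dosage ×
MVN marker effects over the whole panel, founder-population covariance
G0).  The preset uses the marker architecture: with neutral markers the
genomic matrix carries no Mendelian-sampling information and ssGBLUP
cannot outperform pedigree BLUP even in principle, so the orderings the
package is meant to demonstrate require a genic architecture.  The
pedigree architecture is the default for plain configurations and for
variance-component recovery studies (the reference analysis estimates
components with a pedigree model).

Optional truncation selection picks sires as the top fraction on a
phenotypic index (standardized BV + residual sums) co-flowed during
pedigree construction.  Selecting on the phenotypes that remain in the
dataset keeps selection ignorable for the likelihood-based analyses; the
co-flowed Mendelian deviations ignore parental inbreeding (negligible in
these shallow pedigrees).  Selection is available for the pedigree
architecture only.

## Recovery-study designs

Two dedicated designs support estimator-recovery studies at ~3,000
records over 5 generations:

* heritability: records on both sexes and sire_fraction 0.2 — parent-
  offspring and maternal links push the standard error of ĥ² to
  ~0.02–0.03, so a ±0.05 check measures the estimator, not the mating
  plan (male-only half-sib recording has SE(ĥ²) ≈ 0.07 at the same n);
* genetic correlations: the station pattern (trait A on all tested
  males, trait B on steers) with the preset's family structure
  (sire_fraction 0.05, i.e. ~20 male half-sibs per sire); pilot design
  comparisons showed smaller families (sire_fraction 0.2) or very few
  sires (0.02) give markedly worse identification of r_g when one trait
  is subset-recorded.

Gibbs chains start from half the observed (pairwise-complete)
phenotypic covariance, clipped to positive definite — covariance
components mix slowly, and starting them near plausible values shortens
the burn-in transient.  Even with full-length chains the posterior mean
of r_g varies noticeably across data realizations when the weakly
heritable trait (h² 0.19) pairs with a subset-recorded one
(realization SD ≈ 0.08 at 3,000 records, centred slightly below the
generating value); the well-identified pairs and heritabilities are much
tighter (h² SD ≈ 0.025, YW–CW r_g SD ≈ 0.02).  The reproduction script
therefore reports each recovery quantity as the mean posterior mean over
three independently simulated replicates, which measures the same
estimand while shrinking single-realization luck in both directions.

## Numerical choices and edge cases

* Relationship values are validated: A diagonal = 1 + F, PSD within
  1e-8; symmetric within 1e-8 relative.
* Genotype QC order is fixed: SNP call rate ≥ 0.90 → animal call rate →
  MAF ≥ 0.01 → Hardy-Weinberg heterozygote departure
  |obs − 2p(1−p)| ≤ 0.15, with frequencies recomputed after each step;
  the filter is idempotent.  Residual missing dosages after QC are an
  error (imputation is out of scope); the generator produces complete
  genotypes.
* Ties/degenerate inputs: empty SNP panels, singleton cohorts,
  zero-variance partial EBVs and non-PD covariance inputs raise typed
  errors rather than producing numbers.
* All randomness flows from a single root seed split per stage
  (`numpy.random.SeedSequence`); identical seeds reproduce study
  bundles byte for byte.

## Problem sizes used by the test suite

The replicated validation studies run 20 preset replicates at scale 0.1
(≈ 3,550 pedigree animals, 660 genotyped, 4,400 SNPs); the recovery
studies use ~3,000 phenotyped animals with 20,000-iteration chains;
oracle-equivalence checks use ≤ 200-animal pedigrees against dense
inverses and ≤ 50-animal mixed-model systems against a dense GLS
construction.  These sizes were chosen so the full suite runs on a
single CPU in well under half an hour while keeping every check
statistically meaningful.

## Known limitations

* No genotype imputation, maternal/permanent-environment effects,
  genetic groups, dominance, or threshold models (the 9-point marbling
  score is treated as continuous, as in the reference analysis).
* The LR ρ is reported on the covariance/variance scale as printed in
  its source; users wanting classical accuracies should use
  `rho_sqrt`.
* The generator's pedigree is shallower and its focal cohorts
  proportionally larger than a production scheme's, so absolute
  accuracy levels are not comparable to production values — only
  contrasts between evaluators are.
* Single-site Gibbs mixes slowly for strongly correlated traits with
  heavy missingness; the logged effective sample sizes should be
  consulted before trusting short chains.
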