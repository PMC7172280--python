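# Methods

`wrenfit` quantifies indirect fitness consequences of extra-pair paternity
(EPP) and inbreeding in a cooperatively breeding, highly philopatric
songbird population of the *Malurus* (fairy-wren) type.  This note
documents the models, the estimator and its numerical behaviour, the
synthetic-data generator, and the design choices made where the design was
genuinely open.

## 1. Pairwise relatedness, f, and k

Relatedness r between two individuals is estimated from multi-allelic
codominant markers (microsatellites) with Wang's moment estimator.  At
each locus the dyad's two genotypes fall into one of four *similarity
modes*: identical genotypes; one homozygote and one heterozygote sharing
an allele; two heterozygotes sharing exactly one allele; or no shared
alleles.  Under the two-gene/four-gene IBD model with coefficients
(φ, Δ) — φ the probability of exactly one IBD allele pair, Δ of two —
the mode probabilities are linear in (φ, Δ) with coefficients that are
polynomials in the allele-frequency moments a_m = Σᵢ pᵢ^m (the exact
expressions are derived in the `relatedness` module docstring).  The
estimator is the generalised-least-squares solution for (φ, Δ) over loci,
with each locus's mode indicators weighted by the inverse of their
multinomial covariance under the unrelated null, diag(u) − u uᵀ; then
r̂ = φ̂/2 + Δ̂.

* Frequency moments computed from a finite reference sample use the
  falling-factorial unbiased estimators of Σ p^m (the "sample-size
  correction"); with known population frequencies the plain moments are
  used.  The reference set defaults to *all* genotyped individuals.
* Monomorphic loci carry no relatedness information and are skipped;
  loci missing in either individual are skipped per dyad, and
  `n_loci_used` is recorded.  Dyads with fewer than 4 shared informative
  loci are flagged low-confidence but retained.
* r̂ is unbounded below; negative estimates are retained (they carry real
  information about being *less* related than average).

Calibration with 8 loci × 30 equifrequent alleles (the marker panel the
generator emulates): mean r̂ = 0.000 / 0.250 / 0.500 for unrelated /
half-sib / parent–offspring dyads, with per-dyad SD ≈ 0.066 / 0.107 /
0.055.  The residual tail probability P(r̂/2 > 0.10 | unrelated) ≈ 0.004
matters downstream: it sets the contamination rate of the "inbred"
classification (§6).  The GLS weighting was chosen over a scalar
per-locus weight precisely because it cuts this tail about fourfold at
identical (zero) bias.

The inbreeding coefficient of an offspring is estimated as half the
relatedness of its genetic parents, f = r/2, and the kinship of a social
pair as k = r/2 of the two social partners.  f and k values are binned
with upper-inclusive edges at 0.22, 0.16, 0.10, 0.04 and −0.02, giving
bins centred on the pedigree classes 0.25, 0.1875, 0.125, 0.0625, 0 and
an open bin ≤ −0.0625.  "Highly inbred" (and "close kin" for pairs) means
the 0.125 bin or higher, i.e. a value strictly above 0.10.

## 2. Demography and reproductive values

The life cycle is a two-sex, three-stage annual model — fledgling (first
year after fledging), subordinate (helper), dominant (breeder) — under a
pre-breeding census.  Transitions are parameterised by per-state annual
survival s, the probability t (conditional on survival) of holding a
dominant position the next year (survivors not dominant are
subordinates; fledglings never remain fledglings), and the expected
number of genetic fledglings per state.  Each genetic fledgling is
credited half to its mother and half to its father, so fecundity entries
carry a factor ½ and column sums of reproductive credit add up exactly
once per fledgling.

Reproductive values v are the left eigenvector of the dominant eigenvalue
λ of the 6×6 projection matrix, computed by full eigendecomposition with
a power-iteration fallback, sign-normalised and scaled so
v(dominant ♀) = 1.  Acceptance of the eigenpair requires the relative
residual ‖vᵀA − λvᵀ‖/‖v‖ < 1e−10.  The matrix components are *estimated
from the data tables* (year-to-year state transitions; genetic fledgling
production credited to each parent's state in the offspring's hatch
year), not hard-coded: the empirical parameterisation of a real
population is study-specific and enters only through the data.

## 3. Individual fitness

Fitness over the first three years of life is

W = J₍₀₋₃₎ · v(state at t₃) + ½ Σₜ Σ_y J_{y,t} · v(state_{y,t}),

where J₍₀₋₃₎ indicates surviving all three years and the inner sum runs
over the focal bird's genetic offspring in seasons t₀..t₀+3, each counted
if it survives to the next census and valued at the state it then
occupies (typically subordinate/helper).  Conventions:

* Offspring are credited in their hatch season with their own first-year
  survival as J_y.  The t = t₀ term of the outer sum is retained for
  completeness but is structurally zero (nestlings do not breed in their
  hatch season).
* A bird alive at t₃ without a recorded state is an error, not an
  imputation.
* With all v = 1 the measure collapses to J + ½Y, the simplest
  gene-counting form; each surviving offspring changes W by exactly
  ½·v(its state) (both are tested invariants).

The resulting distribution is bimodal — an exact point mass at zero
(most offspring die before contributing) plus positive non-integer
values — which motivates the hurdle model.

Derived covariates: year quality is the yearly mean number of fledglings
per group, with "poor" = strictly below the across-year mean of those
yearly means; nestling body condition is the OLS residual of mass on
tarsus and age, and relative size the OLS residual of tarsus on age.

## 4. The synthetic-population generator

The generator emulates the study conditions the analysis assumes, with
full pedigree ground truth:

* a ring of territories (default 70), each held by a dominant pair plus
  0–8 subordinate helpers; initial helpers are genetic offspring of the
  founder pair;
* clutches of 1–3 (default probabilities 0.25/0.50/0.25), one brood per
  female-season; whole-brood nest predation at rate 0.70 with a
  logit-normal annual environment effect (SD 0.5) that generates good and
  poor years;
* EPP with baseline probability 0.58 per offspring whose odds scale with
  the social pair's true kinship (odds ratio 8 at k = 0.25); extra-pair
  sires are dominant males of other territories sampled with ring-distance
  decay;
* Mendelian transmission at 8 microsatellite loci × 30 equifrequent
  alleles; founders and immigrants draw genotypes from the configured
  frequencies;
* philopatry: offspring help on the natal territory; dominant vacancies
  are filled by subordinates sampled with strong distance decay (scale
  0.5 territories), so incestuous pairings (father–daughter,
  sib–sib) arise endogenously from limited dispersal; unfillable
  vacancies attract an unrelated immigrant with probability 0.3;
* survival: fledgling 0.45, subordinate 0.85, dominant 0.78 per year
  (both sexes); a 5-year burn-in precedes the genotyped cohorts so kin
  structure develops before sampling.

Under these defaults a 12-cohort run yields ≈ 1350 genotyped offspring
with a realized EPP rate ≈ 0.62, ≈ 14.5% of social pairs close kin
(k > 0.10), ≈ 8% first-order pairs, and ≈ 8% of offspring inbred at the
half-sib level or higher — the regime of a strongly philopatric
fairy-wren population.  Close-kin pairing saturates below the ~17%
reported for the most extreme field populations because high EPP itself
erodes pedigree kinship between social partners; we accept this rather
than force pairings exogenously.

Inbreeding depression is injected as a threshold effect on true pedigree
f > 0.10: a nestling-mass deficit (condition channel), an additive
first-year survival offset, and a reproduction multiplier for inbred
adults.  Because every route to nonzero three-year fitness passes through
surviving the first year, multiplying inbred first-year survival by
(1 − δ) scales expected fitness of inbred offspring by the same factor —
the preset used in the recovery study encodes a 75% reduction this way.

What the generator does *not* emulate: spatial territory geometry beyond
ring distance, individual quality heterogeneity, density dependence,
marker mutation or genotyping error, multi-brooding, and environmental
correlation between survival and reproduction.  Passing tests therefore
demonstrate correct recovery of effects under idealised markers and
demography, not robustness to genotyping error or unmodelled
heterogeneity.

## 5. Mixed models, the hurdle, and model selection

All models are fitted by maximum likelihood (never REML, so
log-likelihoods are comparable across fixed-effect structures).  Random
intercepts — one factor, or nest nested within mother — are integrated
by the Laplace approximation with an O(n) inner Newton solver that
exploits the arrow structure of the nested penalised Hessian; for
Gaussian responses the approximation is exact (verified against the
closed-form multivariate-normal density to 1e−8).  Families: Bernoulli
(logit), Gaussian (residual SD an ML parameter), and zero-inflated
Poisson (scalar zero-inflation on the logit scale, random intercept on
the count part; verified against statsmodels' ZeroInflatedPoisson ML).

The hurdle model for fitness fits (1) a logistic mixed model for
1{W > 0} on all rows and (2) a Gaussian mixed model for W on the
positive rows, both with the candidate's predictor set and nested
mother/nest intercepts; the joint log-likelihood is the exact sum.  A
candidate term that is constant within the positive subset (e.g. a rare
threshold factor none of whose carriers have positive fitness — exactly
the strong-effect regime) is unidentifiable there and is fitted in the
zero part only, rather than failing the whole candidate; it contributes
no parameter to part 2.

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting fixed effects,
random-effect SDs, and family extras, and n the number of observations
(all rows for the hurdle).  All-subset selection enumerates every
admissible subset of candidate terms (a covariate's linear and threshold
forms never co-occur), sorts by AICc with ties broken by smaller k then
lexicographic term order, and reports ΔAICc and Akaike weights.
Continuous covariates are z-scored at design-matrix construction; 0/1
factors are not scaled.  Non-convergent candidates are recorded and
excluded from the weights.

Paired EPO–WPO contrasts use one randomly chosen (seeded) EPO and WPO
per mixed-paternity brood and the Wilcoxon signed-rank test: zero
differences dropped, midranks for tied |differences| (which can make the
V statistic fractional), exact p by rank-sum convolution for n ≤ 25
without ties, otherwise a normal approximation with tie and continuity
corrections.

## 6. The parameter-recovery study and its findings

The recovery study (`wrenfit.recovery`) runs replicate populations with
the 75% threshold fitness cost and no direct EPO–WPO effect, at ≈ 1350
offspring per replicate, and asks whether the full marker-based pipeline
recovers the injected signal.  Candidate terms for the hurdle selection
are EPP, the inbred threshold flag, linear f (exclusive with the flag),
and year quality; 20 replicates are used in the test suite and 12 in the
acceptance script — sizes chosen to estimate the replicate-level rates
while keeping a full run in minutes on one CPU.

Findings worth recording:

* The estimated inbred-vs-noninbred fitness ratio averages ≈ 0.24
  (true 0.25), but is highly variable per replicate (SD ≈ 0.15) because
  only ≈ 80 offspring per replicate are inbred and few of those survive.
* *Errors-in-variables blunts threshold recovery.*  f is estimated with
  SD ≈ 0.03 from 7–8 loci, which smooths the true step at f = 0.10 into
  a sigmoid in f̂; the linear form of f is then genuinely competitive.
  Across replicates the top model contains the threshold flag about half
  the time and *some* inbreeding predictor ≈ 86% of the time.  With the
  threshold known exactly (no marker noise) the threshold form wins the
  AICc comparison in ≥ 75% of replicates (tested in the inference
  suite), so the attenuation is a property of the measurement, not of
  the selection machinery.
* *EPP is not a perfect null here.*  Because EPP reduces offspring f and
  inbreeding is costly, EPO carry a real marginal fitness advantage;
  whenever the fitted inbreeding term cannot fully absorb f (estimation
  noise guarantees it cannot), EPP retains residual signal and enters
  the top model more often than pure type-I noise would predict
  (roughly a quarter of replicates).

## 7. Numerical choices and degenerate inputs

* Outer optimisation by L-BFGS-B on (β, log SDs, extras) with bounds
  log SD ∈ [−6, 4]; a boundary fit flags a pinned variance.  Model
  selection uses slightly looser tolerances (ftol 1e−9, gtol 1e−4) than
  direct fits (1e−11 / 1e−7); AICc differences are far coarser than
  either.  A Nelder-Mead polish runs only on reported non-convergence.
* Inner Newton mode search: damped steps with objective-based
  step-halving; negative curvature (possible for the ZIP zero class) is
  clamped for the Hessian while the objective decides acceptance.
* Degenerate inputs fail loudly: constant responses, rank-deficient
  designs, all-zero counts, hurdle responses without zeros or with < 10
  positive rows, non-nested second grouping factors, AICc with
  n ≤ k + 1, non-finite coefficients at binning.
* GenePop output uses 3-digit allele codes and 000000 for a missing
  genotype; CSV missing values are empty fields; years are integer
  breeding-season labels.
* The empty population writes valid header-only tables; a monomorphic
  locus is excluded from relatedness with a warning.
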