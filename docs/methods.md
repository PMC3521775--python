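# Methods

## The model

`flamexp` fits a multievent (hidden-Markov) capture–recapture model of
breeding probability as a function of age and breeding experience, of the
kind used for long-lived colonial birds where only breeders visit the
colony and detection is imperfect.  Each marked individual — ringed as a
chick, age 0 — moves between hidden biological states

    N_e  alive, skipping this season, e previous breeding experiences
    B_e  alive, breeding this season, e previous experiences
    DEAD absorbing (mortality and permanent emigration together:
         survival is *apparent* survival)

with e = 0 .. K−1 and the top level pooled ("K−1 or more").  Between
seasons the bird survives with probability φ (two age classes: first-year
and adult; a "normal" and a one-step "cold-spell" regime), then —
conditional on survival — breeds with probability β(a, e) indexed by the
age a it reaches at the destination season and the experience count e it
carries into it.  Leaving a breeding season increments e (capped at the
pooled level), so B_e is transitory.  β is structurally zero below the age
at maturity (a_min = 3) and ages above a_pool share one pooled class.
At each occasion a breeder is seen ("code 1") with the year's detection
probability p_t; non-breeders are off-colony, hence unobservable, which is
also how "detection fixed to zero in the first two years of life" is
realized: a pre-breeder cannot emit a 1 regardless of p.

The likelihood of an encounter history, conditional on release into N_0 at
the ringing occasion, is computed with the scaled forward recursion
(transition matrix, then emission weight, then renormalization, log of the
normalizer accumulated).  This equals the sum over all latent state paths
of the product of step probabilities and cannot underflow on 25-occasion
histories.  Identical histories are aggregated with a multiplicity; the
model deviance is −2 Σ multiplicity · log-likelihood.

A `FastLikelihood` engine resolves every per-step cell lookup into integer
indices once per model, so repeated evaluations during optimization are
pure array arithmetic.  It is checked against the reference matrix-based
path to 1e−12 in the test suite.

## Individual random effect

Heterogeneity in breeding propensity is modelled as a static additive
effect u_i ~ N(0, σ²) on the logit of every β cell of individual i
(survival and detection unaffected).  The marginal likelihood integrates u
out by Gauss–Hermite quadrature,

    P(h) ≈ Σ_j (w_j/√π) · P(h | u = √2 σ x_j),

with 15 nodes by default: for logit-normal mixing over histories of this
length the quadrature error at 15 nodes is far below the Monte-Carlo noise
of any feasible dataset (the suite verifies agreement with dense-grid
integration to 1e−6 and monotone error decay in the node count).  At σ = 0
the rule is exact for any node count and reduces to the fixed-effect
likelihood.  Because the effect is shared across a bird's β cells only,
identical histories still have identical marginal probabilities, so
multiplicity aggregation remains valid.  The profile at u = 0 is the
"average individual"; the population mean breeding proportion differs from
it (Jensen), which the simulation tests exhibit.

## Estimation

The deviance is minimized by L-BFGS-B from several random starts
(logit coefficients ~ U(−2, 2); multievent likelihoods are multimodal), σ
bounded below by 0.  Gradients are finite-difference (central "3-point" by
default; a cheaper "2-point" option exists for replicate studies).  With
deviances of order 10⁴ the numerical gradient carries a noise floor near
10⁻³, so convergence is declared on the optimizer's success flag or a
scale-aware criterion max|∇D| ≤ 10⁻⁶·(1 + D); a single cold restart
recovers from line-search breakdown at the noise floor.  Standard errors
are quasi-likelihood: 2·ĉ·H⁻¹ with H the numerically differentiated
Hessian of the deviance, mapped to the probability scale by the delta
method.  Estimates with |logit| > 15 are flagged as boundary cases.

ĉ (the variance inflation factor) is an *input*, estimated externally from
a goodness-of-fit test of a general reference model; the package uses it
for QAIC = deviance/ĉ + 2k and for SE inflation, with k the model rank
(free cells minus any diagnosed rank deficiency).  The QAIC arithmetic
reproduces the published fixed-effect ΔQAIC values (86.76, 340.79, 402.20,
757.69) from printed deviances and ranks to ±0.03, the slack introduced by
rounding ĉ itself to 2.244.

## Identifiability

Whether every free cell is separately estimable is diagnosed numerically:
stack the probabilities of *every* possible encounter-history class for a
set of cohorts, differentiate with respect to the free link-scale
coefficients (central differences), column-equilibrate, and take the
numerical rank (singular values above 1e−6 of the largest) at ≥3 random
interior points (median across points).  Column equilibration matters:
rank is invariant to it, but it cleanly separates exact redundancies
(singular values ~1e−12) from merely weakly identified combinations.  When
a deficiency is found, each cell is scored by the factor by which the
smallest singular value recovers when that cell's column is deleted
("repair ratio"): cells participating in the redundancy repair it by
orders of magnitude, others leave it unchanged.  This replaces the
symbolic half of hybrid symbolic–numeric redundancy methods with a purely
numeric decision that agrees with a dense finite-difference Jacobian
oracle on small structures.

The canonical redundancy in this design — first-year survival confounded
with the breeding probabilities of inexperienced birds, because a
pre-recruit is unobservable and its survival can be traded against the
latent recruitment-age distribution — is exhibited in the suite on a
2-experience-level structure with the top age class pooled (T = 8,
4 cohorts): first-year survival free gives deficiency 1 with the repair
set {φ_first, β(·, e=0), …}; fixing φ_first at 0.763 restores full rank.
At these miniature sizes the exact redundancy is structure-dependent (the
3-level miniature of the same depth happens to be full-rank), so the
diagnostic — not one particular structure — is the deliverable.
Exhaustive history-class enumeration restricts the diagnostic to short
occasion axes; it probes model structure, not data volume.

## Synthetic data

The generator emulates the target study design: 21 cohorts ringed
1977–1997 (700/cohort at full scale), resighting through 2001, detection
of breeders only, maturity at 3, a one-step cold-spell survival shock
between the 1984 and 1985 seasons, and an optional logit-normal individual
effect.  Defaults: φ_first,normal = 0.763 (the externally derived value
the model also fixes), φ_first,cold = 0.589, φ_adult = 0.96 normal / 0.88
cold; detection cycles 0.6/0.75/0.9 across years; the β table encodes only
the qualitative published shape — less-experienced curves rising to a peak
near age 8 then declining (peaks 0.30 and 0.55 at the default three
levels), the most-experienced curve rising past 0.9 by age 15 — with no
number read off a figure.  One master seed; per-individual substreams are
derived from (seed, cohort, index), so resizing one cohort leaves every
other individual's draws untouched.

Fixture scales (chosen so the full suite runs on one CPU in minutes):
`tiny` = 3 cohorts × 50 × 6 occasions (unit tests), `small` = 10 × 300 × 12
(recovery studies; ~3 000 birds), `study` = 21 × 700 × 25 (the full
design, ~14 700 birds).  The recovery study fits 20 independent `small`
replicates and requires ≥90% of well-exposed cells (≥100 effective
exposures, counted from the latent truth) within 3 SE of truth; the
random-effect study recovers σ = 0.8 within 3 SE from a single replicate.

What the generator does *not* emulate: year-to-year variation in cohort
sizes and survival (beyond the single cold-spell step), breeding-site
structure, pair-bond effects, sex differences, observable non-breeders,
and Markovian (rather than static) heterogeneity.  Passing recovery tests
therefore show the estimator is consistent and calibrated *under the
model's own assumptions*, not that the model is adequate for any real
colony's data.

## Numerical choices and edge cases

- Logit link everywhere; fixed cells are held exactly on the probability
  scale (0.763 stays 0.763, not expit(logit(0.763)) rounded).
- Structural zeros (β below maturity, p at occasions without a cell) are
  not parameters: they stay 0 under any individual effect.
- Unattainable β cells (experience exceeding seasons since maturity,
  e > a − a_min) are excluded from the parameter set, so rank diagnostics
  never see all-zero Jacobian columns.
- A history with a detection at an occasion with no detection cell is
  rejected at model construction (the likelihood would be identically 0).
- Impossible histories return −∞ log-likelihood and make the deviance +∞;
  the optimizer never sees them for validated data.
- ΔQAIC ties in comparison tables are broken by smaller k.
- The .inp dialect writes the ringing occasion as a release marker `1`
  plus a `/* cohort=YEAR */` comment; the marker is needed to keep plain
  MARK-style lines parseable, the comment to disambiguate all-zero
  histories.  Internally the release record is always code 0 and never a
  detection.

## Known limitations

- The exact model rank of the original 25-occasion analysis (k = 87) is
  not reconstructable from published information (the age range of β cells
  and the number of free p cells are unstated); k is therefore always
  computed from the spec at hand, never asserted.
- Published ΔQAIC rows for the random-effect and
  experience-on-survival models are not consistent with
  ΔQAIC = ΔDev/ĉ + 2Δk from the printed deviances; the package implements
  that standard formula, which exactly explains the four fixed-effect
  comparison rows, and leaves the others unexplained.
- Standard errors at boundary estimates (probabilities at 0/1) are
  reported as 0 with a flag; profile-likelihood intervals are out of
  scope.
- The random-effect deviance is a marginal deviance; comparing it with
  fixed-effect deviances via QAIC inherits the usual ambiguity of
  information criteria for mixed models.
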