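# flamexp

Multievent capture–recapture models of **breeding probability as a function
of age and breeding experience**, for long-lived colonial birds (the
motivating system is the greater flamingo *Phoenicopterus roseus* colony of
the Camargue) where only breeders attend the colony and detection is
imperfect.

## The problem and the model

Encounter histories of chicks ringed at age 0 record, per breeding season,
`1` = seen breeding or `0` = not seen.  A `0` is ambiguous: the bird may be
dead, alive but skipping, or breeding but missed — so the number of
previous breeding episodes ("local experience") is itself unobserved.  The
package treats the history as emissions of a hidden Markov chain over
states `N_e` (non-breeder with `e` previous experiences), `B_e` (breeder),
and `DEAD`, with

- **φ** — apparent survival (two age classes, first-year vs adult, with a
  one-step "cold-spell" regime for a severe winter mortality event),
- **β(a, e)** — probability, conditional on survival, of breeding at age
  `a` with experience `e` (zero below maturity at age 3; top experience
  and age classes pooled),
- **p_t** — year-specific detection of a breeder (non-breeders are
  off-colony and unobservable),
- optionally a static individual effect `u_i ~ N(0, σ²)` on logit β,
  integrated out by Gauss–Hermite quadrature.

The exact likelihood is the scaled forward algorithm conditional on release
into `N_0`.  Models are compared by QAIC = deviance/ĉ + 2k under an
externally estimated overdispersion factor ĉ, and parameter redundancy
(e.g. first-year survival confounded with the breeding probabilities of
inexperienced birds) is diagnosed by the numerical rank of the
history-class probability Jacobian.  A seeded synthetic generator
reproduces the full study design (21 cohorts 1977–1997, resighting to
2001, cold spell between the 1984 and 1985 seasons) with complete latent
truth, so every estimator is testable without field data.

## Worked example

```python
import flamexp as fx

# a scaled-down study: 10 cohorts x 300 chicks x 12 seasons, no heterogeneity
sim, spec = fx.make_fixture("small", seed=21)
model = fx.BreedingExperienceModel(spec, sim.histories)
result = model.fit(n_starts=1, seed=0)
print(result.summary())
```

prints (abridged):

```
Breeding-experience multievent model
====================================================
experience levels (K):     3
occasions:                 12
individuals:               3000
deviance:                  7002.12
rank k:                    27
c-hat:                     1.0
QAIC:                      7056.12
converged:                 True (max |grad| 5.15e-04, start 0/1)
fixed cells:               phi[first,normal]=0.763
...
breeding probability by age x experience:
      e=0   e=1  e=2+
age
3   0.043   NaN   NaN
4   0.073 0.225   NaN
5   0.153 0.219 0.194
6   0.217 0.415 0.214
7   0.250 0.555 0.270
8+  0.271 0.534 0.343
```

Read it as: with first-year survival fixed at 0.763 (it is not separately
estimable from the inexperienced birds' breeding probabilities — see the
rank diagnostic below), the fitted breeding probabilities rise with age
and, at every age, with experience; `NaN` marks age × experience
combinations that cannot occur (experience cannot exceed seasons since
maturity).  The generating truth for this fixture lies within 3 standard
errors of the well-exposed cells, which is exactly what the recovery test
suite checks across 20 replicates.

The identifiability diagnostic that motivates fixing first-year survival:

```python
spec2 = fx.ModelSpec(K=2, n_occasions=8, a_pool=6)
print(fx.numeric_rank(spec2, cohort_indices=(0, 1, 2, 3)))
# numeric rank 13 of 14 free cells (deficiency 1); confounded cells:
# phi[first,normal], beta[3,0], beta[4,0], ...
print(fx.numeric_rank(spec2.with_fixed(**{"phi[first,normal]": 0.763}),
                      cohort_indices=(0, 1, 2, 3)))
# numeric rank 13 of 13 free cells (deficiency 0): all cells separately estimable
```

QAIC model comparison works directly from deviances and ranks:

```python
fx.delta_qaic((54047.69, 67), (53763.22, 87), chat=2.244)   # -> 86.77
fx.emigration_fraction(0.632, 0.763)                        # -> 0.1717
```

A thin CLI mirrors the library: `flamexp simulate`, `flamexp fit`,
`flamexp compare`, `flamexp io summarize` (see `--help`).

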