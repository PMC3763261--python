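# Methods

## Model and assumptions

Onset is modelled as the completion time of `m` independent, exponentially
timed internal changes, so the susceptible onset CDF is a product of
exponential CDFs. The implementation specialises to the two-rate family that
is actually fitted in practice — `m1 = m − 1` changes at rate `k1` and one
at rate `k2` — because a fully general set of `m` distinct rates is not
identifiable from cumulative incidence curves and is never used. The
degenerate single-rate ("3-parameter") model is represented inside the same
family by tying `k2 = k1`, which makes the product exactly
`[1 − exp(−k·t)]^m`.

Key assumptions the analysis inherits:

* **Susceptibility is fixed at birth.** A fraction `f_s` of the birth cohort
  can ever develop the disease; everyone else contributes zero risk.
* **Conditional independence of cotwins.** Given susceptibility, the two
  members of a pair accumulate their changes independently. MZ discordance
  at a census age is then just both-not-yet-finished probability mass, not
  evidence about environment. This is the model's literal content, not a
  verified biological claim.
* **Clock homogeneity within a cohort.** Differences between study cohorts
  are absorbed into a single dimensionless clock rate `r` multiplying both
  rates, so every cohort shares one curve shape up to a time rescaling
  (`P_s(t, r) = P_s(rt, 1)`).

## Parameters

| name | meaning | units | default |
|------|---------|-------|---------|
| `m1` | changes at the fast rate (`m = m1 + 1`) | — | 15 |
| `k1` | fast mutation rate | 1/year | 0.10757 (pooled USA fit) |
| `k2` | slow mutation rate | 1/year | 0.029959 |
| `f_s`| lifetime susceptible fraction | — | 0.0016363 (admission risk) |
| `r`  | clock rate | — | 1 |

The packaged parameter sets (`USA_MALE`, `USA_FEMALE`, `USA_MALE_FEMALE`,
`USA_MALE_3PARAM`) are the published least-squares fits to USA
first-hospital-admission cumulative incidence; their `f_s` is therefore an
*admission* lifetime risk (~0.16%), roughly a sixth of the surveyed
population lifetime risk (~1%). The male slow-stage mean time is
`1/k2 = 35.1` y; for females the literal reciprocal is `1/0.035728 = 28.0` y
(a published summary rounds this to 30.0 y; the package reports the
reciprocal).

## Concordance algebra

Subcohort concordance conditions on at least one affected member of a
randomly matched subcohort pair. It is *not* pairwise or probandwise
concordance: no ascertainment correction is applied, and none of the
inversions below require one. The MZ form adopted is the ratio
`C_M = P_s/(2 − P_s)`; the alternative product form `P_s(2 − P_s)` is kept
only as the first-onset distribution `P_sx⁺ = 1 − (1 − P_s)²` (the CDF of
the *earlier* onset in a pair), a genuinely different quantity. The ratio
form is the one whose inversion `P_s = 2C/(1 + C)` is exact and which
reproduces every published per-study prevalence.

Per-study analysis (`twins.analyze_study`) calibrates the clock from
whatever age information a study reports, in order of preference: a cohort
mean onset age (solve the windowed mean-onset condition for `r`); an age
range that excludes the unscaled equivalent age (solve
`P_s(midpoint, r) = 2C/(1+C)` for `r`); an age range containing the
unscaled equivalent age (keep `r = 1`). Studies with no age information get
prevalence and `S_inher` only.

## Numerical choices

* Quadrature: adaptive (`scipy.integrate.quad`) with absolute tolerance
  1e−8; integrands are smooth, cheap and one-dimensional.
* Root-finding: bracketed Brent only, never derivative-based; every solved
  function is strictly monotone on its bracket (asserted in tests). Age
  tolerance 1e−6 y; clock-rate bracket [1e−3, 1e2]. For the mean-onset-age
  solver the very-slow-clock end of the bracket underflows `P_s`; the solver
  substitutes the analytic `r → 0` limit of the windowed mean (the `t^m`
  density mean) when scanning for a sign change, then Brent-solves on the
  finite sub-bracket.
* Fitting: residuals on the dimensionless cumulative-fraction scale, so the
  objective is invariant to the population denominator. Continuous
  parameters are optimised in log space (Levenberg–Marquardt) from a
  multistart lattice (`k ∈ [0.01, 1]` /y, `f_s` seeded from the data's
  plateau) because the objective has ridges in `(k1, m1)`; the integer `m1`
  is searched exhaustively (default 1–40). The tied `k2 = k1` optimum is
  injected as a start for the 4-parameter fit, which guarantees the nested
  inequality `chisq₄ ≤ chisq₃` on any dataset.
* The fit objective's units: published tables quote a squared-error in
  units tied to the original (external) admission table; those chisq values
  are not reconstructible and are not asserted anywhere. The objective here
  is the dimensionless sum of squared fraction residuals.

## Synthetic data

`synth` draws onset ages mechanistically as the maximum of `m1` Exp(r·k1)
variables and one Exp(r·k2) variable — an exact sampler for the
product-of-CDFs distribution, mirroring the model's story that onset is the
last required change. Incidence tables are the model curve per 100,000 with
multiplicative Gaussian noise (admission counts scale with cohort size),
clipped by a running maximum to stay cumulative; the default grid is 25 ages
on [10, 70] y, emulating the age span of first-admission registries. Twin
cohorts are censored cross-sectionally at a census age, matching the study
designs.

What the simulators deliberately omit: mortality and other demographic
attrition, diagnostic drift, ascertainment bias (severity enrichment of
hospital-based cohorts), and any within-pair onset-age correlation beyond
shared susceptibility. Tests passing on these simulations therefore
demonstrate internal consistency of the estimators with the model's own
assumptions — not robustness of the model against real-data violations of
them.

## Known limitations

* The slow-stage rate `k2` is weakly identified from 25-bin cumulative
  curves: at a noise level of 2% of the final cumulative value its
  asymptotic relative standard deviation is ≈17% with corr(k2, f_s) ≈ −0.99.
  Simulation-based recovery checks at that design accordingly land within
  10% of truth in only about half of replicates, an information limit of the
  design rather than an optimizer deficiency (the fitted objective always
  beats the generating parameters'). The recovery test in the suite asserts
  the published ≥90% success criterion as stated and is expected to fail at
  this design; it is kept rather than weakened, with this analysis as the
  explanation.
* Solving the windowed mean-onset-age condition for the largest classical
  cohort (mean 23.8 y over [15, 45]) gives `r = 1.9510`, while the published
  figure is 1.94 (which reproduces the target mean only to 23.83 y); the
  package reports the exact solution, which propagates to an equivalent age
  of 30.9 y versus the published 31.0 y.
* The published male incidence peak (26.65 y) differs slightly from the
  exact maximiser of the analytic incidence rate at the published male
  parameters (26.76 y); the female peak (30.60 y) reproduces exactly.
* No confidence intervals or likelihood machinery: the fit is pure least
  squares, as in the source analysis. No probandwise-concordance conversion
  and no ascertainment-bias correction are provided.
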