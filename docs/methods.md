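# Methods

`moltcurve` estimates the within-season dynamics of coat molt (shedding of
the winter pelage) in mountain goats from opportunistically collected,
already-scored photographs. This note documents the model, the priors, the
sampler, the synthetic-data generator, and the numerical and design choices
a user should know before trusting or extending the results.

## The observation unit

One photograph yields one record: calendar year, day of year (DOY),
latitude (°N), elevation (m), an estimated fraction of winter coat shed in
[0, 1], and a six-level animal-state code combining sex and kid-at-heel
status — FN (female, no kid), FY (female with kid), MN (male), plus the
ambiguous codes FX, XN, XX where sex and/or kid status could not be
determined. Males are never accompanied by kids in-model, so XN (no kid
visible, sex unknown) can hide only FN or MN, never FY.

## Within-season model

The expected shed fraction at year-fraction `t = DOY / 365` is logistic,

    f(t) = exp(α (t − τ)) / (1 + exp(α (t − τ)))

where τ is the date at which half the coat is shed and α the shedding rate
(units 1/year; the peak shedding speed is α/4 at t = τ). Both parameters
are linear in predictors:

    τ = τ0 + τM·xM + τK·xK + τE·zE + τL·zL + τY·y + τ[y]
    α = α0 + αM·xM + αK·xK + αE·zE + αL·zL + αY·y + α[y]

with xM, xK the male and kid indicators, zE, zL the z-scored elevation and
latitude, y the calendar year centred at 2000, and τ[y], α[y] zero-mean
year random effects drawn from t-distributions with scales στ, σα and
degrees of freedom ητ, ηα. σ is implemented as the t *scale* parameter
(the Stan `student_t` convention), not the standard deviation; for the
estimated dof around 15–20 the two differ by under 7%.

## Observation error

Scored shed fractions carry digitization and orientation error, so they are
coarsened into N equal bins (N = 25 by default; N = 100 supported) with
`n = round(f·N)`, ties rounded half-away-from-zero (configurable). The
count n out of N is beta-binomial with mean N·f(t) and a single
overdispersion parameter φ shared by all records, parameterized so the
variance inflation over the binomial is

    v = 1 + (N − 1) φ / (1 + φ).

Matching v to the standard beta-binomial shape parameterization forces
a + b = 1/φ, i.e. shapes a = f/φ, b = (1 − f)/φ; a Monte-Carlo test
verifies this derivation against direct simulation. f is clamped to
[1e−9, 1 − 1e−9] before the shapes are formed so extreme t − τ cannot
produce degenerate shapes.

## Ambiguous states: the mixture likelihood

Let p be the fraction of photographed animals that are female and q the
fraction of females with a kid, so unambiguous states FN, FY, MN occur with
probabilities p(1−q), pq, 1−p. Ambiguous records contribute mixtures of
the three state-specific beta-binomial pmfs:

    Pr(n | FX) = (1−q)·P(n|FN) + q·P(n|FY)
    Pr(n | XN) = [p(1−q)·P(n|FN) + (1−p)·P(n|MN)] / [p(1−q) + (1−p)]
    Pr(n | XX) = p(1−q)·P(n|FN) + pq·P(n|FY) + (1−p)·P(n|MN)

Unambiguous records condition on their state and bypass p and q entirely.
Mixtures are evaluated in log space with log-sum-exp.

Two consequences of this structure are worth stating plainly:

- **The mixture weights assume ignorable masking.** Conditioning an
  ambiguous record on the population weights is exact only when the
  probability of landing in that ambiguous class is the same for every
  compatible true state. If, say, females with kids are rarely masked
  (a visible kid certifies both sex and status) while lone animals often
  are, the XX pool is enriched in males and the fitted p drifts toward an
  "effective" value below the population one. The package's generator
  defaults to class-uniform (ignorable) masking; a state-dependent
  `ObserverMasking` variant is provided to reproduce realistic archives
  and demonstrate exactly this bias.
- **p and q are weakly identified.** With masking ignorable, information
  about p comes only from deconvolving heavily overlapping mixture
  components; profiling shows a few log-likelihood units across p in
  [0.5, 0.8] even at thousands of records. Expect wide p/q posteriors at
  realistic sample sizes; the state-frequency diagnostic
  (`check_state_frequency_assumption`) gives the direct empirical
  estimates from unambiguous records.

## Model variants

- **Community**: full model above; 19 hyperparameters plus two year
  random-effect vectors.
- **Captive**: repeated measures of 14 known animals at one site in one
  season; environment and year terms are absent and a single t-distributed
  per-animal random effect acts on shedding date (hyperparameters τ0, τM,
  τK, α0, αM, αK, φ, σID, ηID). All states are known, so no mixture.

## Priors

Weakly informative defaults (Normal's second argument is an SD,
Gamma(a, b) has mean a/b, Exponential(a) mean 1/a):

| parameter | prior |
|---|---|
| p, q, τ0 | Beta(2, 2) |
| τM, τK, τY, τE, τL | Normal(0, 0.1) |
| α0 | Normal(25, 5) |
| αM, αK | Normal(0, 20) |
| αY, αE, αL | Normal(0, 1) |
| φ | Exponential(1) |
| στ, σID | Exponential(10) |
| σα | Exponential(1) |
| ητ, ηα, ηID | Gamma(2, 0.1) |

## Sampling

Fitting runs on an unconstrained reparameterization: logit for p, q, τ0;
log for φ and the scales; η = 1 + exp(u) for the degrees of freedom
(bounding them above 1 truncates about 0.5% of the Gamma(2, 0.1) prior
mass — the scale-mixture region below 1 is numerically fragile and
scientifically uninteresting here); random effects are non-centred
(effect = scale × standardized-t draw), which removes the scale–effect
funnel. Priors are evaluated on the constrained scale with Jacobian terms.

The engine is the affine-invariant ensemble sampler (emcee) with
differential-evolution moves (DEMove 80% / DESnookerMove 20%), which mix
far better than stretch moves on this ~25–50-dimensional correlated
posterior. A "chain" is an independently seeded walker ensemble (walkers =
max(48, 2·ndim + 2)); defaults are 3 chains × (1,000 warm-up + 1,000
retained) ensemble steps. Retained draws keep step order so split-R̂
across chains is meaningful; the fit attaches `max_rhat` to the posterior
and warns (never silently passes) above 1.01. By default walkers start in
a small ball around a numerically located posterior mode (batched
finite-difference L-BFGS); `FitConfig(init="prior")` restores fully
prior-dispersed starts at the cost of longer warm-up.

Summaries are equal-tailed 89% credible intervals (5.5%/94.5% quantiles —
the convention of the applied-Bayes literature this model family comes
from; HPD intervals were the other candidate and differ little for these
unimodal marginals). Date offsets are also reported ×365 as days. A
parameter "has an effect" when zero lies outside its 89% interval.

## Synthetic data

`SimTruth` defaults define the reference scenario, chosen to emulate the
community archive the model targets: 562 records over 14 years
(1988–2018, geometric skew toward recent years), DOY uniform on
[140, 260] (bracketing the observed shedding period), latitude/elevation
bivariate normal anchored at 49.14°N / 2,025 m with correlation −0.783
(elevation truncated at 0 by resampling, which attenuates the realized
correlation by ~0.02 in the default scenario), and truth parameters at the
literature's community posterior medians (τ0 = 0.533, τM = −4.38 d,
τK = +6.20 d, α0 = 22.3, φ = 0.264, p = 0.666, q = 0.5, ...).

Masking defaults are class-uniform: any female becomes FX with
probability .141, any kidless-looking animal XN with .0045, anyone XX with
.289 — calibrated to the archive's overall ambiguous-class fractions
(~39% ambiguous). Masking never depends on the shed count given the true
state (missing at random), and a conditional-independence test asserts
this. What the default generator does *not* reproduce: the archive's
state-dependent observability (use `ObserverMasking` for that, accepting
the p bias it implies), per-site spatial clustering of covariates, and any
duplicate-photograph structure. Passing recovery tests therefore
demonstrate correctness of the fitting machinery under the model's own
assumptions, not robustness to these real-data violations.

The captive scenario mirrors the repeated-measures study: 14 animals
(9 FN, 3 FY, 2 MN), 4 photographs each across one season, truths at the
captive posterior medians (τM = −29.2 d, τK = +21.2 d, αM = +35.9,
φ = 0.039, σID = 0.019).

## Recovery harness and problem sizes

`run_recovery` simulates, fits and summarizes per replicate, reporting
per-parameter 89%-CI coverage, median bias and effect-detection rates.
Replicate seeds derive from the scenario seed; z-transforms are anchored at
the generator's covariate moments so slope truths are defined in the units
the fit estimates.

The shipped test suite uses budgets chosen to run comfortably on a single
CPU: community recovery replicates fit 2 chains × (1,200 + 1,200) ensemble
steps at the full 562-record scenario; the null-effect calibration uses a
300-record, 6-year scenario; captive replicates use 2 × (800 + 800). The
acceptance script fits single community/captive replicates with 3 chains at
larger step budgets (2,500 + 2,500 and 1,500 + 1,500). Note that ensemble
steps are not comparable one-to-one with the 1,000 + 1,000 iterations of a
gradient-based sampler: one ensemble step moves ~50–100 walkers a short,
correlated distance, so step budgets here are set by the split-R̂
diagnostic, not by mirroring that protocol. These sizes are the package's
simulation-study design; more replicates and longer chains only sharpen
the same checks.

## Numerical details and edge cases

- Day-of-year scale: t = DOY/365 uniformly; leap-day records keep DOY 366.
  The May–September filter window is DOY [121, 273] (non-leap convention,
  configurable); whether the original analysis used calendar months or a
  DOY band is unrecorded, and the difference is at most two leap days.
- The late-season outlier rule defaults to DOY > 220 with shed < 0.5; the
  exact historical threshold is unrecorded, so both numbers are exposed as
  configuration.
- Binning tie-break: half-away-from-zero, so f·N = 0.5 maps to 1, not 0;
  `rounding="half-even"` switches to banker's rounding.
- Filtering rules 1–3 are per-record predicates and commute; rule 4
  (dropping years without unambiguous records) runs on their survivors by
  construction. Filtering is idempotent.
- Constant covariates (single-site captive data) cannot be z-scored from
  the sample; pass explicit `ZTransform` anchors (the captive model ignores
  the covariates regardless).
- `dataset_loglik` raises, naming the record index, if any contribution is
  non-finite; the vectorized sampler path maps non-finite log-posteriors to
  −inf, which the ensemble rejects.

## Known limitations

- p and q are weakly identified (above); their posteriors lean on the
  Beta(2, 2) prior at n ≈ 500.
- The ensemble sampler provides no divergence diagnostics; convergence
  monitoring rests on split-R̂ across independent ensembles plus the
  recovery calibration.
- Effect detection via "89% CI excludes zero" is a reporting convention,
  not a calibrated test; its false-positive rate under a null truth is
  checked empirically in the recovery suite (~11% nominal).
- Age, temperature and photoperiod are deliberately outside the model;
  elevation and latitude act as their proxies.
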