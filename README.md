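# moltcurve

Bayesian estimation of molt phenology — the timing and speed of winter-coat
shedding — from opportunistic wildlife photographs, built around the
mountain goat (*Oreamnos americanus*) as the model system. The package is
aimed at quantitative ecologists who have photograph records already scored
for the fraction of coat shed and want defensible, uncertainty-aware
estimates of how shedding date and rate depend on sex, offspring presence,
elevation, latitude and year — including from the large share of
photographs where the animal's sex or kid status cannot be determined.

## The model

The expected fraction of coat shed at year-fraction *t* = DOY/365 is
logistic,

```
f(t) = exp(α(t − τ)) / (1 + exp(α(t − τ)))
```

with shedding date τ (the 50%-shed point) and rate α (peak shedding speed
α/4 at *t* = τ) both linear in animal state, z-scored elevation and
latitude, a smooth year trend, and t-distributed year random effects:

```
τ = τ0 + τM·xM + τK·xK + τE·zE + τL·zL + τY·y + τ[y]
α = α0 + αM·xM + αK·xK + αE·zE + αL·zL + αY·y + α[y]
```

Scored shed fractions are coarsened into N = 25 bins and the count
n = round(f·N) is beta-binomial with overdispersion φ (variance inflation
1 + (N−1)φ/(1+φ) over the binomial). Photographs with ambiguous state
(codes FX, XN, XX) contribute through mixtures of the three unambiguous
components weighted by the population female fraction p and kid fraction q,
e.g. Pr(n | XX) = p(1−q)·P(n|FN) + pq·P(n|FY) + (1−p)·P(n|MN). A captive
variant for repeated measures of known animals replaces the environment and
year terms with a per-animal random effect on shedding date.

Fitting is MCMC (ensemble sampler with differential-evolution moves on an
unconstrained, non-centred parameterization); summaries are posterior
medians with equal-tailed 89% credible intervals. `docs/methods.md` has the
full account, including the priors and what the synthetic-data generator
does and does not emulate.

## Worked example

Every capability has a short narrative script under `examples/`. Generating
a synthetic archive with known truth and fitting the captive model
(`examples/fit_captive_model.py`, ~15 s):

```
tauM: -26.1 days [-37.6, -10.4] (truth -29.2)
tauK: +17.5 days [+6.6, +27.0] (truth +21.2)
```

τM is the male shift in 50%-shed date — males shed almost four weeks
earlier than females without kid, and the 89% interval excluding zero
flags the effect as detected; τK is the delay from a kid at heel. Both
intervals cover the values the data were generated from.

`examples/simulate_archive.py` shows the community scenario the generator
emulates — 562 records over 14 seasons with realistic state ambiguity:

```
562 records, 11 distinct years
state composition (FN/FY/MN unambiguous; FX/XN/XX ambiguous):
  FN:  117  (20.8%)
  FY:  114  (20.3%)
  MN:  140  (24.9%)
  FX:   56  (10.0%)
  XN:    1  (0.2%)
  XX:  134  (23.8%)
ambiguous records: 191 (34.0%) — these enter the likelihood through the p/q mixtures
```

The other scripts cover the filtering protocol, the full community fit with
a Table-style parameter summary, posterior-predictive shedding curves and
the annual trend, and a small parameter-recovery study.

A thin CLI wraps the same functions for shell use:

```
moltcurve simulate --n 562 --seed 1 --out archive.csv
moltcurve fit --input archive.csv --variant community --seed 1 --out posterior.nc
moltcurve predict --posterior posterior.nc --out curves.csv
```

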