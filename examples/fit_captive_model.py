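"""Fit the captive (repeated-measures) molt model.

Fourteen known animals photographed repeatedly across one season at one
site: no environment or year terms, but a t-distributed per-animal random
effect on shedding date absorbs the repeated measures.  All states are
known, so there is no mixture.
"""

from moltcurve import (
    CaptiveSimTruth, FitConfig, build_observations, fit_captive,
    simulate_captive_dataset, summarize,
)
from moltcurve.data_model import ZTransform

truth = CaptiveSimTruth(seed=4)
records = simulate_captive_dataset(truth)
obs, meta = build_observations(
    records, n_bins=25,
    elev_transform=ZTransform(650.0, 1.0), lat_transform=ZTransform(60.7, 1.0),
)

config = FitConfig(n_chains=2, n_warmup=600, n_samples=600, seed=0,
                   model_variant="captive")
idata = fit_captive(obs, config=config, meta=meta)

for s in summarize(idata):
    if s.days_scale is not None:
        print(f"{s.name}: {s.days_scale[0]:+.1f} days "
              f"[{s.days_scale[1]:+.1f}, {s.days_scale[2]:+.1f}] "
              f"(truth {getattr(truth.params, s.name) * 365:+.1f})")
print("tauM < 0 means males shed earlier than females without kid;"
      " tauK > 0 means a kid at heel delays shedding")
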