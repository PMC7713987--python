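"""Generate a synthetic community photograph archive and inspect its makeup.

The generator draws each photograph's year (skewed toward recent seasons),
day of year, correlated latitude/elevation, true animal state from the
population fractions (p, q), a binned shed count from the logistic +
beta-binomial observation model, and finally masks sex/kid status for a
subset of records the way opportunistic photographs really arrive.
"""

from collections import Counter

from moltcurve import SimTruth, simulate_dataset, write_records_csv

truth = SimTruth(seed=1)
records = simulate_dataset(truth)
write_records_csv(records, "synthetic_archive.csv")

states = Counter(r.state.value for r in records)
n = len(records)
print(f"{n} records, {len({r.year for r in records})} distinct years")
print("state composition (FN/FY/MN unambiguous; FX/XN/XX ambiguous):")
for code in ("FN", "FY", "MN", "FX", "XN", "XX"):
    print(f"  {code}: {states.get(code, 0):4d}  ({100 * states.get(code, 0) / n:.1f}%)")
ambiguous = sum(v for k, v in states.items() if "X" in k)
print(f"ambiguous records: {ambiguous} ({100 * ambiguous / n:.1f}%)"
      " — these enter the likelihood through the p/q mixtures")
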