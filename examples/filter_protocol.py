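"""Apply the analysis filtering protocol to a raw photograph table.

Four rules run in order: adults only; May-September day-of-year window;
late-season records with unusually low shed removed (default: day of year
above 220 with under half the coat shed); and years with no unambiguous-
state photograph dropped entirely, because their year random effects would
be unanchored.
"""

from moltcurve import SimTruth, filter_dataset, simulate_dataset
from moltcurve.data_model import PhotoRecord, AnimalState

records = simulate_dataset(SimTruth(seed=2))
# splice in records each rule should catch
records += [
    PhotoRecord("juvenile", 2017, 180, 49.0, 2000.0, AnimalState.FN, 0.5, is_adult=False),
    PhotoRecord("winter", 2017, 30, 49.0, 2000.0, AnimalState.FN, 0.0),
    PhotoRecord("late_low", 2017, 240, 49.0, 2000.0, AnimalState.FN, 0.1),
    PhotoRecord("lone_year", 1950, 180, 49.0, 2000.0, AnimalState.XX, 0.5),
]

kept, report = filter_dataset(records)
print(report.to_json())
print(f"\nkept {report.n_kept}/{report.n_input}; "
      f"{report.n_kept_unambiguous} with known animal state")
print("dropped years (no unambiguous photograph):", report.years_dropped)
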