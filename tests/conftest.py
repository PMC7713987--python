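import warnings

import numpy as np
import pytest

from moltcurve import AnimalState, PhotoRecord

warnings.filterwarnings("ignore", message=".*ArviZ.*")


def make_record(
    record_id="r0",
    year=2015,
    doy=180,
    latitude=49.0,
    elevation=2000.0,
    state=AnimalState.FN,
    shed_fraction=0.5,
    is_adult=True,
    animal_id=None,
):
    return PhotoRecord(
        record_id=record_id, year=year, doy=doy, latitude=latitude,
        elevation=elevation, state=state, shed_fraction=shed_fraction,
        is_adult=is_adult, animal_id=animal_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_record_set():
    """A handful of records over three years, mixing states."""
    rows = []
    rng = np.random.default_rng(7)
    for i in range(60):
        year = [2014, 2015, 2016][i % 3]
        state = list(AnimalState)[i % 6]
        rows.append(
            make_record(
                record_id=f"r{i}", year=year, doy=int(rng.integers(140, 260)),
                latitude=float(rng.uniform(40, 60)),
                elevation=float(rng.uniform(100, 3500)),
                state=state, shed_fraction=float(rng.uniform(0, 1)),
            )
        )
    return rows
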