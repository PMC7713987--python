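"""Photograph records, animal-state codes, covariate transforms and filtering.

The raw unit of observation is a photograph of a mountain goat scored for the
fraction of its winter coat already shed (a value in [0, 1]).  Each record
carries the calendar year, day of year (DOY), latitude, elevation, and a
six-level animal-state code combining sex and kid presence:

==== =========================================
FN   female, no kid
FY   female with kid
MN   male (kids never accompany males in-model)
FX   female, kid presence unknown
XN   sex unknown, no kid present
XX   sex and kid presence unknown
==== =========================================

FN, FY and MN are *unambiguous*; FX, XN and XX are *ambiguous* and enter the
likelihood through a mixture over the unambiguous states.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnimalState",
    "PhotoRecord",
    "BinnedObservation",
    "ZTransform",
    "FilterReport",
    "bin_shed_fraction",
    "z_transform_fit",
    "filter_dataset",
    "doy_to_yearfrac",
    "read_records_csv",
    "write_records_csv",
    "records_to_frame",
]

#: days per year used to map DOY onto the model's year-fraction timescale;
#: leap days keep DOY 366 but share the same divisor.
DAYS_PER_YEAR = 365.0

#: May 1 .. September 30 in the non-leap DOY convention.
MAY_SEP_WINDOW = (121, 273)


class AnimalState(str, enum.Enum):
    """Six-level sex / kid-presence code."""

    FN = "FN"
    FY = "FY"
    MN = "MN"
    FX = "FX"
    XN = "XN"
    XX = "XX"

    @property
    def is_ambiguous(self) -> bool:
        return self in _AMBIGUOUS

    @property
    def is_unambiguous(self) -> bool:
        return self in _UNAMBIGUOUS


_UNAMBIGUOUS = frozenset({AnimalState.FN, AnimalState.FY, AnimalState.MN})
_AMBIGUOUS = frozenset({AnimalState.FX, AnimalState.XN, AnimalState.XX})

UNAMBIGUOUS_STATES = (AnimalState.FN, AnimalState.FY, AnimalState.MN)


@dataclass(frozen=True)
class PhotoRecord:
    """One scored photograph.

    ``shed_fraction`` is the digitized estimate of the fraction of winter coat
    shed; ``animal_id`` is present only for captive (repeated-measures)
    records.
    """

    record_id: str
    year: int
    doy: int
    latitude: float
    elevation: float
    state: AnimalState
    shed_fraction: float
    is_adult: bool = True
    animal_id: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.shed_fraction <= 1.0):
            raise ValueError(f"shed_fraction {self.shed_fraction!r} outside [0, 1]")
        if not (1 <= self.doy <= 366):
            raise ValueError(f"doy {self.doy!r} outside 1..366")
        if not (30.0 <= self.latitude <= 70.0):
            raise ValueError(f"latitude {self.latitude!r} outside [30, 70]")
        if self.elevation < 0:
            raise ValueError(f"elevation {self.elevation!r} negative")


@dataclass(frozen=True)
class BinnedObservation:
    """A photograph after binning, ready for the likelihood.

    ``n_shed`` of ``n_total`` shedding bins are shed; covariates are on the
    z-scale; ``year_index`` indexes the year random-effect vector.
    """

    n_shed: int
    n_total: int
    z_elevation: float
    z_latitude: float
    year_centered: float
    year_index: int
    state: AnimalState
    t: float  # year fraction
    animal_index: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_shed <= self.n_total):
            raise ValueError("n_shed outside 0..n_total")
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")


@dataclass(frozen=True)
class ZTransform:
    """Standardization x -> (x - mean) / sd fitted on the analysis dataset."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be positive")

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def invert(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def z_transform_fit(values: Iterable[float]) -> ZTransform:
    """Fit a z-transform (sample sd, n-1 denominator) to ``values``.

    Raises ``ValueError`` on fewer than two distinct values, where the scale
    is degenerate.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2 or np.ptp(arr) == 0:
        raise ValueError("need at least two distinct values to fit a z-transform")
    return ZTransform(mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def bin_shed_fraction(f: float, n_bins: int, *, rounding: str = "half-away") -> int:
    """Map a shed fraction onto an integer count of shed bins, n = round(f*N).

    Ties (f*N exactly .5 above an integer) round half-away-from-zero by
    default; pass ``rounding="half-even"`` for banker's rounding.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"shed fraction {f!r} outside [0, 1]")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = f * n_bins
    if rounding == "half-away":
        n = math.floor(x + 0.5)
    elif rounding == "half-even":
        n = int(round(x))
    else:
        raise ValueError(f"unknown rounding convention {rounding!r}")
    return min(n, n_bins)


def doy_to_yearfrac(doy: float) -> float:
    """Convert day of year to the year-fraction timescale t = doy / 365."""
    if not (1 <= doy <= 366):
        raise ValueError(f"doy {doy!r} outside 1..366")
    return doy / DAYS_PER_YEAR


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`filter_dataset`."""

    n_input: int = 0
    removed_not_adult: int = 0
    removed_outside_window: int = 0
    removed_late_low_shed: int = 0
    removed_year_no_unambiguous: int = 0
    n_kept: int = 0
    n_kept_unambiguous: int = 0
    years_kept: list[int] = field(default_factory=list)
    years_dropped: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def filter_dataset(
    records: Sequence[PhotoRecord],
    *,
    late_doy_cutoff: int = 220,
    late_low_shed_max: float = 0.5,
    doy_window: tuple[int, int] = MAY_SEP_WINDOW,
) -> tuple[list[PhotoRecord], FilterReport]:
    """Apply the analysis filtering protocol and log per-rule counts.

    Rules, in order: (1) adults only; (2) DOY within the May-September
    window; (3) drop late-season records with unusually low shed
    (doy > ``late_doy_cutoff`` and shed_fraction < ``late_low_shed_max``);
    (4) drop every record from years containing no unambiguous-state record,
    since year random effects cannot be anchored there.

    Rules 1-3 are pure per-record predicates (order-invariant among
    themselves); rule 4 operates on the survivors of 1-3.
    """
    report = FilterReport(n_input=len(records))

    kept = []
    for r in records:
        if not r.is_adult:
            report.removed_not_adult += 1
        elif not (doy_window[0] <= r.doy <= doy_window[1]):
            report.removed_outside_window += 1
        elif r.doy > late_doy_cutoff and r.shed_fraction < late_low_shed_max:
            report.removed_late_low_shed += 1
        else:
            kept.append(r)

    anchored_years = {r.year for r in kept if r.state.is_unambiguous}
    final = [r for r in kept if r.year in anchored_years]
    report.removed_year_no_unambiguous = len(kept) - len(final)
    report.n_kept = len(final)
    report.n_kept_unambiguous = sum(r.state.is_unambiguous for r in final)
    report.years_kept = sorted(anchored_years)
    report.years_dropped = sorted({r.year for r in kept} - anchored_years)
    return final, report


_CSV_COLUMNS = [
    "record_id",
    "year",
    "doy",
    "latitude",
    "elevation_m",
    "state",
    "shed_fraction",
    "is_adult",
    "animal_id",
]


def records_to_frame(records: Sequence[PhotoRecord]) -> pd.DataFrame:
    rows = [
        {
            "record_id": r.record_id,
            "year": r.year,
            "doy": r.doy,
            "latitude": r.latitude,
            "elevation_m": r.elevation,
            "state": r.state.value,
            "shed_fraction": r.shed_fraction,
            "is_adult": r.is_adult,
            "animal_id": r.animal_id,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[PhotoRecord]:
    records = []
    for row in df.itertuples(index=False):
        animal_id = getattr(row, "animal_id", None)
        if animal_id is not None and (pd.isna(animal_id) or animal_id == ""):
            animal_id = None
        is_adult = getattr(row, "is_adult", True)
        if pd.isna(is_adult):
            is_adult = True
        records.append(
            PhotoRecord(
                record_id=str(row.record_id),
                year=int(row.year),
                doy=int(row.doy),
                latitude=float(row.latitude),
                elevation=float(row.elevation_m),
                state=AnimalState(str(row.state)),
                shed_fraction=float(row.shed_fraction),
                is_adult=bool(is_adult),
                animal_id=None if animal_id is None else str(animal_id),
            )
        )
    return records


def read_records_csv(path) -> list[PhotoRecord]:
    """Read a photograph table (see module docstring for the schema)."""
    return frame_to_records(pd.read_csv(path))


def write_records_csv(records: Sequence[PhotoRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def build_observations(
    records: Sequence[PhotoRecord],
    *,
    n_bins: int = 25,
    year_origin: float = 2000.0,
    elev_transform: ZTransform | None = None,
    lat_transform: ZTransform | None = None,
) -> tuple[list[BinnedObservation], dict]:
    """Bin shed fractions, z-transform covariates and index years/animals.

    Returns the observation list plus a metadata dict with the fitted
    transforms, the sorted year list and (if any) the animal-id list, which
    the inference and reporting layers need to interpret indices.
    """
    if not records:
        raise ValueError("no records to build observations from")

    def _fit_or_center(values):
        # single-site data have constant covariates: center at the value
        # with unit scale (the captive model ignores them anyway)
        try:
            return z_transform_fit(values)
        except ValueError:
            return ZTransform(mean=float(values[0]), sd=1.0)

    if elev_transform is None:
        elev_transform = _fit_or_center([r.elevation for r in records])
    if lat_transform is None:
        lat_transform = _fit_or_center([r.latitude for r in records])
    years = sorted({r.year for r in records})
    year_index = {y: i for i, y in enumerate(years)}
    animal_ids = sorted({r.animal_id for r in records if r.animal_id is not None})
    animal_index = {a: i for i, a in enumerate(animal_ids)}

    obs = [
        BinnedObservation(
            n_shed=bin_shed_fraction(r.shed_fraction, n_bins),
            n_total=n_bins,
            z_elevation=float(elev_transform.apply(r.elevation)),
            z_latitude=float(lat_transform.apply(r.latitude)),
            year_centered=r.year - year_origin,
            year_index=year_index[r.year],
            state=r.state,
            t=doy_to_yearfrac(r.doy),
            animal_index=animal_index.get(r.animal_id) if r.animal_id else None,
        )
        for r in records
    ]
    meta = {
        "elev_transform": elev_transform,
        "lat_transform": lat_transform,
        "years": years,
        "animal_ids": animal_ids,
        "year_origin": year_origin,
        "n_bins": n_bins,
    }
    return obs, meta
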