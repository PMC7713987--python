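"""Presentation surfaces: predicted curves, annual trend, parameter tables.

Credible bands on the curves are pointwise quantiles on the shed-fraction
scale (each posterior draw is pushed through the logistic curve, then the
5.5%/50%/94.5% quantiles are taken per grid point).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AnimalState
from .inference import DAY_SCALE_PARAMS, PosteriorSummary
from .likelihood import logistic_fraction

__all__ = [
    "PredictionGrid",
    "predict_curves",
    "predict_annual_trend",
    "render_parameter_table",
    "parse_parameter_table",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class PredictionGrid:
    """Predicted shedding curve for one state with an 89% band."""

    state: AnimalState
    doy: np.ndarray
    median: np.ndarray
    lower89: np.ndarray
    upper89: np.ndarray
    z_elevation: float = 0.0
    z_latitude: float = 0.0
    year: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.state.value,
                "doy": self.doy,
                "median": self.median,
                "lower89": self.lower89,
                "upper89": self.upper89,
            }
        )


def _flat(idata, name):
    return idata.posterior[name].values.reshape(-1)


def _state_draws(idata, state: AnimalState, z_e, z_l, year_centered):
    """Per-draw (tau, alpha) for one unambiguous state, random effects at 0."""
    if state not in (AnimalState.FN, AnimalState.FY, AnimalState.MN):
        raise ValueError(f"cannot predict for ambiguous state {state.value}")
    variant = idata.posterior.attrs.get("model_variant", "community")
    x_m = 1.0 if state is AnimalState.MN else 0.0
    x_k = 1.0 if state is AnimalState.FY else 0.0
    tau = _flat(idata, "tau0") + x_m * _flat(idata, "tauM") + x_k * _flat(idata, "tauK")
    alpha = _flat(idata, "alpha0") + x_m * _flat(idata, "alphaM") + x_k * _flat(idata, "alphaK")
    if variant == "community":
        tau = tau + _flat(idata, "tauE") * z_e + _flat(idata, "tauL") * z_l \
              + _flat(idata, "tauY") * year_centered
        alpha = alpha + _flat(idata, "alphaE") * z_e + _flat(idata, "alphaL") * z_l \
                + _flat(idata, "alphaY") * year_centered
    return tau, alpha


def predict_curves(
    idata,
    states: list[AnimalState] | None = None,
    z_elevation: float = 0.0,
    z_latitude: float = 0.0,
    year: int | None = None,
    doy_grid: np.ndarray | None = None,
) -> list[PredictionGrid]:
    """Median shedding curves with 89% bands, random effects set to zero.

    Predictions default to the covariate origin (z = 0) and, for the
    community model, the year passed (its smooth trend only; the year random
    effect is zeroed).
    """
    states = states or [AnimalState.FN, AnimalState.FY, AnimalState.MN]
    if doy_grid is None:
        doy_grid = np.arange(120, 281)
    year_origin = float(idata.posterior.attrs.get("year_origin", 2000.0))
    yc = 0.0 if year is None else year - year_origin
    t = np.asarray(doy_grid, float) / DAYS_PER_YEAR
    out = []
    for state in states:
        tau, alpha = _state_draws(idata, state, z_elevation, z_latitude, yc)
        f = logistic_fraction(t[None, :], tau[:, None], alpha[:, None])  # (draws, grid)
        lo, med, hi = np.quantile(f, [0.055, 0.5, 0.945], axis=0)
        out.append(
            PredictionGrid(
                state=state, doy=np.asarray(doy_grid, float),
                median=med, lower89=lo, upper89=hi,
                z_elevation=z_elevation, z_latitude=z_latitude, year=year,
            )
        )
    return out


def predict_annual_trend(idata, years: list[int] | None = None) -> pd.DataFrame:
    """Per-year 50%-shed date for state FN (year effect included) plus trend.

    Returns a frame with, per year, the median and 89% CI of the full
    per-year date (tau0 + tauY * y + tau[y]) and of the smooth trend alone
    (tau0 + tauY * y), on the day scale.  Years outside the fitted range are
    flagged as extrapolation (their random effect is zero).
    """
    post = idata.posterior
    if "tau_re" not in post:
        raise ValueError("annual trend requires a community posterior with year effects")
    fitted_years = list(post.attrs.get("years", []))
    if years is None:
        years = fitted_years
    year_origin = float(post.attrs.get("year_origin", 2000.0))
    tau0 = _flat(idata, "tau0")
    tauY = _flat(idata, "tauY")
    n_chain, n_draw, n_year = post["tau_re"].shape
    tau_re = post["tau_re"].values.reshape(n_chain * n_draw, n_year)
    rows = []
    for y in years:
        yc = y - year_origin
        trend = tau0 + tauY * yc
        extrapolated = y not in fitted_years
        if extrapolated:
            full = trend
        else:
            full = trend + tau_re[:, fitted_years.index(y)]
        t_lo, t_med, t_hi = np.quantile(trend, [0.055, 0.5, 0.945])
        f_lo, f_med, f_hi = np.quantile(full, [0.055, 0.5, 0.945])
        rows.append(
            {
                "year": y,
                "date_doy": f_med * DAYS_PER_YEAR,
                "date_lower89": f_lo * DAYS_PER_YEAR,
                "date_upper89": f_hi * DAYS_PER_YEAR,
                "trend_doy": t_med * DAYS_PER_YEAR,
                "trend_lower89": t_lo * DAYS_PER_YEAR,
                "trend_upper89": t_hi * DAYS_PER_YEAR,
                "extrapolated": extrapolated,
            }
        )
    return pd.DataFrame(rows)


def render_parameter_table(
    summaries: list[PosteriorSummary],
    variant_label: str = "fit",
    digits: int = 3,
    fmt: str = "csv",
) -> str:
    """Render summaries as a CSV (or markdown) table.

    Day-scale rows are appended for the tau offsets; the ``effect`` column
    applies the CI-excludes-zero rule used for bolding in print.
    """
    if not summaries:
        raise ValueError("no summaries to render")
    rows = []
    for s in summaries:
        rows.append(
            {
                "variant": variant_label,
                "parameter": s.name,
                "prior": s.prior_label or "",
                "median": round(s.median, digits),
                "lower89": round(s.lower89, digits),
                "upper89": round(s.upper89, digits),
                "effect_detected": "" if s.effect_detected is None else s.effect_detected,
                "scale": "year",
            }
        )
        if s.days_scale is not None:
            med, lo, hi = s.days_scale
            rows.append(
                {
                    "variant": variant_label,
                    "parameter": s.name + "_days",
                    "prior": s.prior_label or "",
                    "median": round(med, max(digits - 1, 2)),
                    "lower89": round(lo, max(digits - 1, 2)),
                    "upper89": round(hi, max(digits - 1, 2)),
                    "effect_detected": "" if s.effect_detected is None else s.effect_detected,
                    "scale": "days",
                }
            )
    df = pd.DataFrame(rows)
    if fmt == "csv":
        return df.to_csv(index=False)
    if fmt == "markdown":
        return df.to_markdown(index=False)
    raise ValueError(f"unknown table format {fmt!r}")


def parse_parameter_table(text: str) -> pd.DataFrame:
    """Read back a CSV table produced by render_parameter_table."""
    return pd.read_csv(io.StringIO(text))
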