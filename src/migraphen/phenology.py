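"""Land-surface phenology from regional NDVI series: double-logistic seasonal
fit and amplitude-threshold green-up extraction.

The green-up date for a region-year is the first spring day on which the
fitted seasonal curve reaches the base level plus a fraction (default 50%) of
the annual NDVI amplitude. Only the double-logistic model class and the
amplitude-threshold output are implemented — the standard reduction used for
composited satellite greenness series.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .curves import ndvi_double_logistic


class SeasonalityError(ValueError):
    """Fitted annual amplitude below the floor: no usable seasonal signal."""


@dataclass
class SeasonalCurveFit:
    vmin: float
    vmax: float
    t0: float      # spring midpoint (day of year)
    k: float       # spring rate (1/day)
    ta: float      # autumn midpoint
    ka: float      # autumn rate
    resid_sd: float
    n: int

    @property
    def amplitude(self) -> float:
        return self.vmax - self.vmin

    def predict(self, t):
        return ndvi_double_logistic(t, self.vmin, self.vmax, self.t0, self.k,
                                    self.ta, self.ka)


@dataclass
class PhenologyEstimate:
    region: str
    year: int
    green_up_doy: float
    vmin: float
    vmax: float
    amplitude: float
    resid_sd: float


def _year_doy(series: pd.DataFrame, year: int) -> Tuple[np.ndarray, np.ndarray]:
    dts = pd.DatetimeIndex(series["date"])
    sel = dts.year == year
    t = dts.dayofyear.to_numpy(dtype=float)[sel]
    v = series["ndvi"].to_numpy(dtype=float)[sel]
    order = np.argsort(t)
    return t[order], v[order]


def fit_seasonal_curve(series: pd.DataFrame, year: int,
                       amplitude_floor: float = 0.05) -> SeasonalCurveFit:
    """Least-squares double-logistic fit to one region-year of composites.

    Needs at least 12 composites in the year. Raises SeasonalityError when
    the fitted amplitude falls below ``amplitude_floor``.
    """
    t, v = _year_doy(series, year)
    if len(t) < 12:
        raise ValueError(f"need >=12 composites in {year}, got {len(t)}")
    vmin0, vmax0 = float(np.min(v)), float(np.max(v))
    if vmax0 - vmin0 < amplitude_floor / 2.0:
        raise SeasonalityError(
            f"observed range {vmax0 - vmin0:.3f} shows no seasonal signal")
    half = 0.5 * (vmin0 + vmax0)
    above = v >= half
    t0_0 = float(t[np.argmax(above)]) if np.any(above) else 100.0
    ta_0 = float(t[len(t) - 1 - np.argmax(above[::-1])]) if np.any(above) else 280.0

    def resid(p):
        return ndvi_double_logistic(t, *p) - v

    lb = [-1.0, -1.0, 1.0, 1e-3, 30.0, 1e-3]
    ub = [1.0, 1.5, 330.0, 2.0, 400.0, 2.0]
    best = None
    for k0 in (0.05, 0.15):
        p0 = np.clip([vmin0, vmax0, t0_0, k0, max(ta_0, t0_0 + 40.0), k0], lb, ub)
        sol = least_squares(resid, p0, bounds=(lb, ub), max_nfev=3000)
        if best is None or sol.cost < best.cost:
            best = sol
    vmin, vmax, t0, k, ta, ka = best.x
    if vmax - vmin < amplitude_floor:
        raise SeasonalityError(
            f"fitted amplitude {vmax - vmin:.3f} below floor {amplitude_floor}")
    return SeasonalCurveFit(vmin=float(vmin), vmax=float(vmax), t0=float(t0),
                            k=float(k), ta=float(ta), ka=float(ka),
                            resid_sd=float(np.sqrt(2.0 * best.cost / len(t))),
                            n=len(t))


def green_up_date(curve: SeasonalCurveFit, threshold: float = 0.5,
                  window: Tuple[float, float] = (1.0, 180.0)) -> float:
    """Smallest day in the spring window where the fitted curve reaches
    ``vmin + threshold * amplitude``. Default threshold 0.5 (the 50%-amplitude
    green-up definition); the window excludes autumn crossings."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    target = curve.vmin + threshold * curve.amplitude
    grid = np.arange(window[0], window[1] + 0.05, 0.05)
    vals = curve.predict(grid)
    above = vals >= target
    if not np.any(above):
        raise SeasonalityError(
            f"threshold {threshold} never reached in window {window}")
    i = int(np.argmax(above))
    if i == 0:
        return float(grid[0])
    return float(brentq(lambda tt: curve.predict(tt) - target, grid[i - 1], grid[i]))


def estimate_phenology(ndvi: pd.DataFrame, threshold: float = 0.5,
                       window: Tuple[float, float] = (1.0, 180.0)) -> pd.DataFrame:
    """Green-up dates for every region-year in an NDVI table
    (columns region, date, ndvi)."""
    rows = []
    for region, g in ndvi.groupby("region"):
        for year in sorted(pd.DatetimeIndex(g["date"]).year.unique()):
            curve = fit_seasonal_curve(g, int(year))
            doy = green_up_date(curve, threshold=threshold, window=window)
            rows.append(dict(region=region, year=int(year), green_up_doy=doy,
                             vmin=curve.vmin, vmax=curve.vmax,
                             amplitude=curve.amplitude, resid_sd=curve.resid_sd))
    return pd.DataFrame(rows)


def phenology_trend(estimates: pd.DataFrame):
    """OLS year trend of green-up dates for one region (columns year,
    green_up_doy): returns (model_table, headline slope dict)."""
    from .trends import fit_trend_ols, model_table

    df = estimates.sort_values("year")
    if len(df) < 3:
        raise ValueError("need at least 3 years for a phenology trend")
    models = fit_trend_ols(df["green_up_doy"], df["year"])
    tab = model_table(models)
    year_model = next(m for m in models if m.label.endswith("year"))
    null_model = next(m for m in models if m.label.endswith("null"))
    headline = dict(slope=float(year_model.params["year"]),
                    slope_se=float(year_model.bse["year"]),
                    year_beats_null=bool(year_model.aicc < null_model.aicc))
    return tab, headline
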