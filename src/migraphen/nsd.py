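"""Net squared displacement (NSD), the double-logistic migration model, and
migration-date determination against range polygons.

NSD is the squared great-circle distance (km^2) between a bird's first fix
inside the non-breeding range in a given annual cycle and every subsequent
fix. For a round-trip migrant it follows a double-logistic profile

    NSD(t) = delta / (1 + exp((theta_s - t)/phi_s))
           - delta / (1 + exp((theta_a - t)/phi_a))

rising at the spring inflection theta_s, levelling off at the plateau delta
(the squared migration distance), and falling at the autumn inflection
theta_a. The model is fitted by least squares from a deterministic grid of
starting values and compared against a constant-NSD (resident) alternative by
AICc. The four migration dates themselves are read off the track with
explicit persistence-based boundary-crossing rules against the non-breeding
and summer range polygons.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .curves import nsd_double_logistic
from .geo import haversine_km
from .ranges import RangePolygon, point_in_range
from .trends import aicc

EVENTS = ("spring_departure", "spring_arrival", "autumn_departure", "autumn_arrival")


class NoWinterAnchorError(ValueError):
    """Track never enters the non-breeding range: no NSD reference exists."""


class PlateauError(ValueError):
    """Fitted curve never reaches the requested occupancy fraction."""


def continuous_doy(timestamps: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Continuous day-of-year: 1.0 at Jan 1 00:00, 1.5 at Jan 1 12:00, ..."""
    ts = pd.DatetimeIndex(timestamps)
    frac = (ts.hour + ts.minute / 60.0 + ts.second / 3600.0) / 24.0
    return ts.dayofyear.to_numpy(dtype=float) + frac.to_numpy(dtype=float)


@dataclass
class NSDSeries:
    bird_id: str
    year: int
    t: np.ndarray          # continuous day of year, strictly increasing
    nsd: np.ndarray        # km^2
    ref_lon: float
    ref_lat: float


@dataclass
class DoubleLogisticFit:
    delta: float
    theta_s: float
    phi_s: float
    theta_a: float
    phi_a: float
    resid_sd: float
    converged: bool
    aicc_dl: float
    aicc_const: float
    n: int
    min_migration_nsd_km2: float = 1.0e4

    @property
    def classification(self) -> str:
        """"migrant" only when the double-logistic beats the constant model by
        AICc *and* the fitted plateau corresponds to a real displacement
        (default floor (100 km)^2); otherwise "resident"."""
        if not self.converged:
            return "resident"
        if self.aicc_const <= self.aicc_dl or self.delta < self.min_migration_nsd_km2:
            return "resident"
        return "migrant"

    def predict(self, t):
        return nsd_double_logistic(t, self.delta, self.theta_s, self.phi_s,
                                   self.theta_a, self.phi_a)


def compute_nsd(track: pd.DataFrame, non_breeding: RangePolygon,
                year: Optional[int] = None) -> NSDSeries:
    """NSD series for one bird(-year): squared great-circle displacement from
    the first fix inside the non-breeding range."""
    df = track
    if year is not None:
        df = df[pd.DatetimeIndex(df["timestamp"]).year == year]
    df = df.sort_values("timestamp")
    if len(df) == 0:
        raise NoWinterAnchorError("empty track")
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    inside = point_in_range(lon, lat, non_breeding)
    if not np.any(inside):
        raise NoWinterAnchorError(
            f"no fix of {df['bird_id'].iloc[0]} ever inside the non-breeding range")
    i0 = int(np.argmax(inside))
    d = haversine_km(lon[i0], lat[i0], lon, lat)
    yr = int(pd.DatetimeIndex(df["timestamp"]).year[0]) if year is None else int(year)
    return NSDSeries(bird_id=str(df["bird_id"].iloc[0]), year=yr,
                     t=continuous_doy(df["timestamp"]), nsd=d * d,
                     ref_lon=float(lon[i0]), ref_lat=float(lat[i0]))


def _daily_median(t: np.ndarray, y: np.ndarray):
    day = np.floor(t).astype(int)
    df = pd.DataFrame({"day": day, "y": y}).groupby("day")["y"].median()
    return df.index.to_numpy(dtype=float) + 0.5, df.to_numpy()


def _gauss_llf(ssr: float, n: int) -> float:
    s2 = max(ssr / n, 1e-12)
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def fit_double_logistic(nsd: NSDSeries, daily_aggregate: bool = True,
                        min_migration_nsd_km2: float = 1.0e4) -> DoubleLogisticFit:
    """Least-squares double-logistic fit of an NSD series with a deterministic
    multi-start grid, plus the constant-NSD alternative; both AICc values are
    reported and drive the migrant/resident classification.

    Hourly series are aggregated to daily medians before fitting: the daily
    scale is where the migration signal lives, and it damps the heavy-tailed
    within-day wander noise.
    """
    t, y = (nsd.t, nsd.nsd)
    if daily_aggregate:
        t, y = _daily_median(t, y)
    n = len(t)
    if n < 20 or (t[-1] - t[0]) < 200.0:
        raise ValueError(f"need >=20 points spanning >=200 days, got n={n}, "
                         f"span={t[-1] - t[0]:.0f}")

    const = float(np.mean(y))
    ssr_const = float(np.sum((y - const) ** 2))
    aicc_const = aicc(_gauss_llf(ssr_const, n), 2, n)

    ymax = float(np.percentile(y, 98))
    half = ymax / 2.0
    above = y >= half
    if np.any(above) and ymax > 0:
        t_rise = float(t[np.argmax(above)])
        t_fall = float(t[len(t) - 1 - np.argmax(above[::-1])])
    else:
        t_rise, t_fall = 120.0, 270.0
    starts = []
    for th_s, th_a in ((t_rise, t_fall), (t_rise - 10, t_fall + 10), (120.0, 270.0)):
        for phi in (2.0, 8.0):
            gap = max(th_a - th_s, 5.0)
            starts.append((max(ymax, 1.0), th_s, phi, gap, phi))

    def resid(p):
        delta, th_s, phi_s, gap, phi_a = p
        return nsd_double_logistic(t, delta, th_s, phi_s, th_s + gap, phi_a) - y

    lb = [0.0, t[0] - 30.0, 0.2, 1.0, 0.2]
    ub = [max(4.0 * ymax, 1.0), t[-1] + 30.0, 80.0, 400.0, 80.0]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lb, ub)
        try:
            sol = least_squares(resid, p0, bounds=(lb, ub), max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return DoubleLogisticFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                                 converged=False, aicc_dl=np.inf,
                                 aicc_const=aicc_const, n=n,
                                 min_migration_nsd_km2=min_migration_nsd_km2)
    delta, th_s, phi_s, gap, phi_a = best.x
    ssr = float(2.0 * best.cost)
    aicc_dl = aicc(_gauss_llf(ssr, n), 6, n)
    return DoubleLogisticFit(delta=float(delta), theta_s=float(th_s),
                             phi_s=float(phi_s), theta_a=float(th_s + gap),
                             phi_a=float(phi_a),
                             resid_sd=float(np.sqrt(ssr / n)),
                             converged=bool(best.success), aicc_dl=aicc_dl,
                             aicc_const=aicc_const, n=n,
                             min_migration_nsd_km2=min_migration_nsd_km2)


def detect_plateau(fit: DoubleLogisticFit, occupancy_fraction: float = 0.95):
    """(plateau_start, plateau_end): earliest and latest day where the fitted
    NSD is at least ``occupancy_fraction * delta``. Fixes between the two
    bound the summer-range occupancy."""
    if fit.classification != "migrant":
        raise ValueError("plateau detection requires a migrant classification")
    target = occupancy_fraction * fit.delta
    grid = np.arange(fit.theta_s - 60.0, fit.theta_a + 60.0, 0.05)
    vals = fit.predict(grid)
    above = vals >= target
    if not np.any(above):
        raise PlateauError(
            f"fitted curve never reaches {occupancy_fraction:.2f} of the plateau")
    i0 = int(np.argmax(above))
    i1 = len(grid) - 1 - int(np.argmax(above[::-1]))
    f = lambda tt: fit.predict(tt) - target
    start = grid[i0] if i0 == 0 else brentq(f, grid[i0 - 1], grid[i0])
    end = grid[i1] if i1 == len(grid) - 1 else brentq(f, grid[i1], grid[i1 + 1])
    return float(start), float(end)


# ----------------------------------------------------------------------
# persistence-based migration-date rules

@dataclass
class MigrationDates:
    bird_id: str
    year: int
    spring_departure: Optional[float] = None
    spring_arrival: Optional[float] = None
    autumn_departure: Optional[float] = None
    autumn_arrival: Optional[float] = None
    age_class: str = ""
    sex: str = ""
    classification: str = "migrant"
    diagnostic: str = ""

    def as_dict(self):
        d = dict(bird_id=self.bird_id, year=self.year, age_class=self.age_class,
                 sex=self.sex, classification=self.classification)
        for ev in EVENTS:
            d[ev] = getattr(self, ev)
        return d


def _runs(mask: np.ndarray):
    """(start_idx, end_idx) pairs of maximal True runs, end inclusive."""
    if len(mask) == 0:
        return []
    diff = np.diff(mask.astype(int))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def determine_migration_dates(track: pd.DataFrame, non_breeding: RangePolygon,
                              summer: RangePolygon, persistence_days: float = 5.0,
                              year: Optional[int] = None) -> MigrationDates:
    """Read the four annual-cycle dates off one bird-year track with
    persistence rules:

    * spring departure — last fix inside the non-breeding range before the
      first excursion that stays out for at least ``persistence_days`` and is
      followed by summer-range arrival;
    * spring arrival — first summer-range fix opening at least
      ``persistence_days`` of continuous summer occupancy;
    * autumn departure / autumn arrival — the mirror-image rules.

    Occupancy is judged at the day level (a day is "in" a range when at least
    half of its fixes are inside) so that the occasional fix just outside a
    95% isopleth does not break a genuine residence period.
    """
    df = track
    if year is not None:
        df = df[pd.DatetimeIndex(df["timestamp"]).year == year]
    df = df.sort_values("timestamp")
    bird_id = str(df["bird_id"].iloc[0]) if len(df) else "?"
    yr = int(year) if year is not None else int(pd.DatetimeIndex(df["timestamp"]).year[0])
    out = MigrationDates(bird_id=bird_id, year=yr)
    if len(df) == 0:
        out.diagnostic = "empty track"
        return out

    t = continuous_doy(df["timestamp"])
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    in_nb = point_in_range(lon, lat, non_breeding)
    in_sm = point_in_range(lon, lat, summer)

    day = np.floor(t).astype(int)
    days = np.unique(day)
    fr_nb = pd.Series(in_nb).groupby(day).mean().reindex(days).to_numpy()
    fr_sm = pd.Series(in_sm).groupby(day).mean().reindex(days).to_numpy()
    day_nb = fr_nb >= 0.5
    day_sm = fr_sm >= 0.5

    def run_len(i0, i1):
        return days[i1] - days[i0] + 1

    sm_runs = [(i0, i1) for i0, i1 in _runs(day_sm) if run_len(i0, i1) >= persistence_days]
    if not sm_runs:
        out.diagnostic = "no persistent summer occupancy"
        return out
    arr_i0, arr_i1 = sm_runs[0]
    arrival_day = days[arr_i0]

    # qualifying spring excursion: out of non-breeding >= persistence, before arrival
    dep_time = None
    for i0, i1 in _runs(~day_nb):
        if days[i0] > arrival_day:
            break
        if run_len(i0, i1) >= persistence_days and days[i1] >= arrival_day - 1:
            sel = in_nb & (t < days[i0] + 1)
            if np.any(sel):
                dep_time = float(t[np.where(sel)[0][-1]])
            break
    if dep_time is None:
        out.diagnostic = "no qualifying non-breeding departure"
        return out
    out.spring_departure = dep_time
    sel = in_sm & (t >= arrival_day)
    out.spring_arrival = float(t[np.where(sel)[0][0]])

    # autumn: after the summer run ends
    adep_time = None
    aarr_time = None
    for i0, i1 in _runs(~day_sm):
        if days[i0] <= days[arr_i1]:
            continue
        if run_len(i0, i1) >= persistence_days:
            sel = in_sm & (t < days[i0] + 1)
            if np.any(sel):
                adep_time = float(t[np.where(sel)[0][-1]])
            break
    if adep_time is not None:
        for i0, i1 in _runs(day_nb):
            if days[i0] <= adep_time:
                continue
            if run_len(i0, i1) >= persistence_days:
                sel = in_nb & (t >= days[i0])
                aarr_time = float(t[np.where(sel)[0][0]])
                break
    out.autumn_departure = adep_time
    out.autumn_arrival = aarr_time
    if adep_time is None or aarr_time is None:
        out.diagnostic = "incomplete autumn cycle"
    # enforce the ordering invariant: drop any event violating it
    seq = [out.spring_departure, out.spring_arrival, out.autumn_departure, out.autumn_arrival]
    filled = [v for v in seq if v is not None]
    if filled != sorted(filled):
        out.diagnostic = (out.diagnostic + "; " if out.diagnostic else "") + "date ordering violated"
        out.autumn_departure = out.autumn_arrival = None
    return out


def summarize_dates(dates: pd.DataFrame) -> dict:
    """Per-event median dates plus the distribution of absolute differences of
    the same individual's date between successive years.

    ``dates`` is wide-form: one row per bird-year with the four event columns.
    """
    mig = dates[dates["classification"] == "migrant"]
    if len(mig) == 0:
        raise ValueError("no migrant bird-years to summarize")
    out = {"medians": {}, "successive_diffs": {}}
    for ev in EVENTS:
        vals = mig[ev].dropna()
        out["medians"][ev] = float(vals.median()) if len(vals) else np.nan
        diffs = []
        for _, g in mig.sort_values("year").groupby("bird_id"):
            g = g.dropna(subset=[ev])
            yrs = g["year"].to_numpy()
            vs = g[ev].to_numpy()
            for i in range(len(g) - 1):
                if yrs[i + 1] - yrs[i] == 1:
                    diffs.append(abs(vs[i + 1] - vs[i]))
        out["successive_diffs"][ev] = {
            "n": len(diffs),
            "min": float(np.min(diffs)) if diffs else np.nan,
            "max": float(np.max(diffs)) if diffs else np.nan,
            "mean": float(np.mean(diffs)) if diffs else np.nan,
        }
    return out
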