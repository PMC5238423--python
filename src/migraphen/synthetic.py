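"""Synthetic GPS tracks, NDVI series, and station weather with known truth.

The generator emulates the data structure of a multi-year satellite-telemetry
study of a short-distance migrant (wintering on the Gulf of Mexico coast,
breeding in the Northern Great Plains): hourly fixes with ~18 m positional
noise and fix dropout, a mix of year-round residents and round-trip migrants,
individual-specific spring departure dates with a between-individual variance
component (repeatability), a linear advancing year trend in spring timing,
seasonal double-logistic NDVI at 16-day composite spacing, and daily station
weather with a seasonal cycle.

Movement model
--------------
Each bird has a winter site (and, for migrants, a summer site) drawn around
the population centroids. The deterministic anchor path sits at the winter
site, moves along the great circle to the summer site between the true spring
departure and arrival, sits at the summer site, and returns between the true
autumn departure and arrival. Around the anchor, the bird performs a
mean-reverting (Ornstein-Uhlenbeck) wander in a local planar frame, with
stationary standard deviation ``wander_sd_km`` and relaxation time
``wander_tau_days``; GPS noise of ``fix_noise_sd_m`` is added on top, and
scheduled fixes are dropped i.i.d. with probability ``dropout_prob``.

Timing model
------------
True spring departure for bird *i* in year *y* is

    mean_spring_departure + year_trend * (y - y0) + b_i + e_iy

with ``b_i ~ N(0, sigma_b^2)`` and ``e_iy ~ N(0, within_sd^2)`` where
``sigma_b`` is chosen so that ``sigma_b^2 / (sigma_b^2 + within_sd^2)``
equals ``icc_target``. Arrival dates are departure plus a travel time
(great-circle distance / migration_speed) perturbed by individual and yearly
components; autumn departure has its own, mostly within-year, variance. The
default noise split reproduces the qualitative repeatability ordering seen in
telemetry studies: spring departure highly repeatable, spring arrival and
autumn arrival moderate, autumn departure near zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .curves import ndvi_double_logistic
from .geo import KM_PER_DEG, great_circle_interpolate, haversine_km


@dataclass
class NDVIRegionParams:
    """Double-logistic seasonal NDVI parameters for one region."""

    vmin: float = 0.25
    vmax: float = 0.65
    t0: float = 70.0        # spring midpoint, day of year, first simulated year
    k: float = 0.08         # spring rate (1/day)
    ta: float = 300.0       # autumn midpoint
    ka: float = 0.06        # autumn rate
    t0_trend: float = -1.61  # advance of the spring midpoint, days per year
    noise_sd: float = 0.02


@dataclass
class WeatherParams:
    annual_mean_c: float = 20.0
    seasonal_amp_c: float = 8.0
    daily_sd_c: float = 3.0
    p_wet: float = 0.3            # probability a day has any precipitation
    wet_mean_cm: float = 1.2      # mean precipitation on wet days
    n_stations: int = 5
    station_offset_sd_c: float = 1.0
    peak_doy: float = 199.0       # day of the warm-season temperature peak


def _default_ndvi_params() -> Dict[str, NDVIRegionParams]:
    return {
        "non_breeding": NDVIRegionParams(t0=70.0, ta=300.0),
        "breeding": NDVIRegionParams(t0=130.0, ta=280.0, vmin=0.2, vmax=0.7),
    }


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the synthetic population."""

    n_residents: int = 12
    n_migrants: int = 24
    years: Tuple[int, int] = (2002, 2011)

    fix_interval_hours: float = 1.0
    fix_noise_sd_m: float = 18.0
    dropout_prob: float = 0.2

    winter_centroid: Tuple[float, float] = (-91.5, 30.2)   # lon, lat
    summer_centroid: Tuple[float, float] = (-99.5, 47.5)

    mean_spring_departure: float = 121.0   # day of year, first simulated year
    mean_autumn_departure: float = 241.0
    year_trend: float = -6.44              # days/yr applied to spring departure

    icc_target: float = 0.76
    within_sd: float = 5.0                 # within-individual SD of departure, days

    migration_speed: float = 90.0          # km/day along the great circle
    spring_travel_within_sd: float = 12.0  # days
    spring_travel_between_sd: float = 1.0
    autumn_travel_within_sd: float = 3.0
    autumn_travel_between_sd: float = 9.0
    autumn_between_sd: float = 2.0         # autumn departure variance split
    autumn_within_sd: float = 12.0

    wander_sd_km: float = 8.0
    wander_tau_days: float = 1.0
    site_sd_resident_km: float = 15.0
    site_sd_migrant_km: float = 10.0
    site_sd_summer_km: float = 30.0

    migrant_years_tracked: int = 3
    resident_years_tracked: int = 2
    prop_male: float = 0.8
    prop_immature_capture: float = 0.6

    ndvi_params: Dict[str, NDVIRegionParams] = field(default_factory=_default_ndvi_params)
    weather_params: WeatherParams = field(default_factory=WeatherParams)

    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def sigma_between(self) -> float:
        """Between-individual SD of spring departure implied by icc_target."""
        return self.within_sd * np.sqrt(self.icc_target / (1.0 - self.icc_target))

    def validate(self) -> None:
        if not (0.0 < self.icc_target < 1.0):
            raise ValueError(f"icc_target must be in (0, 1), got {self.icc_target}")
        if self.fix_interval_hours <= 0:
            raise ValueError("fix_interval_hours must be positive")
        if self.years[1] < self.years[0]:
            raise ValueError(f"empty year span {self.years}")
        for region, p in self.ndvi_params.items():
            if p.vmin >= p.vmax:
                raise ValueError(f"NDVI vmin >= vmax for region {region!r}")
        sep = haversine_km(*self.winter_centroid, *self.summer_centroid)
        if self.n_migrants > 0 and sep < 2.0 * self.wander_sd_km:
            raise ValueError(
                f"winter and summer centroids only {sep:.1f} km apart; migration is "
                f"undefined below 2 x wander scale ({2 * self.wander_sd_km:.1f} km)")


# ----------------------------------------------------------------------
# truth tables

def _bird_roster(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-bird static attributes: sites, sex, capture age, tracked span."""
    y0, y1 = config.years
    n_years = y1 - y0 + 1
    rows = []
    wlon, wlat = config.winter_centroid
    slon, slat = config.summer_centroid
    for kind, n, tracked in (("resident", config.n_residents, config.resident_years_tracked),
                             ("migrant", config.n_migrants, config.migrant_years_tracked)):
        for j in range(n):
            bird_id = f"{'R' if kind == 'resident' else 'M'}{j + 1:02d}"
            site_sd = (config.site_sd_resident_km if kind == "resident"
                       else config.site_sd_migrant_km)
            dx, dy = rng.normal(0.0, site_sd, size=2)
            w_lat = wlat + dy / KM_PER_DEG
            w_lon = wlon + dx / (KM_PER_DEG * np.cos(np.radians(wlat)))
            sx, sy = rng.normal(0.0, config.site_sd_summer_km, size=2)
            s_lat = slat + sy / KM_PER_DEG
            s_lon = slon + sx / (KM_PER_DEG * np.cos(np.radians(slat)))
            span = min(tracked, n_years)
            start = y0 if n_years == span else int(rng.integers(y0, y1 - span + 2))
            sex = "M" if rng.random() < config.prop_male else "F"
            if rng.random() < config.prop_immature_capture:
                capture_age = int(rng.integers(1, 3))        # 1-2 yr: immature
            else:
                capture_age = int(rng.integers(4, 9))        # adult at capture
            rows.append(dict(bird_id=bird_id, kind=kind, winter_lon=w_lon,
                             winter_lat=w_lat, summer_lon=s_lon, summer_lat=s_lat,
                             year_start=start, year_end=start + span - 1,
                             sex=sex, capture_age=capture_age))
    return pd.DataFrame(rows)


def simulate_truth(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the per-bird roster and per bird-year true migration dates.

    Returns ``(roster, truth)``. ``truth`` has one row per bird-year with the
    four true event dates (NaN for residents), residency flag, age class, sex,
    and the bird's spring-departure random effect in days.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    roster = _bird_roster(config, rng)
    y0 = config.years[0]
    sigma_b = config.sigma_between
    rows = []
    for bird in roster.itertuples():
        dist = haversine_km(bird.winter_lon, bird.winter_lat,
                            bird.summer_lon, bird.summer_lat)
        base_travel = dist / config.migration_speed
        b_dep = rng.normal(0.0, sigma_b)
        b_trav_sp = rng.normal(0.0, config.spring_travel_between_sd)
        b_adep = rng.normal(0.0, config.autumn_between_sd)
        b_trav_au = rng.normal(0.0, config.autumn_travel_between_sd)
        for year in range(bird.year_start, bird.year_end + 1):
            age = bird.capture_age + (year - bird.year_start)
            age_class = "adult" if age > 3 else "immature"
            if bird.kind == "resident":
                rows.append(dict(bird_id=bird.bird_id, year=year, resident=True,
                                 spring_departure=np.nan, spring_arrival=np.nan,
                                 autumn_departure=np.nan, autumn_arrival=np.nan,
                                 age_class=age_class, sex=bird.sex,
                                 indiv_effect=np.nan))
                continue
            dep = (config.mean_spring_departure + config.year_trend * (year - y0)
                   + b_dep + rng.normal(0.0, config.within_sd))
            dep = max(dep, 10.0)
            trav = max(base_travel + b_trav_sp
                       + rng.normal(0.0, config.spring_travel_within_sd), 3.0)
            arr = dep + trav
            adep = (config.mean_autumn_departure + b_adep
                    + rng.normal(0.0, config.autumn_within_sd))
            adep = max(adep, arr + 15.0)
            trav_a = max(base_travel + b_trav_au
                         + rng.normal(0.0, config.autumn_travel_within_sd), 3.0)
            aarr = min(adep + trav_a, 360.0)
            rows.append(dict(bird_id=bird.bird_id, year=year, resident=False,
                             spring_departure=dep, spring_arrival=arr,
                             autumn_departure=adep, autumn_arrival=aarr,
                             age_class=age_class, sex=bird.sex, indiv_effect=b_dep))
    truth = pd.DataFrame(rows)
    return roster, truth


# ----------------------------------------------------------------------
# movement

def _ou_series(n: int, dt_days: float, sd: float, tau: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path (exact discretisation)."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = np.exp(-dt_days / tau)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    e = rng.normal(0.0, innov_sd, size=n)
    x0 = rng.normal(0.0, sd)  # stationary initial condition
    # linear recursion x[t] = a x[t-1] + e[t]
    x, _ = lfilter([1.0], [1.0, -a], e, zi=np.array([a * x0]))
    return x


def _abs_day(year: int, doy: float, t_ref: pd.Timestamp) -> float:
    return (pd.Timestamp(year=year, month=1, day=1) - t_ref) / pd.Timedelta(days=1) + (doy - 1.0)


def simulate_tracks(config: SimulationConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the GPS relocation table and its ground-truth table.

    Returns ``(tracks, truth)``: ``tracks`` with columns
    ``bird_id, timestamp, lon, lat`` (UTC, strictly increasing per bird) and
    ``truth`` as from :func:`simulate_truth`.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_move = (np.random.default_rng(s) for s in ss.spawn(2))
    roster, truth = simulate_truth(config, rng_truth)
    noise_km = config.fix_noise_sd_m / 1000.0
    dt_days = config.fix_interval_hours / 24.0

    frames = []
    for bird in roster.itertuples():
        t_start = pd.Timestamp(year=bird.year_start, month=1, day=1, tz="UTC")
        t_end = pd.Timestamp(year=bird.year_end, month=12, day=31, hour=23,
                             minute=59, tz="UTC")
        times = pd.date_range(t_start, t_end, freq=pd.Timedelta(hours=config.fix_interval_hours))
        t_abs = (times - t_start) / pd.Timedelta(days=1)
        t_abs = np.asarray(t_abs, dtype=float)
        n = len(times)

        if bird.kind == "resident":
            progress = np.zeros(n)
        else:
            tt = truth[(truth.bird_id == bird.bird_id)]
            knots_x = [t_abs[0] - 1.0]
            knots_y = [0.0]
            t_ref = t_start.tz_localize(None)
            for row in tt.itertuples():
                for doy, p in ((row.spring_departure, 0.0), (row.spring_arrival, 1.0),
                               (row.autumn_departure, 1.0), (row.autumn_arrival, 0.0)):
                    knots_x.append(_abs_day(row.year, doy, t_ref))
                    knots_y.append(p)
            knots_x.append(t_abs[-1] + 1.0)
            knots_y.append(0.0)
            progress = np.interp(t_abs, knots_x, knots_y)

        lon_a, lat_a = great_circle_interpolate(
            bird.winter_lon, bird.winter_lat, bird.summer_lon, bird.summer_lat, progress)
        ox = _ou_series(n, dt_days, config.wander_sd_km, config.wander_tau_days, rng_move)
        oy = _ou_series(n, dt_days, config.wander_sd_km, config.wander_tau_days, rng_move)
        if noise_km > 0:
            ox = ox + rng_move.normal(0.0, noise_km, size=n)
            oy = oy + rng_move.normal(0.0, noise_km, size=n)
        lat = lat_a + oy / KM_PER_DEG
        lon = lon_a + ox / (KM_PER_DEG * np.cos(np.radians(lat)))
        keep = rng_move.random(n) >= config.dropout_prob
        frames.append(pd.DataFrame(dict(bird_id=bird.bird_id, timestamp=times[keep],
                                        lon=lon[keep], lat=lat[keep])))
    tracks = pd.concat(frames, ignore_index=True)
    return tracks, truth


# ----------------------------------------------------------------------
# NDVI and weather

def composite_doys(spacing_days: int = 16) -> np.ndarray:
    """Start days of the 16-day compositing periods within a year (1, 17, ...)."""
    return np.arange(1, 366, spacing_days, dtype=float)


def simulate_ndvi(config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Regional mean NDVI series at 16-day composite spacing, one series per
    region per year, covering the year before the first tracking year through
    the last tracking year (so winter/greening covariates exist for every
    bird-year)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    y0, y1 = config.years
    doys = composite_doys()
    rows = []
    for region in sorted(config.ndvi_params):
        p = config.ndvi_params[region]
        for year in range(y0 - 1, y1 + 1):
            t0_y = p.t0 + p.t0_trend * (year - y0)
            vals = ndvi_double_logistic(doys, p.vmin, p.vmax, t0_y, p.k, p.ta, p.ka)
            if p.noise_sd > 0:
                vals = vals + rng.normal(0.0, p.noise_sd, size=len(doys))
            vals = np.clip(vals, -1.0, 1.0)
            dates = (pd.Timestamp(year=year, month=1, day=1)
                     + pd.to_timedelta(doys - 1.0, unit="D"))
            rows.append(pd.DataFrame(dict(region=region, date=dates, ndvi=vals)))
    return pd.concat(rows, ignore_index=True)


def simulate_weather(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Daily station records ``station_id, date, tmean_c, prcp_cm`` covering
    the year before the first tracking year through the last tracking year."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    w = config.weather_params
    if w.n_stations < 1:
        raise ValueError("need at least one weather station")
    y0, y1 = config.years
    dates = pd.date_range(pd.Timestamp(year=y0 - 1, month=1, day=1),
                          pd.Timestamp(year=y1, month=12, day=31), freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    frames = []
    offsets = rng.normal(0.0, w.station_offset_sd_c, size=w.n_stations)
    for s in range(w.n_stations):
        temp = (w.annual_mean_c + offsets[s]
                + w.seasonal_amp_c * np.cos(2.0 * np.pi * (doy - w.peak_doy) / 365.25))
        if w.daily_sd_c > 0:
            temp = temp + rng.normal(0.0, w.daily_sd_c, size=len(dates))
        wet = rng.random(len(dates)) < w.p_wet
        prcp = np.where(wet, rng.exponential(max(w.wet_mean_cm, 1e-12), size=len(dates)), 0.0)
        if w.wet_mean_cm <= 0 or w.p_wet <= 0:
            prcp = np.zeros(len(dates))
        frames.append(pd.DataFrame(dict(station_id=f"S{s + 1:02d}", date=dates,
                                        tmean_c=temp, prcp_cm=prcp)))
    return pd.concat(frames, ignore_index=True)


def simulate_all(config: SimulationConfig) -> Dict[str, pd.DataFrame]:
    """Run all three generators under one seed; keys: tracks, truth, ndvi, weather."""
    tracks, truth = simulate_tracks(config)
    return dict(tracks=tracks, truth=truth,
                ndvi=simulate_ndvi(config), weather=simulate_weather(config))


# ----------------------------------------------------------------------
# small scenario builder used by model-selection power checks

def make_coupling_frame(rng: np.random.Generator, n_birds: int = 24,
                        years: Tuple[int, int] = (2002, 2011),
                        years_per_bird: int = 3, coupling: float = 0.0,
                        date_trend: float = -6.44, greenup_trend: float = -1.61,
                        within_sd: float = 5.0, between_sd: float = 8.9,
                        greenup_sd: float = 3.0) -> pd.DataFrame:
    """Bird-year frame where migration date and green-up share a year trend
    and, optionally, a residual coupling of the given strength. Used to probe
    whether detrended model selection separates shared-trend coincidence from
    true year-to-year tracking."""
    y0, y1 = years
    yrs = np.arange(y0, y1 + 1)
    greenup = 100.0 + greenup_trend * (yrs - y0) + rng.normal(0.0, greenup_sd, len(yrs))
    g_resid = greenup - np.polyval(np.polyfit(yrs, greenup, 1), yrs)
    g_by_year = dict(zip(yrs, zip(greenup, g_resid)))
    rows = []
    for i in range(n_birds):
        b = rng.normal(0.0, between_sd)
        start = int(rng.integers(y0, y1 - years_per_bird + 2))
        adult = rng.random() < 0.5
        for year in range(start, start + years_per_bird):
            g, gr = g_by_year[year]
            date = (150.0 + date_trend * (year - y0) + b
                    + coupling * gr + rng.normal(0.0, within_sd))
            rows.append(dict(ID=f"B{i:02d}", year=year, date=date,
                             age_class="adult" if adult else "immature",
                             greenup=g))
    return pd.DataFrame(rows)
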