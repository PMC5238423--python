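import numpy as np
import pandas as pd
import pytest

from migraphen.geo import haversine_km
from migraphen.repeatability import icc_estimate
from migraphen.synthetic import (SimulationConfig, composite_doys, simulate_all,
                                 simulate_ndvi, simulate_tracks, simulate_truth,
                                 simulate_weather)


def _noiseless_single_migrant(**kw):
    base = dict(n_residents=0, n_migrants=1, years=(2002, 2002),
                fix_noise_sd_m=0.0, dropout_prob=0.0, within_sd=1e-9,
                year_trend=0.0, mean_spring_departure=121.0,
                spring_travel_within_sd=0.0, spring_travel_between_sd=0.0,
                autumn_within_sd=1e-9, autumn_between_sd=1e-9,
                autumn_travel_within_sd=0.0, autumn_travel_between_sd=0.0,
                site_sd_migrant_km=0.0, site_sd_summer_km=0.0, seed=11)
    base.update(kw)
    return SimulationConfig(**base)


def test_identical_seed_gives_identical_outputs():
    a = simulate_all(SimulationConfig(n_residents=2, n_migrants=2,
                                      years=(2002, 2003), seed=5))
    b = simulate_all(SimulationConfig(n_residents=2, n_migrants=2,
                                      years=(2002, 2003), seed=5))
    for key in ("tracks", "truth", "ndvi", "weather"):
        pd.testing.assert_frame_equal(a[key], b[key])


def test_timestamps_strictly_increasing_and_inside_span():
    tracks, _ = simulate_tracks(SimulationConfig(n_residents=1, n_migrants=2,
                                                 years=(2003, 2004), seed=2))
    for _, g in tracks.groupby("bird_id"):
        ts = pd.DatetimeIndex(g["timestamp"])
        assert (np.diff(ts.asi8) > 0).all()
        assert ts.year.min() >= 2003 and ts.year.max() <= 2004


def test_noiseless_migrant_crosses_50_km_at_true_departure():
    cfg = _noiseless_single_migrant()
    tracks, truth = simulate_tracks(cfg)
    dep_true = truth["spring_departure"].iloc[0]
    assert dep_true == pytest.approx(121.0, abs=1e-6)
    d = haversine_km(*cfg.winter_centroid, tracks["lon"], tracks["lat"])
    doy = (pd.DatetimeIndex(tracks["timestamp"]).dayofyear
           + pd.DatetimeIndex(tracks["timestamp"]).hour / 24.0)
    first_out = doy[np.argmax(d.to_numpy() > 50.0)] if hasattr(d, "to_numpy") else None
    first_out = doy[np.argmax(np.asarray(d) > 50.0)]
    assert abs(first_out - dep_true) <= 1.0


def test_resident_only_population_stays_in_winter_range():
    cfg = SimulationConfig(n_residents=1, n_migrants=0, years=(2002, 2002),
                           site_sd_resident_km=0.0, seed=4)
    tracks, truth = simulate_tracks(cfg)
    assert truth["resident"].all()
    d = haversine_km(*cfg.winter_centroid, tracks["lon"].to_numpy(),
                     tracks["lat"].to_numpy())
    # 8 km mean-reverting wander: excursions beyond ~8 sigma do not occur
    assert d.max() < 8.0 * cfg.wander_sd_km


def test_departure_variance_partition_matches_icc_target():
    """Monte-Carlo check of the between/within split: 24 migrants x 4 common
    years, no year trend, within-sd 5 days, target ICC 0.76."""
    cfg = SimulationConfig(n_residents=0, n_migrants=24, years=(2002, 2005),
                           migrant_years_tracked=4, year_trend=0.0,
                           within_sd=5.0, icc_target=0.76, seed=9)
    _, truth = simulate_truth(cfg)
    m = truth[~truth["resident"]]
    r = icc_estimate(m["spring_departure"], m["bird_id"]).r
    assert 0.6 < r < 0.9


def test_truth_dates_ordered_within_each_cycle():
    _, truth = simulate_truth(SimulationConfig(seed=6))
    m = truth[~truth["resident"]]
    assert (m["spring_departure"] < m["spring_arrival"]).all()
    assert (m["spring_arrival"] < m["autumn_departure"]).all()
    assert (m["autumn_departure"] < m["autumn_arrival"]).all()


def test_ndvi_16_day_spacing_gives_23_composites_per_year():
    assert len(composite_doys()) == 23
    cfg = SimulationConfig(n_residents=1, n_migrants=0, years=(2002, 2002), seed=1)
    ndvi = simulate_ndvi(cfg)
    per_year = ndvi.groupby(["region", pd.DatetimeIndex(ndvi["date"]).year]).size()
    assert (per_year == 23).all()


def test_noiseless_ndvi_hits_half_amplitude_at_spring_midpoint():
    from migraphen.curves import ndvi_double_logistic
    # autumn term negligible when ta >> t0
    v = ndvi_double_logistic(90.0, 0.2, 0.8, 90.0, 0.1, 330.0, 0.1)
    assert v == pytest.approx(0.2 + 0.6 / 2.0, abs=1e-6)


def test_weather_constant_when_noise_and_amplitude_zero():
    from migraphen.synthetic import WeatherParams
    cfg = SimulationConfig(
        n_residents=1, n_migrants=0, years=(2002, 2002), seed=3,
        weather_params=WeatherParams(annual_mean_c=10.0, seasonal_amp_c=0.0,
                                     daily_sd_c=0.0, p_wet=0.0, n_stations=2,
                                     station_offset_sd_c=0.0))
    w = simulate_weather(cfg)
    assert np.allclose(w["tmean_c"], 10.0)
    assert np.allclose(w["prcp_cm"], 0.0)


def test_rejects_invalid_configs():
    with pytest.raises(ValueError):
        SimulationConfig(icc_target=1.2).validate()
    with pytest.raises(ValueError):
        SimulationConfig(years=(2005, 2002)).validate()
    with pytest.raises(ValueError):
        SimulationConfig(summer_centroid=(-91.5, 30.21)).validate()
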