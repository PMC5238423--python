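import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPolygon, Polygon

from migraphen.curves import nsd_double_logistic
from migraphen.geo import KM_PER_DEG
from migraphen.nsd import (MigrationDates, NSDSeries, NoWinterAnchorError,
                           compute_nsd, detect_plateau, determine_migration_dates,
                           fit_double_logistic, summarize_dates)
from migraphen.ranges import RangePolygon


def _square(lon0, lat0, half=1.0, label="range"):
    ring = [(lon0 - half, lat0 - half), (lon0 + half, lat0 - half),
            (lon0 + half, lat0 + half), (lon0 - half, lat0 + half)]
    return RangePolygon(label=label, geometry=MultiPolygon([Polygon(ring)]),
                        method="kernel_isopleth", isopleth_level=0.95)


def _track(times, lons, lats, bird="B1"):
    return pd.DataFrame(dict(bird_id=bird, timestamp=pd.to_datetime(times, utc=True),
                             lon=lons, lat=lats))


class TestComputeNSD:
    def test_reference_fix_is_zero_and_one_degree_value(self):
        nb = _square(-91.0, 30.0)
        tr = _track(["2002-01-01", "2002-01-02", "2002-01-03"],
                    [-91.0, -91.0, -91.0], [30.0, 30.0, 31.0])
        s = compute_nsd(tr, nb)
        assert s.nsd[0] == 0.0
        assert s.nsd[2] == pytest.approx(KM_PER_DEG ** 2, rel=1e-3)
        assert s.nsd[2] == pytest.approx(111.195 ** 2, rel=1e-3)

    def test_monotone_poleward_path_gives_nondecreasing_nsd(self):
        lats = 30.0 + np.linspace(0, 15, 40)
        times = pd.date_range("2002-01-01", periods=40, freq="D", tz="UTC")
        s = compute_nsd(_track(times, np.full(40, -91.0), lats), _square(-91.0, 30.0))
        assert (np.diff(s.nsd) >= 0).all()

    def test_no_winter_anchor_raises(self):
        tr = _track(["2002-01-01"], [-50.0], [10.0])
        with pytest.raises(NoWinterAnchorError):
            compute_nsd(tr, _square(-91.0, 30.0))


def _series_from_curve(params, noise_sd=0.0, rng=None):
    t = np.arange(1.0, 366.0)
    y = nsd_double_logistic(t, *params)
    if noise_sd:
        y = y + rng.normal(0, noise_sd, len(t))
    return NSDSeries(bird_id="B1", year=2002, t=t, nsd=y, ref_lon=0.0, ref_lat=0.0)


class TestDoubleLogisticFit:
    def test_noiseless_parameters_recovered_to_1e3_relative(self):
        truth = (1.6e6, 120.0, 3.0, 270.0, 5.0)
        fit = fit_double_logistic(_series_from_curve(truth), daily_aggregate=False)
        est = (fit.delta, fit.theta_s, fit.phi_s, fit.theta_a, fit.phi_a)
        for e, tr in zip(est, truth):
            assert abs(e - tr) / tr < 1e-3
        assert fit.classification == "migrant"

    def test_constant_zero_series_classified_resident(self):
        s = NSDSeries("B1", 2002, np.arange(1.0, 366.0), np.zeros(365), 0.0, 0.0)
        assert fit_double_logistic(s, daily_aggregate=False).classification == "resident"

    def test_curve_at_spring_inflection_is_half_plateau(self):
        fit = fit_double_logistic(
            _series_from_curve((1.0e6, 120.0, 3.0, 330.0, 5.0)), daily_aggregate=False)
        assert fit.predict(fit.theta_s) == pytest.approx(fit.delta / 2.0, rel=1e-3)

    def test_too_short_series_rejected(self):
        s = NSDSeries("B1", 2002, np.arange(1.0, 50.0), np.zeros(49), 0.0, 0.0)
        with pytest.raises(ValueError):
            fit_double_logistic(s)


class TestPlateau:
    def _fit(self, delta=1.0e6, theta_s=120.0, phi_s=3.0, theta_a=350.0, phi_a=5.0):
        return fit_double_logistic(
            _series_from_curve((delta, theta_s, phi_s, theta_a, phi_a)),
            daily_aggregate=False)

    def test_start_matches_logistic_inversion(self):
        fit = self._fit()
        start, end = detect_plateau(fit, 0.95)
        assert start == pytest.approx(120.0 + 3.0 * np.log(19.0), abs=0.1)
        assert start < end

    def test_half_occupancy_is_inflection_day(self):
        start, _ = detect_plateau(self._fit(), 0.5)
        assert start == pytest.approx(120.0, abs=0.1)

    def test_occupancy_monotone_in_fraction(self):
        fit = self._fit()
        s1, e1 = detect_plateau(fit, 0.5)
        s2, e2 = detect_plateau(fit, 0.95)
        assert s1 < s2 and e2 < e1


class TestMigrationDates:
    nb = _square(-91.0, 30.0, half=0.6, label="non_breeding")
    summer = _square(-99.0, 47.0, half=0.6, label="summer")

    def _migrant_track(self):
        """Deterministic migrant: winter to day 120, travel 10 days, summer to
        day 260, return travel 10 days."""
        times = pd.date_range("2002-01-01", "2002-12-31", freq="6h", tz="UTC")
        doy = times.dayofyear + times.hour / 24.0
        p = np.interp(doy, [1, 120, 130, 260, 270, 366], [0, 0, 1, 1, 0, 0])
        lons = -91.0 + (-99.0 + 91.0) * p
        lats = 30.0 + (47.0 - 30.0) * p
        return _track(times, lons, lats)

    def test_dates_recovered_on_constructed_migrant(self):
        md = determine_migration_dates(self._migrant_track(), self.nb, self.summer)
        assert md.spring_departure == pytest.approx(120.0, abs=2.0)
        assert md.spring_arrival == pytest.approx(130.0, abs=2.0)
        assert md.autumn_departure == pytest.approx(260.0, abs=2.0)
        assert md.autumn_arrival == pytest.approx(270.0, abs=2.0)
        assert (md.spring_departure < md.spring_arrival
                < md.autumn_departure < md.autumn_arrival)

    def test_resident_track_yields_no_dates(self):
        times = pd.date_range("2002-01-01", "2002-12-31", freq="12h", tz="UTC")
        md = determine_migration_dates(
            _track(times, np.full(len(times), -91.0), np.full(len(times), 30.0)),
            self.nb, self.summer)
        assert md.spring_departure is None and md.spring_arrival is None

    def test_short_excursion_is_not_a_departure(self):
        """A 2-day out-and-back trip must not register with 5-day persistence."""
        times = pd.date_range("2002-01-01", "2002-12-31", freq="6h", tz="UTC")
        doy = times.dayofyear + times.hour / 24.0
        p = np.interp(doy, [1, 120, 130, 260, 270, 366], [0, 0, 1, 1, 0, 0])
        excursion = (doy >= 60) & (doy < 62)
        lons = -91.0 + (-99.0 + 91.0) * p
        lats = 30.0 + (47.0 - 30.0) * p
        lats = np.where(excursion, 33.0, lats)  # 2 days well outside winter
        md = determine_migration_dates(_track(times, lons, lats), self.nb, self.summer)
        assert md.spring_departure is not None
        assert md.spring_departure > 100.0  # the day-60 excursion was ignored


class TestSummaries:
    @staticmethod
    def _frame(rows):
        df = pd.DataFrame(rows)
        df["classification"] = "migrant"
        for ev in ("spring_arrival", "autumn_departure", "autumn_arrival"):
            if ev not in df:
                df[ev] = np.nan
        return df

    def test_single_bird_two_years_mean_difference(self):
        df = self._frame([dict(bird_id="A", year=2002, spring_departure=120.0),
                          dict(bird_id="A", year=2003, spring_departure=130.0)])
        out = summarize_dates(df)
        assert out["successive_diffs"]["spring_departure"]["mean"] == pytest.approx(10.0)

    def test_identical_dates_give_zero_differences(self):
        df = self._frame([dict(bird_id=b, year=y, spring_departure=121.0)
                          for b in "AB" for y in (2002, 2003, 2004)])
        sd = summarize_dates(df)["successive_diffs"]["spring_departure"]
        assert sd["min"] == sd["max"] == sd["mean"] == 0.0
        assert summarize_dates(df)["medians"]["spring_departure"] == 121.0
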