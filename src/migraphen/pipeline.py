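"""Config-driven orchestration of the full migration-phenology analysis.

Stage order mirrors the analysis workflow: seasonal ranges -> NSD fits and
migration dates -> NDVI phenology -> winter climate -> repeatability ->
cross-sectional trends and longitudinal mixed models -> detrended
(spurious-correlation) models. Every tabular artifact is written as CSV and
every polygon as GeoJSON; a fixed seed makes the outputs byte-identical
between runs.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from . import io as io_mod
from . import nsd as nsd_mod
from . import phenology as phen_mod
from . import ranges as ranges_mod
from . import repeatability as rpt_mod
from . import trends as trends_mod
from .synthetic import SimulationConfig, simulate_all

log = logging.getLogger("migraphen")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration: a simulate block or input paths, plus the
    analysis parameters (defaults follow the standard telemetry workflow:
    95% isopleths, 0.8 x reference bandwidth, 50%-amplitude green-up, 5000
    permutations)."""

    simulate: Optional[SimulationConfig] = field(default_factory=SimulationConfig)
    tracks_path: Optional[str] = None
    ndvi_path: Optional[str] = None
    weather_path: Optional[str] = None
    colonies_path: Optional[str] = None

    isopleth_level: float = 0.95
    bandwidth_scale: float = 0.8
    persistence_days: float = 5.0
    plateau_fraction: float = 0.95
    greenup_threshold: float = 0.5
    spring_window: Tuple[float, float] = (1.0, 180.0)
    winter_window: Tuple[Tuple[int, int], Tuple[int, int]] = climate_mod.DEFAULT_WINDOW
    n_perm: int = 5000
    southern_lat_cut: float = 31.5
    min_migration_nsd_km2: float = 1.0e4
    grid_size: int = 250
    seed: Optional[int] = None

    def validate(self) -> None:
        for name in ("isopleth_level", "plateau_fraction", "greenup_threshold",
                     "bandwidth_scale"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.simulate is None:
            for p in (self.tracks_path, self.ndvi_path, self.weather_path):
                if p is None or not Path(p).exists():
                    raise ValueError(f"input path missing or absent: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", "default")
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is None:
            cfg.simulate = None
        elif sim == "default":
            cfg.simulate = SimulationConfig()
        elif isinstance(sim, dict):
            from .synthetic import NDVIRegionParams, WeatherParams
            sim = dict(sim)
            if "ndvi_params" in sim:
                sim["ndvi_params"] = {k: NDVIRegionParams(**v)
                                      for k, v in sim["ndvi_params"].items()}
            if "weather_params" in sim:
                sim["weather_params"] = WeatherParams(**sim["weather_params"])
            if "years" in sim:
                sim["years"] = tuple(sim["years"])
            for key in ("winter_centroid", "summer_centroid"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulate = SimulationConfig(**sim)
        return cfg

    def apply_overrides(self, overrides) -> None:
        """Apply ``key=value`` strings; dotted keys reach the simulate block
        (e.g. ``simulate.n_migrants=6``)."""
        for item in overrides:
            key, _, val = item.partition("=")
            val = yaml.safe_load(val)
            if key.startswith("simulate."):
                setattr(self.simulate, key.split(".", 1)[1], val)
            else:
                if key in ("years",):
                    val = tuple(val)
                setattr(self, key, val)


def _load_inputs(cfg: PipelineConfig) -> Dict[str, pd.DataFrame]:
    if cfg.simulate is not None:
        if cfg.seed is not None:
            cfg.simulate = dataclasses.replace(cfg.simulate, seed=int(cfg.seed))
        log.info("simulating inputs (seed=%s)", cfg.simulate.seed)
        return simulate_all(cfg.simulate)
    data = dict(tracks=io_mod.read_tracks_csv(cfg.tracks_path),
                ndvi=io_mod.read_ndvi_csv(cfg.ndvi_path),
                weather=io_mod.read_weather_csv(cfg.weather_path),
                truth=None)
    return data


def run_pipeline(cfg: PipelineConfig, out_dir) -> Dict:
    """Execute the full analysis; writes CSV/GeoJSON artifacts plus a run log
    into ``out_dir`` and returns the in-memory results."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: Dict = {"config": cfg}
    try:
        data = _load_inputs(cfg)
        tracks, truth = data["tracks"], data.get("truth")
        ndvi, weather = data["ndvi"], data["weather"]
        results["truth"] = truth
        log.info("inputs: %d fixes, %d birds, %d NDVI composites, %d station-days",
                 len(tracks), tracks["bird_id"].nunique(), len(ndvi), len(weather))

        # ---------------- stage 1: ranges -------------------------------
        resident_ids = (set(truth.loc[truth["resident"], "bird_id"])
                        if truth is not None else set())
        if resident_ids:
            pool = tracks[tracks["bird_id"].isin(resident_ids)]
        else:
            # fall back to early-winter fixes of all birds
            doy = nsd_mod.continuous_doy(tracks["timestamp"])
            pool = tracks[doy < 32.0]
            log.info("no residents: anchoring the non-breeding range on "
                     "January fixes of all birds")
        non_breeding = ranges_mod.super_range(
            pool, label="non_breeding", level=cfg.isopleth_level,
            bandwidth_scale=cfg.bandwidth_scale, grid_size=cfg.grid_size)
        polygons = [non_breeding]
        log.info("non-breeding super range: %d fixes pooled", len(pool))

        # ---------------- stage 2: NSD fits, summer ranges, dates -------
        years = range(cfg.simulate.years[0], cfg.simulate.years[1] + 1) \
            if cfg.simulate is not None else \
            range(tracks["timestamp"].dt.year.min(), tracks["timestamp"].dt.year.max() + 1)
        date_records = []
        fits = {}
        summer_fix_frames = []
        meta = (truth.set_index(["bird_id", "year"])
                if truth is not None else None)
        n_migrant_birds = 0
        for bird_id, bt in tracks.groupby("bird_id"):
            bird_years = sorted(pd.DatetimeIndex(bt["timestamp"]).year.unique())
            bird_fits = {}
            plateau_fixes = []
            for year in bird_years:
                try:
                    series = nsd_mod.compute_nsd(bt, non_breeding, year=int(year))
                    fit = nsd_mod.fit_double_logistic(
                        series, min_migration_nsd_km2=cfg.min_migration_nsd_km2)
                except (nsd_mod.NoWinterAnchorError, ValueError) as exc:
                    log.warning("NSD fit skipped for %s %s: %s", bird_id, year, exc)
                    continue
                bird_fits[int(year)] = fit
                fits[(bird_id, int(year))] = fit
                if fit.classification == "migrant":
                    try:
                        p0, p1 = nsd_mod.detect_plateau(fit, cfg.plateau_fraction)
                    except nsd_mod.PlateauError as exc:
                        log.warning("plateau not found for %s %s: %s", bird_id, year, exc)
                        continue
                    ydf = bt[pd.DatetimeIndex(bt["timestamp"]).year == year]
                    doy = nsd_mod.continuous_doy(ydf["timestamp"])
                    plateau_fixes.append(ydf[(doy >= p0) & (doy <= p1)])
            migrant_years = [y for y, f in bird_fits.items()
                             if f.classification == "migrant"]
            if not migrant_years or not plateau_fixes:
                for year in bird_years:
                    rec = nsd_mod.MigrationDates(bird_id=bird_id, year=int(year),
                                                 classification="resident")
                    _attach_meta(rec, meta)
                    date_records.append(rec)
                continue
            n_migrant_birds += 1
            pl = pd.concat(plateau_fixes, ignore_index=True)
            summer_fix_frames.append(pl)
            summer = ranges_mod.super_range(
                pl, label=f"summer_{bird_id}", level=cfg.isopleth_level,
                bandwidth_scale=cfg.bandwidth_scale, grid_size=cfg.grid_size)
            for year in bird_years:
                if year in migrant_years:
                    rec = nsd_mod.determine_migration_dates(
                        bt, non_breeding, summer,
                        persistence_days=cfg.persistence_days, year=int(year))
                    rec.classification = "migrant"
                else:
                    rec = nsd_mod.MigrationDates(bird_id=bird_id, year=int(year),
                                                 classification="resident")
                _attach_meta(rec, meta)
                date_records.append(rec)
        dates = pd.DataFrame([r.as_dict() for r in date_records])
        dates = dates.sort_values(["bird_id", "year"]).reset_index(drop=True)
        results["migration_dates"] = dates
        results["fits"] = fits
        log.info("migration dates: %d bird-years, %d migrant birds",
                 len(dates), n_migrant_birds)
        if summer_fix_frames:
            summer_super = ranges_mod.super_range(
                pd.concat(summer_fix_frames, ignore_index=True),
                label="summer_super", level=cfg.isopleth_level,
                bandwidth_scale=cfg.bandwidth_scale, grid_size=cfg.grid_size)
            polygons.append(summer_super)
        if cfg.colonies_path:
            pts = io_mod.read_points_csv(cfg.colonies_path)
            polygons.append(ranges_mod.convex_hull_range(pts, label="breeding"))
        ranges_mod.write_geojson(polygons, out / "ranges.geojson")
        results["ranges"] = {p.label: p for p in polygons}

        # ---------------- stage 3: phenology ----------------------------
        phen = phen_mod.estimate_phenology(ndvi, threshold=cfg.greenup_threshold,
                                           window=cfg.spring_window)
        phen.to_csv(out / "phenology.csv", index=False)
        results["phenology"] = phen
        phen_trends = {}
        for region, g in phen.groupby("region"):
            tab, headline = phen_mod.phenology_trend(g)
            phen_trends[region] = headline
            log.info("green-up trend %s: %.2f d/yr (se %.2f)", region,
                     headline["slope"], headline["slope_se"])
        results["phenology_trends"] = phen_trends

        # ---------------- stage 4: climate ------------------------------
        clim = climate_mod.winter_summary(weather, years, window=cfg.winter_window)
        clim.to_csv(out / "climate.csv", index=False)
        results["climate"] = clim

        migrants = dates[(dates["classification"] == "migrant")]
        if len(migrants) == 0:
            log.info("no migrant bird-years: repeatability and trend stages skipped")
            dates_long = _dates_long(dates)
            dates_long.to_csv(out / "migration_dates.csv", index=False)
            return results

        # ---------------- stage 5: repeatability ------------------------
        rpt_rows = []
        rpt_results = {}
        seed0 = cfg.simulate.seed if cfg.simulate is not None else (cfg.seed or 0)
        for i, ev in enumerate(nsd_mod.EVENTS):
            sub = migrants.dropna(subset=[ev])
            for mode in ("raw", "detrended"):
                detr = sub["year"] if mode == "detrended" else None
                try:
                    res = rpt_mod.permutation_test(sub[ev], sub["bird_id"],
                                                   n_perm=cfg.n_perm,
                                                   seed=(seed0 + 1000 + i) % (2**31),
                                                   event=ev, detrend_years=detr)
                except ValueError as exc:
                    log.warning("repeatability skipped for %s (%s): %s", ev, mode, exc)
                    continue
                rpt_results[(ev, mode)] = res
                rpt_rows.append(dict(event=ev, mode=mode, r=res.r, p_perm=res.p_perm,
                                     n_ind=res.n_individuals, n_obs=res.n_obs,
                                     n_perm=res.n_permutations))
        rpt_df = pd.DataFrame(rpt_rows)
        rpt_df.to_csv(out / "repeatability.csv", index=False)
        results["repeatability"] = rpt_results
        results["date_summary"] = nsd_mod.summarize_dates(dates)

        # ---------------- stage 6: trends -------------------------------
        frame = _analysis_frame(migrants, clim, phen)
        results["frame"] = frame
        cs_tables = []
        coef_tables = []
        cross = {}
        for resp, label in (("spring_departure", "population_departure"),
                            ("spring_arrival", "population_arrival")):
            yearly = (frame.dropna(subset=[resp]).groupby("year")[resp]
                      .mean().reset_index().rename(columns={resp: "date"}))
            if len(yearly) >= 4:
                tab, coefs, headline = trends_mod.fit_cross_sectional(yearly)
                tab.insert(0, "analysis", label)
                coefs.insert(0, "analysis", label)
                cs_tables.append(tab)
                coef_tables.append(coefs)
                cross[label] = headline
                log.info("cross-sectional %s slope: %.2f d/yr", label, headline["slope"])
        adults = frame[frame["age_class"] == "adult"].dropna(subset=["spring_departure"])
        yearly_ad = (adults.groupby("year")["spring_departure"].mean()
                     .reset_index().rename(columns={"spring_departure": "date"}))
        if len(yearly_ad) >= 4:
            tab, coefs, headline = trends_mod.fit_cross_sectional(yearly_ad)
            tab.insert(0, "analysis", "adult_departure")
            coefs.insert(0, "analysis", "adult_departure")
            cs_tables.append(tab)
            coef_tables.append(coefs)
            cross["adult_departure"] = headline
        results["cross_sectional"] = cross

        lmm_results = {}
        for resp in ("spring_departure", "spring_arrival"):
            sub = frame.dropna(subset=[resp, "temp", "prec", "greenup"]).copy()
            sub = sub.rename(columns={resp: "date"})
            if len(sub) < 10 or sub["ID"].nunique() < 5:
                log.warning("LMM set skipped for %s: too few bird-years", resp)
                continue
            tab, coefs, _ = trends_mod.fit_lmm_set(sub, ["temp", "prec"], "date")
            tab.insert(0, "analysis", f"lmm_climate_{resp}")
            coefs.insert(0, "analysis", f"lmm_climate_{resp}")
            cs_tables.append(tab)
            coef_tables.append(coefs)
            lmm_results[f"climate_{resp}"] = tab
            tabg, coefsg, _ = trends_mod.fit_lmm_set(sub, ["greenup"], "date")
            tabg.insert(0, "analysis", f"lmm_greenup_{resp}")
            coefsg.insert(0, "analysis", f"lmm_greenup_{resp}")
            cs_tables.append(tabg)
            coef_tables.append(coefsg)
            lmm_results[f"greenup_{resp}"] = tabg

            # detrended (spurious-correlation) check
            det = sub.copy()
            det["ddate"] = trends_mod.detrend(det["date"], det["year"])
            det["dgreenup"] = trends_mod.detrend(det["greenup"], det["year"])
            tabd, coefsd, _ = trends_mod.detrended_greenup_models(det)
            tabd.insert(0, "analysis", f"lmm_detrended_{resp}")
            coefsd.insert(0, "analysis", f"lmm_detrended_{resp}")
            cs_tables.append(tabd)
            coef_tables.append(coefsd)
            lmm_results[f"detrended_{resp}"] = tabd
        results["lmm"] = lmm_results

        if cs_tables:
            pd.concat(cs_tables, ignore_index=True).to_csv(
                out / "model_selection.csv", index=False)
            pd.concat(coef_tables, ignore_index=True).to_csv(
                out / "coefficients.csv", index=False)
        dates_long = _dates_long(dates)
        dates_long.to_csv(out / "migration_dates.csv", index=False)
        log.info("pipeline complete: artifacts in %s", out)
        return results
    finally:
        log.removeHandler(handler)
        handler.close()


def _attach_meta(rec, meta) -> None:
    if meta is None:
        return
    key = (rec.bird_id, rec.year)
    if key in meta.index:
        row = meta.loc[key]
        rec.age_class = str(row["age_class"])
        rec.sex = str(row["sex"])


def _dates_long(dates: pd.DataFrame) -> pd.DataFrame:
    long = dates.melt(id_vars=["bird_id", "year", "age_class", "sex", "classification"],
                      value_vars=list(nsd_mod.EVENTS), var_name="event",
                      value_name="doy")
    return long.sort_values(["bird_id", "year", "event"]).reset_index(drop=True)


def _analysis_frame(migrants: pd.DataFrame, clim: pd.DataFrame,
                    phen: pd.DataFrame) -> pd.DataFrame:
    """Merge bird-year migration dates with yearly winter climate and
    non-breeding green-up into the longitudinal modelling frame."""
    frame = migrants.rename(columns={"bird_id": "ID"}).copy()
    frame = frame.merge(clim.rename(columns={"tmean_c": "temp", "prcp_cm": "prec"})[
        ["year", "temp", "prec"]], on="year", how="left")
    nb = phen[phen["region"] == "non_breeding"][["year", "green_up_doy"]]
    frame = frame.merge(nb.rename(columns={"green_up_doy": "greenup"}),
                        on="year", how="left")
    return frame
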