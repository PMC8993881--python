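"""End-to-end pipeline: raw fixes -> filters -> declutter -> BBMM -> catscape.

``run_pipeline`` executes the full analysis for a population of cats and
(optionally) writes all artifacts to an output directory:

* ``catscape.asc`` — the population surface (ESRI ASCII grid, text)
* ``ud_<cat>.asc`` — individual UDs
* ``contours.geojson`` — per-cat and population volume contours
* ``summary_per_cat.csv`` / ``summary_population.csv``
* ``manifest.yaml`` — configuration, defaults used, per-cat exclusions

Every default used is serialised into the manifest so a run can be
reproduced exactly; the pipeline itself contains no randomness.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import bbmm as _bbmm
from .clustering import declutter_track
from .geo import LandCover, geometry_feature, write_geojson
from .population import (
    Catscape,
    build_catscape,
    catscape_contour,
    distance_stats,
    intensity_fold_range,
    landcover_partition,
    near_home_intensity_ratio,
    range_nonurban_fraction,
)
from .raster import GridSpec, write_ascii_grid
from .tracks import (
    StudyCat,
    Track,
    apply_standard_filters,
    daily_coverage,
    outdoor_weight,
    thin_track,
)


@dataclass
class PipelineConfig:
    """All knobs of the standard analysis, with study defaults."""

    min_elev: float = 0.0
    max_elev: float = 300.0
    first_days: int = 2
    max_ehpe: float = 5000.0
    thin_interval: float = 120.0  # s
    cluster_radius: float = 10.0  # m
    cluster_window: float = 24 * 3600.0  # s
    cluster_min_points: int = 2
    location_error: float = 10.0  # m
    error_model: str = "full"  # leave-one-out likelihood variant
    max_lag: float = 3600.0  # s
    cell_size: float = 10.0  # m
    n_alpha: int = 50
    levels: tuple[float, ...] = (0.5, 0.95, 0.99)
    min_tracking_days: int = 5
    near_home_radius: float = 50.0  # m
    annulus_outer_radius: float = 100.0  # m
    gap_cap: float = 1800.0  # s, daily-coverage gap cap
    tz_offset_hours: float = 2.0
    grid_buffer_cap: float = 500.0  # m

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(d)
        if "levels" in kwargs:
            kwargs["levels"] = tuple(float(x) for x in kwargs["levels"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        return d


@dataclass
class PerCatResult:
    """Everything computed for one included cat."""

    cat_id: str
    track_outdoor: Track  # decluttered, pre-thinning (time-fraction proxy)
    track_thinned: Track
    weight: float
    n_tracking_days: int
    mean_daily_outdoor_hours: float
    results: _bbmm.BrownianBridgeResults
    ud: "object" = None  # UdRaster, filled after the shared grid is known
    contours: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    catscape: Catscape
    per_cat: dict[str, PerCatResult]
    summary_per_cat: pd.DataFrame
    summary_population: dict
    excluded: dict[str, str]
    grid: GridSpec
    config: PipelineConfig


def _prepare_cat(
    track: Track, cat: StudyCat, config: PipelineConfig
) -> tuple[PerCatResult | None, str | None]:
    """Filter, declutter and fit one cat; returns (result, exclusion reason)."""
    filtered = apply_standard_filters(
        track,
        min_elev=config.min_elev,
        max_elev=config.max_elev,
        first_days=config.first_days,
        max_ehpe=config.max_ehpe,
    )
    if filtered.n_fixes < 2:
        return None, f"only {filtered.n_fixes} fixes after filtering"
    outdoor, _clusters = declutter_track(
        filtered,
        cat.home_polygon,
        radius=config.cluster_radius,
        window=config.cluster_window,
        min_points=config.cluster_min_points,
    )
    if outdoor.n_fixes < 2:
        return None, "no outdoor fixes after indoor-cluster excision"
    coverages = daily_coverage(outdoor, gap_cap=config.gap_cap)
    if len(coverages) < config.min_tracking_days:
        return None, (
            f"{len(coverages)} tracking day(s) with outdoor data "
            f"< required {config.min_tracking_days}"
        )
    w = outdoor_weight(coverages)
    thinned = thin_track(outdoor, min_interval=config.thin_interval)
    if thinned.n_fixes < 3:
        return None, f"only {thinned.n_fixes} fixes after thinning"
    model = _bbmm.BrownianBridge(
        thinned,
        location_error=config.location_error,
        max_lag=config.max_lag,
        error_model=config.error_model,
    )
    try:
        results = model.fit()
    except ValueError as exc:
        return None, f"BBMM fit failed: {exc}"
    res = PerCatResult(
        cat_id=track.cat_id,
        track_outdoor=outdoor,
        track_thinned=thinned,
        weight=w.w,
        n_tracking_days=len(coverages),
        mean_daily_outdoor_hours=float(np.mean([c.outdoor_hours for c in coverages])),
        results=results,
    )
    return res, None


def _shared_grid(per_cat: dict[str, PerCatResult], config: PipelineConfig) -> GridSpec:
    """One global grid for all cats: outdoor bounding box plus bridge buffer."""
    xs, ys = [], []
    for r in per_cat.values():
        xy = r.track_thinned.xy()
        xs.append(xy[:, 0])
        ys.append(xy[:, 1])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    sigma2_max = max(r.results.sigma2_m for r in per_cat.values())
    buf = _bbmm.grid_buffer(
        sigma2_max, config.location_error, config.max_lag, cap=config.grid_buffer_cap
    )
    crs = next(iter(per_cat.values())).track_thinned.crs_tag
    return GridSpec.from_extent(
        x.min() - buf, y.min() - buf, x.max() + buf, y.max() + buf,
        config.cell_size, crs_tag=crs,
    )


def run_pipeline(
    tracks: Mapping[str, Track],
    homes: Mapping[str, StudyCat],
    landcover: LandCover | None = None,
    config: PipelineConfig | Mapping | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run the complete analysis for a population of tracked cats.

    Parameters
    ----------
    tracks : mapping cat_id -> Track
        Raw per-cat fixes (download dates already attached to the tracks).
    homes : mapping cat_id -> StudyCat
        Residence footprints (cats without a home entry are excluded).
    landcover : LandCover, optional
        Enables the developed/other partition statistics.
    config : PipelineConfig or mapping, optional
    out_dir : path, optional
        If given, all artifacts and the run manifest are written there.
    """
    if config is None:
        config = PipelineConfig()
    elif not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)

    per_cat: dict[str, PerCatResult] = {}
    excluded: dict[str, str] = {}
    for cat_id in sorted(tracks):
        if cat_id not in homes:
            excluded[cat_id] = "no home footprint in metadata"
            continue
        res, reason = _prepare_cat(tracks[cat_id], homes[cat_id], config)
        if res is None:
            excluded[cat_id] = reason
        else:
            per_cat[cat_id] = res
    if not per_cat:
        raise ValueError(f"no usable cats; exclusions: {excluded}")

    grid = _shared_grid(per_cat, config)
    uds = {}
    for cat_id, r in per_cat.items():
        r.ud = r.results.compute_ud(grid=grid, n_alpha=config.n_alpha)
        r.contours = _bbmm.home_range_summary(r.ud, config.levels)
        uds[cat_id] = r.ud
    weights = {cid: r.weight for cid, r in per_cat.items()}
    cs = build_catscape(uds, weights, grid)

    rows = []
    for cat_id, r in sorted(per_cat.items()):
        ds = distance_stats(
            r.track_outdoor, homes[cat_id].home_point, radius=config.near_home_radius
        )
        row = {
            "cat_id": cat_id,
            "n_fixes_outdoor": r.track_outdoor.n_fixes,
            "n_fixes_thinned": r.track_thinned.n_fixes,
            "n_tracking_days": r.n_tracking_days,
            "mean_daily_outdoor_hours": r.mean_daily_outdoor_hours,
            "outdoor_weight": r.weight,
            "sigma2_m_per_min": r.results.motion_variance.sigma2_m_per_min,
            "mean_distance_home_m": ds.mean_m,
            "max_distance_home_m": ds.max_m,
            "frac_fixes_within_50m": ds.frac_within,
        }
        for lv in config.levels:
            row[f"area_ha_{int(round(lv * 100))}"] = r.contours[lv].area_ha
        if landcover is not None:
            row["frac_range95_nonurban"] = range_nonurban_fraction(r.ud, landcover, 0.95)
        rows.append(row)
    summary_per_cat = pd.DataFrame(rows)

    pop_contour = catscape_contour(cs, 0.99)
    population = {
        "n_cats": len(per_cat),
        "total_weight": cs.total_weight,
        "catscape_area_99_ha": pop_contour.area_ha,
        "intensity_fold_range_99": intensity_fold_range(cs, 0.99),
        "near_home_intensity_ratio": near_home_intensity_ratio(
            cs,
            [homes[cid].home_point for cid in per_cat],
            r1=config.near_home_radius,
            r2=config.annulus_outer_radius,
        ),
    }
    if landcover is not None:
        fa, fi = landcover_partition(cs, landcover, level=0.99)
        population["frac_area_outside_developed"] = fa
        population["frac_intensity_outside_developed"] = fi

    result = PipelineResult(
        catscape=cs,
        per_cat=per_cat,
        summary_per_cat=summary_per_cat,
        summary_population=population,
        excluded=excluded,
        grid=grid,
        config=config,
    )
    if out_dir is not None:
        _write_artifacts(result, out_dir)
    return result


def _write_artifacts(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(result.catscape.raster, out / "catscape.asc")
    for cat_id, r in sorted(result.per_cat.items()):
        write_ascii_grid(r.ud, out / f"ud_{cat_id}.asc")
    feats = []
    for cat_id, r in sorted(result.per_cat.items()):
        for lv, c in sorted(r.contours.items()):
            feats.append(
                geometry_feature(
                    c.polygons, {"cat_id": cat_id, "level": lv, "area_ha": c.area_ha}
                )
            )
    pc = catscape_contour(result.catscape, 0.99)
    feats.append(
        geometry_feature(
            pc.polygons, {"cat_id": "population", "level": 0.99, "area_ha": pc.area_ha}
        )
    )
    write_geojson(feats, out / "contours.geojson")

    result.summary_per_cat.to_csv(
        out / "summary_per_cat.csv", index=False, float_format="%.6f"
    )
    pop = pd.DataFrame([result.summary_population])
    pop.to_csv(out / "summary_population.csv", index=False, float_format="%.6f")

    manifest = {
        "config": result.config.to_dict(),
        "n_cats_included": len(result.per_cat),
        "included": sorted(result.per_cat),
        "excluded": dict(sorted(result.excluded.items())),
        "grid": {
            "x_min": float(result.grid.x_min),
            "y_min": float(result.grid.y_min),
            "cell_size": float(result.grid.cell_size),
            "n_cols": int(result.grid.n_cols),
            "n_rows": int(result.grid.n_rows),
            "crs_tag": str(result.grid.crs_tag),
        },
        "written_utc": dt.datetime.now(dt.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
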