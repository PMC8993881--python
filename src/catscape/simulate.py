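"""Synthetic neighbourhood cat populations with known ground truth.

The generator emulates the study design that motivates this package: a
month of high-throughput GPS tracking (one fix attempt every 30 s) of the
pet cats of a small residential neighbourhood, with homes on a jittered
grid inside a rectangular "urban" polygon surrounded by other land cover,
and a minority of households owning two cats.

Movement during outdoor excursions is an Ornstein-Uhlenbeck (OU)
mean-reverting walk anchored at the owner's home, which yields bounded,
home-centred ranges like those of real pet cats; a ``pure_brownian``
switch replaces it with unanchored Brownian motion for exact-model
parameter-recovery tests of the bridge estimator.  Observation error is
additive isotropic Gaussian.  The generator deliberately plants everything
the preprocessing stack must handle: fixes on the first two deployment
days, a data-download day mid-study, occasional EHPE and elevation
outliers, whole missing days, and indoor bouts logged as tight position
clusters inside the home footprint (owners leaving units switched on).

Randomness is split per cat via ``numpy.random.SeedSequence([seed, i])``
so that adding a cat to a population never perturbs the data of existing
cats.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from .geo import LandCover, write_homes, write_landcover
from .raster import GridSpec, UdRaster
from .tracks import StudyCat, Track, write_tracks


@dataclass
class SimConfig:
    """Study conditions for a synthetic cat population.

    Defaults mirror a month-long neighbourhood tracking campaign: 28 study
    days of 30-s fixes, homes ~120 m apart (residential density of roughly
    70 households per km^2), square 10-m building footprints, per-cat
    Brownian motion variances of 5-30 m^2/min, a weak home attraction that
    keeps 95% ranges at the few-hectare scale, 4-12 h outdoors per day, and
    5-m GPS noise with a 2% rate of gross EHPE outliers.
    """

    n_cats: int = 12
    study_days: int = 28
    fix_interval_s: float = 30.0
    home_spacing: float = 120.0  # m, mean nearest-neighbour distance
    home_footprint: float = 10.0  # m, square side
    sigma2_m_range: tuple[float, float] = (5.0, 30.0)  # m^2/min
    attraction_rate: float = 0.005  # 1/min, OU mean reversion toward home
    excursion_hours_per_day_range: tuple[float, float] = (4.0, 12.0)
    indoor_bout_fraction: float = 0.3  # probability a day logs an indoor bout
    gps_error_sd_m: float = 5.0
    ehpe_outlier_rate: float = 0.02
    elevation_base_m: float = 50.0
    elevation_outlier_rate: float = 0.005
    missing_day_prob: float = 0.1
    seed: int = 0
    pure_brownian: bool = False
    two_cat_household_prob: float = 0.18  # ~14 of 76 households with 2 cats
    start_date: dt.date = dt.date(2021, 5, 1)
    download_day: int = 11  # study day whose data are flagged for removal
    tz_offset_hours: float = 2.0

    def __post_init__(self) -> None:
        for name in ("indoor_bout_fraction", "ehpe_outlier_rate",
                     "elevation_outlier_rate", "missing_day_prob",
                     "two_cat_household_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_cats < 1 or self.study_days < 1:
            raise ValueError("need at least one cat and one study day")

    @property
    def download_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=self.download_day)


@dataclass
class CatTruth:
    """Ground truth for one simulated cat."""

    cat_id: str
    home_point: tuple[float, float]
    sigma2_m_per_min: float
    mean_outdoor_hours: float  # scheduled, over days with data
    frac_within_50m: float  # of true outdoor positions
    indoor_indices: list[int]  # row positions of indoor-bout fixes in the track
    n_days_with_data: int
    download_date: dt.date


@dataclass
class SimTruth:
    """Ground truth for a simulated population."""

    cats: dict[str, CatTruth]
    config: SimConfig

    def expected_intensity(self, grid: GridSpec) -> UdRaster:
        """Expected long-run intensity surface of the generating process.

        Under the OU excursion process, a cat's stationary location is
        isotropic Gaussian about its home with per-axis variance
        sigma_m^2 / (2 beta) plus the observation-error variance; the
        population surface is the weight-scaled sum of these kernels.
        Not defined for ``pure_brownian`` (no stationary distribution).
        """
        if self.config.pure_brownian:
            raise ValueError("pure Brownian motion has no stationary intensity")
        beta = self.config.attraction_rate
        gx, gy = grid.center_grids()
        total = np.zeros_like(gx)
        for ct in self.cats.values():
            var = ct.sigma2_m_per_min / (2.0 * beta) + self.config.gps_error_sd_m**2
            w = ct.mean_outdoor_hours / 24.0
            d2 = (gx - ct.home_point[0]) ** 2 + (gy - ct.home_point[1]) ** 2
            total += w * np.exp(-d2 / (2 * var)) / (2 * np.pi * var)
        return UdRaster(grid, total * grid.cell_area, cat_id="population-truth")

    def to_dict(self) -> dict:
        return {
            cid: {
                "home_point": [float(v) for v in ct.home_point],
                "sigma2_m_per_min": float(ct.sigma2_m_per_min),
                "mean_outdoor_hours": float(ct.mean_outdoor_hours),
                "frac_within_50m": float(ct.frac_within_50m),
                "indoor_indices": [int(i) for i in ct.indoor_indices],
                "n_days_with_data": int(ct.n_days_with_data),
                "download_date": ct.download_date.isoformat(),
            }
            for cid, ct in sorted(self.cats.items())
        }


@dataclass
class SimPopulation:
    """A complete synthetic study: data, metadata, land cover, truth."""

    tracks: dict[str, Track]
    cats: dict[str, StudyCat]
    landcover: LandCover
    truth: SimTruth
    config: SimConfig

    def download_dates(self) -> dict[str, list[dt.date]]:
        return {cid: [self.config.download_date] for cid in self.tracks}

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tracks(self.tracks, out / "fixes.csv")
        write_homes(self.cats, out / "homes.geojson")
        write_landcover(self.landcover, out / "landcover.geojson")
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump(self.truth.to_dict(), fh, sort_keys=True)
        meta = {
            "download_dates": {
                cid: [d.isoformat() for d in ds]
                for cid, ds in self.download_dates().items()
            }
        }
        with open(out / "meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# One cat
# ---------------------------------------------------------------------------


def _ou_path(
    rng: np.random.Generator,
    n: int,
    dt_min: float,
    home: np.ndarray,
    sigma2_per_min: float,
    beta_per_min: float,
    start: np.ndarray,
) -> np.ndarray:
    """Exact-discretisation OU sample path anchored at ``home`` (n, 2)."""
    phi = np.exp(-beta_per_min * dt_min)
    step_sd = np.sqrt(sigma2_per_min / (2 * beta_per_min) * (1 - phi * phi))
    out = np.empty((n, 2))
    out[0] = start
    noise = rng.normal(0.0, step_sd, size=(n - 1, 2)) if n > 1 else np.empty((0, 2))
    for i in range(1, n):
        out[i] = home + phi * (out[i - 1] - home) + noise[i - 1]
    return out


def _brownian_path(
    rng: np.random.Generator, n: int, dt_min: float, sigma2_per_min: float, start: np.ndarray
) -> np.ndarray:
    steps = rng.normal(0.0, np.sqrt(sigma2_per_min * dt_min), size=(n - 1, 2))
    return start + np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])


def simulate_cat(
    config: SimConfig,
    cat_index: int,
    home_point: tuple[float, float],
    cat_id: str | None = None,
    sigma2_m_per_min: float | None = None,
) -> tuple[Track, StudyCat, CatTruth]:
    """Simulate one cat's full tracking record.

    The per-cat random stream is ``SeedSequence([config.seed, cat_index])``,
    so each cat's data are reproducible independently of the rest of the
    population.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, cat_index]))
    if cat_id is None:
        cat_id = f"cat{cat_index:03d}"
    home = np.asarray(home_point, dtype=float)
    if sigma2_m_per_min is None:
        sigma2_m_per_min = float(rng.uniform(*config.sigma2_m_range))
    beta = config.attraction_rate
    dt_min = config.fix_interval_s / 60.0
    stat_sd = np.sqrt(sigma2_m_per_min / (2 * beta))

    times: list[dt.datetime] = []
    true_pts: list[np.ndarray] = []
    is_indoor: list[bool] = []
    scheduled_hours: list[float] = []

    e_lo, e_hi = config.excursion_hours_per_day_range
    utc_shift = dt.timedelta(hours=-config.tz_offset_hours)

    for day in range(config.study_days):
        forced = day in (0, 1, config.download_day)
        if not forced and rng.uniform() < config.missing_day_prob:
            continue  # whole tracking day missing
        date = config.start_date + dt.timedelta(days=day)
        hours = float(rng.uniform(e_lo, min(e_hi, 15.9)))
        start_h = float(rng.uniform(6.0, 22.0 - hours))
        n_fix = max(2, int(hours * 3600.0 / config.fix_interval_s))
        t0 = dt.datetime.combine(date, dt.time()) + dt.timedelta(hours=start_h) + utc_shift
        if config.pure_brownian:
            path = _brownian_path(rng, n_fix, dt_min, sigma2_m_per_min, home)
        else:
            start = home + rng.normal(0.0, stat_sd, size=2)
            path = _ou_path(rng, n_fix, dt_min, home, sigma2_m_per_min, beta, start)
        for k in range(n_fix):
            times.append(t0 + dt.timedelta(seconds=k * config.fix_interval_s))
            true_pts.append(path[k])
            is_indoor.append(False)
        scheduled_hours.append(hours)

        if rng.uniform() < config.indoor_bout_fraction:
            bout_min = float(rng.uniform(30.0, 120.0))
            bout_start_h = start_h + hours + float(rng.uniform(0.25, 1.0))
            n_bout = max(2, int(bout_min * 60.0 / config.fix_interval_s))
            b0 = (
                dt.datetime.combine(date, dt.time())
                + dt.timedelta(hours=min(bout_start_h, 23.0))
                + utc_shift
            )
            half = config.home_footprint / 2.0 - 1.0
            jitter = np.clip(rng.normal(0.0, 1.0, size=(n_bout, 2)), -half, half)
            for k in range(n_bout):
                times.append(b0 + dt.timedelta(seconds=k * config.fix_interval_s))
                true_pts.append(home + jitter[k])
                is_indoor.append(True)

    order = np.argsort(np.array(times, dtype="datetime64[us]"), kind="stable")
    times_arr = [times[i] for i in order]
    true_xy = np.array([true_pts[i] for i in order])
    indoor = np.array([is_indoor[i] for i in order])

    n = len(times_arr)
    obs = true_xy + rng.normal(0.0, config.gps_error_sd_m, size=(n, 2))
    # indoor fixes keep their tight 1-m jitter (the unit sits still indoors)
    obs[indoor] = true_xy[indoor]

    ehpe = np.exp(rng.normal(1.0, 0.4, size=n))
    out_mask = rng.uniform(size=n) < config.ehpe_outlier_rate
    ehpe[out_mask] = rng.uniform(5000.0, 20000.0, size=int(out_mask.sum()))
    elev = config.elevation_base_m + rng.normal(0.0, 2.0, size=n)
    bad_elev = rng.uniform(size=n) < config.elevation_outlier_rate
    n_bad = int(bad_elev.sum())
    elev[bad_elev] = np.where(
        rng.uniform(size=n_bad) < 0.5,
        rng.uniform(-50.0, -5.0, size=n_bad),
        rng.uniform(310.0, 500.0, size=n_bad),
    )

    fixes = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(times_arr),
            "x": obs[:, 0],
            "y": obs[:, 1],
            "elevation": elev,
            "ehpe": ehpe,
        }
    )
    track = Track(
        cat_id=cat_id,
        fixes=fixes,
        download_dates={config.download_date},
        crs_tag="local-meters",
        tz_offset_hours=config.tz_offset_hours,
    )

    half_fp = config.home_footprint / 2.0
    cat = StudyCat(
        cat_id=cat_id,
        home_polygon=box(home[0] - half_fp, home[1] - half_fp, home[0] + half_fp, home[1] + half_fp),
        sex="F" if rng.uniform() < 0.5 else "M",
        age_years=float(np.round(rng.uniform(1.0, 12.0), 1)),
        sterilized=True,
    )

    outdoor_true = true_xy[~indoor]
    d = np.hypot(outdoor_true[:, 0] - home[0], outdoor_true[:, 1] - home[1])
    truth = CatTruth(
        cat_id=cat_id,
        home_point=(float(home[0]), float(home[1])),
        sigma2_m_per_min=sigma2_m_per_min,
        mean_outdoor_hours=float(np.mean(scheduled_hours)),
        frac_within_50m=float(np.mean(d <= 50.0)),
        indoor_indices=[int(i) for i in np.flatnonzero(indoor)],
        n_days_with_data=len(scheduled_hours),
        download_date=config.download_date,
    )
    return track, cat, truth


# ---------------------------------------------------------------------------
# A population
# ---------------------------------------------------------------------------


def simulate_population(config: SimConfig | None = None, out_dir=None) -> SimPopulation:
    """Simulate a neighbourhood of cats; optionally write all input files.

    Homes sit on a jittered grid inside a rectangular urban polygon
    surrounded by "other" land cover; a fraction of households hosts two
    cats.  The outputs (``fixes.csv``, ``homes.geojson``,
    ``landcover.geojson``, ``meta.yaml``, ``truth.yaml``) are directly
    consumable by the pipeline.
    """
    if config is None:
        config = SimConfig()
    struct_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 999_983]))

    # household structure: some homes host two cats.  The assignment loop is
    # prefix-stable (one draw per household, in order), and each household's
    # home jitter uses its own seed stream, so adding cats to a config never
    # perturbs the homes or data of existing cats.
    household_of: list[int] = []
    hh = 0
    i = 0
    while i < config.n_cats:
        take = (
            2
            if (struct_rng.uniform() < config.two_cat_household_prob and i + 1 < config.n_cats)
            else 1
        )
        household_of.extend([hh] * take)
        i += take
        hh += 1
    n_house = hh

    n_cols = int(np.ceil(np.sqrt(n_house)))
    sp = config.home_spacing
    centers = []
    for h in range(n_house):
        r, c = divmod(h, n_cols)
        h_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 500_000 + h]))
        jitter = h_rng.uniform(-sp / 4.0, sp / 4.0, size=2)
        centers.append(np.array([c * sp, r * sp]) + jitter)

    tracks: dict[str, Track] = {}
    cats: dict[str, StudyCat] = {}
    truths: dict[str, CatTruth] = {}
    for idx in range(config.n_cats):
        home = centers[household_of[idx]]
        track, cat, truth = simulate_cat(config, idx, (home[0], home[1]))
        tracks[track.cat_id] = track
        cats[cat.cat_id] = cat
        truths[truth.cat_id] = truth

    xs = np.array([c[0] for c in centers])
    ys = np.array([c[1] for c in centers])
    urban = box(xs.min() - 60.0, ys.min() - 60.0, xs.max() + 60.0, ys.max() + 60.0)
    outer = box(xs.min() - 1000.0, ys.min() - 1000.0, xs.max() + 1000.0, ys.max() + 1000.0)
    landcover = LandCover(
        classes={"urban": urban, "other": outer.difference(urban)},
        developed_classes=("urban", "developed"),
    )

    pop = SimPopulation(
        tracks=tracks,
        cats=cats,
        landcover=landcover,
        truth=SimTruth(cats=truths, config=config),
        config=config,
    )
    if out_dir is not None:
        pop.write(out_dir)
    return pop


def simulate_brownian_track(
    sigma2_m_per_min: float,
    location_error: float,
    n_fixes: int,
    interval_s: float,
    seed: int,
    cat_id: str = "bm",
) -> Track:
    """Pure 2-D Brownian motion observed with Gaussian error.

    Exactly the generating model assumed by the bridge likelihood; used for
    parameter-recovery checks of the motion-variance estimator.
    """
    rng = np.random.default_rng(seed)
    true = _brownian_path(rng, n_fixes, interval_s / 60.0, sigma2_m_per_min, np.zeros(2))
    obs = true + rng.normal(0.0, location_error, size=(n_fixes, 2))
    t0 = dt.datetime(2021, 5, 3, 6, 0, 0)
    times = [t0 + dt.timedelta(seconds=k * interval_s) for k in range(n_fixes)]
    fixes = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(times),
            "x": obs[:, 0],
            "y": obs[:, 1],
            "elevation": 50.0,
            "ehpe": 3.0,
        }
    )
    return Track(cat_id=cat_id, fixes=fixes, tz_offset_hours=0.0)


# ---------------------------------------------------------------------------
# Deterministic small fixtures for exact filter / excision checks
# ---------------------------------------------------------------------------


def make_filter_fixture(seed: int = 0) -> tuple[Track, dict[str, int]]:
    """A 200-fix track with planted, mutually exclusive filter violations.

    Returns the track and the exact removal counts each preprocessing rule
    must produce when applied in the standard order, plus the number of
    fixes the 2-min greedy thinning retains.  Violations are planted in
    disjoint time blocks so every count is determined by construction.
    """
    rng = np.random.default_rng(seed)
    base = dt.datetime(2021, 5, 1, 10, 0, 0)
    rows = []

    def block(day: int, hour: float, n: int, spacing_s: float, elevation=50.0, ehpe=3.0):
        t0 = base.replace(hour=0) + dt.timedelta(days=day, hours=hour)
        for k in range(n):
            rows.append(
                {
                    "timestamp": t0 + dt.timedelta(seconds=k * spacing_s),
                    "x": float(rng.normal(0.0, 30.0)),
                    "y": float(rng.normal(0.0, 30.0)),
                    "elevation": elevation,
                    "ehpe": ehpe,
                }
            )

    block(0, 10.0, 15, 120.0)            # first-days violations (day 0)
    block(1, 10.0, 15, 120.0)            # first-days violations (day 1)
    block(5, 10.0, 20, 120.0)            # download-day violations
    block(3, 14.0, 7, 30.0, elevation=-5.0)   # elevation violations
    block(4, 15.0, 9, 30.0, ehpe=7500.0)      # EHPE violations
    block(3, 10.0, 50, 30.0)             # clean 30-s data -> thinning work
    block(4, 10.0, 50, 30.0)
    block(6, 10.0, 34, 30.0)

    fixes = pd.DataFrame(rows)
    track = Track(
        cat_id="fixture",
        fixes=fixes,
        deployment_start=dt.date(2021, 5, 1),
        download_dates={dt.date(2021, 5, 6)},
        tz_offset_hours=0.0,
    )
    assert track.n_fixes == 200
    # 30-s blocks of m fixes thin to floor((m-1)/4) + 1 under the greedy rule
    thin_kept = ((50 - 1) // 4 + 1) * 2 + ((34 - 1) // 4 + 1)
    counts = {
        "total": 200,
        "elevation": 7,
        "first_days": 30,
        "download": 20,
        "ehpe": 9,
        "clean": 134,
        "thin_kept": thin_kept,
    }
    return track, counts


def make_indoor_fixture(seed: int = 0) -> tuple[Track, StudyCat, np.ndarray]:
    """A track with two planted indoor bouts and a separable outdoor transect.

    Outdoor fixes march outward in 15-m steps, so no two lie within the
    10-m cluster radius of each other or of the home-cluster centroid;
    indoor fixes jitter within 1 m of the home centre.  Exact excision of
    the planted indoor fixes is therefore determined by construction.
    Returns the track, the cat metadata and the indoor row indices.
    """
    rng = np.random.default_rng(seed)
    base = dt.datetime(2021, 5, 4, 0, 0, 0)
    rows = []
    indoor_flags = []

    def indoor_bout(hour: float, n: int):
        t0 = base + dt.timedelta(hours=hour)
        jit = np.clip(rng.normal(0.0, 1.0, size=(n, 2)), -4.0, 4.0)
        for k in range(n):
            rows.append(
                {
                    "timestamp": t0 + dt.timedelta(seconds=30.0 * k),
                    "x": float(jit[k, 0]),
                    "y": float(jit[k, 1]),
                    "elevation": 50.0,
                    "ehpe": 3.0,
                }
            )
            indoor_flags.append(True)

    indoor_bout(8.0, 25)
    t0 = base + dt.timedelta(hours=10.0)
    for k in range(60):
        rows.append(
            {
                "timestamp": t0 + dt.timedelta(seconds=30.0 * k),
                "x": 30.0 + 15.0 * k + float(rng.normal(0.0, 0.5)),
                "y": float(rng.normal(0.0, 0.5)),
                "elevation": 50.0,
                "ehpe": 3.0,
            }
        )
        indoor_flags.append(False)
    indoor_bout(13.0, 25)

    fixes = pd.DataFrame(rows)
    track = Track(cat_id="fixture", fixes=fixes, tz_offset_hours=0.0)
    cat = StudyCat(cat_id="fixture", home_polygon=box(-5.0, -5.0, 5.0, 5.0))
    return track, cat, np.flatnonzero(np.array(indoor_flags))
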