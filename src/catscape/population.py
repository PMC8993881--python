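"""Population-level utilization surface ("catscape") and spatial summaries.

Individual utilization distributions are (1) resampled onto a shared grid,
(2) re-scaled so each sums to the cat's outdoor weight w — the mean
fraction of a 24-h day the cat was tracked outdoors on days with data —
and (3) summed cell-wise across cats.  The result is deliberately NOT
renormalised: its total equals the sum of the weights, so surfaces are
comparable between populations and time slices in both magnitude and shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Point

from .bbmm import volume_contour
from .geo import LandCover
from .raster import GridSpec, UdRaster, contour_mask, resample_mass
from .tracks import OutdoorWeight, Track


@dataclass
class Catscape:
    """Summed, weighted population utilization surface with provenance."""

    raster: UdRaster
    weights: dict[str, float]
    grid: GridSpec = field(init=False)

    def __post_init__(self) -> None:
        self.grid = self.raster.grid
        if any(w < 0 or w > 1 for w in self.weights.values()):
            raise ValueError("all outdoor weights must lie in [0, 1]")

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights.values()))

    @property
    def cat_ids(self) -> list[str]:
        return sorted(self.weights)

    def normalized(self) -> UdRaster:
        return self.raster.normalized()

    def plot(self, ax=None, **kwargs):
        return self.raster.plot(ax=ax, **kwargs)


@dataclass(frozen=True)
class DistanceStats:
    """Per-cat summary of fix distances to the owner's home."""

    cat_id: str
    mean_m: float
    max_m: float
    frac_within: float
    radius: float
    n_fixes: int


# ---------------------------------------------------------------------------
# The three aggregation steps
# ---------------------------------------------------------------------------


def align_rasters(uds: Iterable[UdRaster], template: GridSpec) -> list[UdRaster]:
    """Step 1: conservative resampling of every UD onto the template grid."""
    return [resample_mass(ud, template) for ud in uds]


def weight_ud(ud: UdRaster, w: OutdoorWeight | float) -> UdRaster:
    """Step 2: re-scale a unit-mass UD to sum to the outdoor weight."""
    wv = w.w if isinstance(w, OutdoorWeight) else float(w)
    if not 0.0 <= wv <= 1.0:
        raise ValueError("outdoor weight must lie in [0, 1]")
    return UdRaster(ud.grid, ud.values * wv, ud.cat_id)


def aggregate(weighted_uds: Sequence[UdRaster], weights: Mapping[str, float]) -> Catscape:
    """Step 3: cell-wise sum of the weighted UD stack (no renormalisation)."""
    if not weighted_uds:
        raise ValueError("nothing to aggregate")
    grid = weighted_uds[0].grid
    for ud in weighted_uds[1:]:
        if ud.grid != grid:
            raise ValueError("all rasters must share one grid; align first")
    total = np.zeros_like(weighted_uds[0].values)
    for ud in weighted_uds:
        total = total + ud.values
    return Catscape(
        raster=UdRaster(grid, total, cat_id="population"), weights=dict(weights)
    )


def build_catscape(
    uds: Mapping[str, UdRaster],
    weights: Mapping[str, OutdoorWeight | float],
    template: GridSpec,
) -> Catscape:
    """All three steps: align, weight, sum."""
    wvals = {
        cid: (w.w if isinstance(w, OutdoorWeight) else float(w)) for cid, w in weights.items()
    }
    weighted = [
        weight_ud(resample_mass(uds[cid], template), wvals[cid]) for cid in sorted(uds)
    ]
    return aggregate(weighted, wvals)


# ---------------------------------------------------------------------------
# Spatial summary statistics
# ---------------------------------------------------------------------------


def intensity_fold_range(cs: Catscape, level: float = 0.99) -> float:
    """Max/min cell-intensity ratio within the catscape's level contour.

    The contour is taken on the normalised surface; the ratio uses the raw
    intensities of the positive cells inside it.  A flat surface gives 1.
    """
    if cs.raster.total <= 0:
        raise ValueError("catscape is empty")
    mask = contour_mask(cs.raster.values / cs.raster.total, level)
    vals = cs.raster.values[mask]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("no positive cells inside the contour")
    return float(vals.max() / vals.min())


def near_home_intensity_ratio(
    cs: Catscape,
    homes: Sequence[tuple[float, float]],
    r1: float = 50.0,
    r2: float = 100.0,
) -> float:
    """Mean intensity within r1 of any home vs the (r1, r2] annulus.

    Zones are defined by cell-center distance to the nearest home; means are
    per-cell (per unit area) so zones of different size are comparable.
    """
    if not len(homes):
        raise ValueError("at least one home is required")
    gx, gy = cs.grid.center_grids()
    h = np.asarray(homes, dtype=float)
    d2 = np.min(
        (gx[..., None] - h[:, 0]) ** 2 + (gy[..., None] - h[:, 1]) ** 2, axis=-1
    )
    near = d2 <= r1**2
    annulus = (d2 > r1**2) & (d2 <= r2**2)
    if not annulus.any() or not near.any():
        raise ValueError("empty near-home zone or annulus on this grid")
    denom = float(cs.raster.values[annulus].mean())
    numer = float(cs.raster.values[near].mean())
    if denom == 0:
        return float("inf")
    return numer / denom


def distance_stats(
    track: Track, home_point: tuple[float, float], radius: float = 50.0
) -> DistanceStats:
    """Distance-to-home summary for an outdoor-only track.

    The fraction of fixes within ``radius`` serves as the fraction of
    outdoor time near home: at a near-constant fix interval, fixes are an
    (approximately) uniform sample of tracked time.
    """
    if track.n_fixes == 0:
        raise ValueError("empty track")
    xy = track.xy()
    d = np.hypot(xy[:, 0] - home_point[0], xy[:, 1] - home_point[1])
    return DistanceStats(
        cat_id=track.cat_id,
        mean_m=float(d.mean()),
        max_m=float(d.max()),
        frac_within=float(np.mean(d <= radius)),
        radius=radius,
        n_fixes=len(d),
    )


def landcover_partition(
    cs: Catscape | UdRaster, lc: LandCover, level: float = 0.99
) -> tuple[float, float]:
    """Share of the catscape's contour area and intensity outside developed land.

    Returns ``(fraction_area_outside, fraction_intensity_outside)`` where
    the area fraction is over cells of the ``level`` volume contour (by
    cell-center point-in-polygon against the developed classes) and the
    intensity fraction is those outside-cells' intensity over the surface's
    total intensity.
    """
    raster = cs.raster if isinstance(cs, Catscape) else cs
    if raster.total <= 0:
        raise ValueError("empty surface")
    developed = lc.developed_geometry()
    if not developed.is_valid:
        raise ValueError("invalid developed-land geometry")
    mask = contour_mask(raster.values / raster.total, level)
    gx, gy = raster.grid.center_grids()
    pts = shapely.points(gx[mask], gy[mask])
    shapely.prepare(developed)
    inside = shapely.intersects(developed, pts)  # covers boundary cells as developed
    n_contour = int(mask.sum())
    outside_mask_vals = raster.values[mask][~inside]
    frac_area = float(np.sum(~inside) / n_contour)
    frac_intensity = float(outside_mask_vals.sum() / raster.values.sum())
    return frac_area, frac_intensity


def range_nonurban_fraction(ud: UdRaster, lc: LandCover, level: float = 0.95) -> float:
    """Fraction of an individual home range's area outside developed land."""
    frac_area, _ = landcover_partition(ud, lc, level=level)
    return frac_area


def catscape_contour(cs: Catscape, level: float = 0.99):
    """Volume contour of the normalised catscape (area in hectares)."""
    return volume_contour(cs.normalized(), level)
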