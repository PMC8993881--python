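"""Sequential position-cluster detection and indoor-activity excision.

GPS units left powered on indoors log long bouts of near-stationary fixes.
These appear as *sequential position clusters*: runs of fixes, close in time
and within a small radius of one another, whose centroid sits on the
owner's residence.  Detecting such clusters and removing every fix that
belongs to a cluster whose centroid falls within the home's building
footprint leaves a track that can be treated as purely outdoor activity.

The detector is a single time-ordered scan with a running centroid:

* a candidate cluster opens when a fix lies within ``radius`` of an earlier,
  still-unclustered fix logged within ``window``;
* later fixes join an open cluster when they lie within ``radius`` of its
  running centroid (recomputed after every addition) and within ``window``
  of the cluster's most recent member;
* a cluster closes once ``window`` elapses without an addition;
* clusters with fewer than ``min_points`` members are discarded, and no fix
  belongs to more than one cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .tracks import Track


@dataclass
class PositionCluster:
    """A sequential cluster of fixes with its centroid and membership."""

    cluster_id: int
    cat_id: str
    member_indices: np.ndarray  # positional indices into the track's fix sequence
    centroid: tuple[float, float]
    start_time: pd.Timestamp
    end_time: pd.Timestamp

    @property
    def n_members(self) -> int:
        return len(self.member_indices)


class _OpenCluster:
    __slots__ = ("members", "sx", "sy", "last_t")

    def __init__(self, i: int, j: int, xy: np.ndarray, t: np.ndarray):
        self.members = [j, i]
        self.sx = xy[i, 0] + xy[j, 0]
        self.sy = xy[i, 1] + xy[j, 1]
        self.last_t = t[i]

    def centroid(self) -> tuple[float, float]:
        n = len(self.members)
        return self.sx / n, self.sy / n

    def add(self, i: int, xy: np.ndarray, t: np.ndarray) -> None:
        self.members.append(i)
        self.sx += xy[i, 0]
        self.sy += xy[i, 1]
        self.last_t = t[i]


def find_sequential_clusters(
    track: Track,
    radius: float = 10.0,
    window: float = 24 * 3600.0,
    min_points: int = 2,
) -> list[PositionCluster]:
    """Detect sequential position clusters in a time-ordered track.

    Parameters
    ----------
    track : Track
        Time-ordered fixes.
    radius : float
        Spatial radius in meters; the default 10 m mirrors the reported GPS
        error below which stationary fixes are indistinguishable.
    window : float
        Maximum time (seconds) between a fix and the cluster's most recent
        member (or, when opening, the earlier partner fix).
    min_points : int
        Minimum cluster size retained.
    """
    n = track.n_fixes
    if n == 0:
        return []
    xy = track.xy()
    t = track.times_s()
    assigned = np.zeros(n, dtype=bool)

    open_clusters: list[_OpenCluster] = []
    closed: list[_OpenCluster] = []
    r2 = radius * radius
    lo = 0  # left edge of the time window among candidate partner fixes

    for i in range(n):
        # retire clusters that have gone quiet for longer than the window
        if open_clusters:
            still = []
            for c in open_clusters:
                (closed if t[i] - c.last_t > window else still).append(c)
            open_clusters = still

        # join the most recently active open cluster whose centroid is close
        joined = False
        for c in sorted(open_clusters, key=lambda c: -c.last_t):
            cx, cy = c.centroid()
            if (xy[i, 0] - cx) ** 2 + (xy[i, 1] - cy) ** 2 <= r2:
                c.add(i, xy, t)
                assigned[i] = True
                joined = True
                break
        if joined:
            continue

        # otherwise try to open a new cluster with the most recent
        # unclustered fix within the window and radius
        while lo < i and t[i] - t[lo] > window:
            lo += 1
        cand = np.flatnonzero(~assigned[lo:i]) + lo
        if cand.size:
            d2 = (xy[cand, 0] - xy[i, 0]) ** 2 + (xy[cand, 1] - xy[i, 1]) ** 2
            hits = cand[d2 <= r2]
            if hits.size:
                j = int(hits[-1])  # most recent partner
                open_clusters.append(_OpenCluster(i, j, xy, t))
                assigned[i] = assigned[j] = True

    closed.extend(open_clusters)

    timestamps = track.fixes["timestamp"]
    clusters: list[PositionCluster] = []
    cid = 0
    for c in sorted(closed, key=lambda c: c.members[0]):
        if len(c.members) < min_points:
            continue
        members = np.array(sorted(c.members), dtype=int)
        clusters.append(
            PositionCluster(
                cluster_id=cid,
                cat_id=track.cat_id,
                member_indices=members,
                centroid=c.centroid(),
                start_time=timestamps.iloc[members[0]],
                end_time=timestamps.iloc[members[-1]],
            )
        )
        cid += 1
    return clusters


def remove_home_clusters(
    track: Track, clusters: list[PositionCluster], home_polygon
) -> Track:
    """Excise every fix belonging to a cluster centred on the home footprint.

    A cluster is "home" when its centroid lies inside or on the boundary of
    ``home_polygon``.  Fixes outside home clusters are untouched; the
    returned track preserves time ordering.  Idempotent.
    """
    if home_polygon is None or not home_polygon.is_valid or home_polygon.is_empty:
        raise ValueError("home polygon must be a valid, non-empty polygon")
    drop: set[int] = set()
    for cl in clusters:
        if home_polygon.covers(Point(*cl.centroid)):
            drop.update(int(i) for i in cl.member_indices)
    if not drop:
        return track
    keep = np.ones(track.n_fixes, dtype=bool)
    keep[list(drop)] = False
    return track._replace_fixes(keep)


def declutter_track(
    track: Track,
    home_polygon,
    radius: float = 10.0,
    window: float = 24 * 3600.0,
    min_points: int = 2,
) -> tuple[Track, list[PositionCluster]]:
    """Convenience: detect clusters and excise the home-centred ones."""
    clusters = find_sequential_clusters(track, radius=radius, window=window, min_points=min_points)
    return remove_home_clusters(track, clusters, home_polygon), clusters
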