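"""Plain-GeoJSON vector I/O (shapely-backed) for homes and land cover."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .tracks import StudyCat


@dataclass
class LandCover:
    """Named land-cover classes as (multi)polygons.

    ``developed_classes`` lists the class names treated as "urban and other
    developed areas" by the landscape partition statistics; cells outside
    every listed class count as "other".
    """

    classes: dict[str, BaseGeometry]
    developed_classes: tuple[str, ...] = ("urban", "developed")

    def developed_geometry(self) -> BaseGeometry:
        geoms = [g for name, g in self.classes.items() if name in self.developed_classes]
        if not geoms:
            raise ValueError(
                f"no land-cover class among {self.developed_classes!r} present "
                f"(have: {sorted(self.classes)})"
            )
        return unary_union(geoms)


def feature_collection(features: Iterable[dict]) -> dict:
    return {"type": "FeatureCollection", "features": list(features)}


def geometry_feature(geom: BaseGeometry, properties: Mapping | None = None) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": dict(properties or {})}


def write_geojson(features: Iterable[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(feature_collection(features), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_homes(path) -> dict[str, StudyCat]:
    """Read a building-footprint GeoJSON into :class:`StudyCat` per cat.

    Each feature must be a polygon with a ``cat_id`` property; optional
    properties ``sex``, ``age_years`` and ``sterilized`` are carried through.
    """
    with open(path) as fh:
        fc = json.load(fh)
    cats: dict[str, StudyCat] = {}
    for feat in fc.get("features", []):
        props = feat.get("properties") or {}
        cat_id = str(props["cat_id"])
        cats[cat_id] = StudyCat(
            cat_id=cat_id,
            home_polygon=shape(feat["geometry"]),
            sex=props.get("sex", "unknown"),
            age_years=props.get("age_years"),
            sterilized=props.get("sterilized"),
        )
    return cats


def write_homes(cats: Mapping[str, StudyCat], path) -> None:
    feats = []
    for cat_id in sorted(cats):
        c = cats[cat_id]
        props = {"cat_id": c.cat_id, "sex": c.sex}
        if c.age_years is not None:
            props["age_years"] = c.age_years
        if c.sterilized is not None:
            props["sterilized"] = c.sterilized
        feats.append(geometry_feature(c.home_polygon, props))
    write_geojson(feats, path)


def read_landcover(path, developed_classes: tuple[str, ...] = ("urban", "developed")) -> LandCover:
    """Read land-cover polygons from GeoJSON (property ``class`` per feature).

    Multiple features sharing a class name are unioned.
    """
    with open(path) as fh:
        fc = json.load(fh)
    classes: dict[str, list[BaseGeometry]] = {}
    for feat in fc.get("features", []):
        name = str((feat.get("properties") or {}).get("class", "other"))
        classes.setdefault(name, []).append(shape(feat["geometry"]))
    merged = {name: unary_union(geoms) for name, geoms in classes.items()}
    return LandCover(classes=merged, developed_classes=developed_classes)


def write_landcover(lc: LandCover, path) -> None:
    feats = [
        geometry_feature(geom, {"class": name}) for name, geom in sorted(lc.classes.items())
    ]
    write_geojson(feats, path)
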