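"""Spatial units and attribute join for choropleth export.

Geometries are read from and written to GeoJSON (the text-based exchange
format); coordinates and CRS pass through untouched — the tool computes no
areas or distances, so no reprojection is attempted.  Area ids are compared
as trimmed, case-sensitive text.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .aggregate import SVIResult
from .errors import GeometryError, JoinError, UnsupportedFormatError

__all__ = ["SpatialUnits", "JoinReport", "read_geometry", "join_and_export"]

_GEOJSON_SUFFIXES = {".geojson", ".json"}


@dataclass(frozen=True)
class SpatialUnits:
    area_ids: tuple[str, ...]
    geometries: tuple[BaseGeometry, ...]
    crs: object | None = None  # GeoJSON crs member, passed through verbatim

    def __post_init__(self) -> None:
        if len(self.area_ids) != len(self.geometries):
            raise GeometryError("area_ids and geometries differ in length")
        if len(set(self.area_ids)) != len(self.area_ids):
            dupes = sorted(
                {a for a in self.area_ids if self.area_ids.count(a) > 1}
            )
            raise GeometryError(f"duplicate area ids in geometry: {dupes}")


@dataclass(frozen=True)
class JoinReport:
    matched_ids: tuple[str, ...]
    unmatched_table_ids: tuple[str, ...]
    unmatched_geometry_ids: tuple[str, ...]


def _ensure_geojson(path) -> Path:
    p = Path(path)
    if p.suffix.lower() not in _GEOJSON_SUFFIXES:
        raise UnsupportedFormatError(
            f"unsupported spatial format {p.suffix!r}: this build reads and "
            "writes GeoJSON only (convert GeoPackage/Shapefile with e.g. ogr2ogr)"
        )
    return p


def read_geometry(path, id_field: str, *, repair: bool = True) -> SpatialUnits:
    """Read a GeoJSON FeatureCollection into SpatialUnits.

    ``id_field`` names the feature property holding the area id (ids are
    coerced to trimmed text).  Invalid geometries are repaired with
    ``make_valid`` when ``repair`` is on, otherwise rejected.
    """
    p = _ensure_geojson(path)
    try:
        with open(p, encoding="utf-8") as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise GeometryError(f"cannot read {p}: {exc}")
    if doc.get("type") != "FeatureCollection":
        raise GeometryError(f"{p} is not a GeoJSON FeatureCollection")
    ids: list[str] = []
    geoms: list[BaseGeometry] = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        if id_field not in props:
            raise GeometryError(
                f"feature {i} has no property {id_field!r}; "
                f"available: {sorted(props)}"
            )
        geom = shape(feat["geometry"])
        if geom.is_empty:
            raise GeometryError(f"feature {props[id_field]!r} has an empty geometry")
        if not geom.is_valid:
            if repair:
                geom = make_valid(geom)
            else:
                raise GeometryError(
                    f"feature {props[id_field]!r} has an invalid geometry"
                )
        ids.append(str(props[id_field]).strip())
        geoms.append(geom)
    return SpatialUnits(
        area_ids=tuple(ids), geometries=tuple(geoms), crs=doc.get("crs")
    )


def _jsonable(v):
    if isinstance(v, float) and math.isnan(v):
        return None
    if hasattr(v, "item"):
        return v.item()
    return v


def join_and_export(
    result: SVIResult, units: SpatialUnits, out_path, format: str = "geojson"
) -> JoinReport:
    """Join SVI results onto geometries by area id and write a GeoJSON layer.

    Each matched feature carries the area id, SVI, class, tier, dimension and
    domain scores.  Unmatched ids on either side are reported, never silently
    dropped; zero overlap is an error.
    """
    if format.lower() != "geojson":
        raise UnsupportedFormatError(
            f"unsupported export format {format!r}: this build writes GeoJSON only"
        )
    table = result.to_frame()
    table_ids = [str(a).strip() for a in table.index]
    table.index = pd.Index(table_ids)
    geo_ids = list(units.area_ids)
    matched = [g for g in geo_ids if g in set(table_ids)]
    if not matched:
        raise JoinError(
            "no overlap between result area ids and geometry area ids"
        )
    unmatched_table = tuple(t for t in table_ids if t not in set(geo_ids))
    unmatched_geo = tuple(g for g in geo_ids if g not in set(table_ids))
    features = []
    drop_cols = [c for c in table.columns if c.startswith("z__")]
    attrs = table.drop(columns=drop_cols)
    for aid, geom in zip(units.area_ids, units.geometries):
        if aid not in set(matched):
            continue
        props = {"area_id": aid}
        props.update(
            {k: _jsonable(v) for k, v in attrs.loc[aid].items()}
        )
        props["svi_class"] = str(props["svi_class"])
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
        )
    doc: dict = {"type": "FeatureCollection", "features": features}
    if units.crs is not None:
        doc["crs"] = units.crs
    out = _ensure_geojson(out_path)
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return JoinReport(
        matched_ids=tuple(matched),
        unmatched_table_ids=unmatched_table,
        unmatched_geometry_ids=unmatched_geo,
    )
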