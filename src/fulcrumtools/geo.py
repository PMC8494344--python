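"""Point-in-polygon annotation of collection sites with named features.

Users supply named polygons (islands, trails, parks, mountains) as a
GeoJSON FeatureCollection; each collection's final location is tested for
containment and the matching feature names are added to the table. The
containment test is an even–odd ray cast in WGS84 decimal degrees with a
boundary-inclusive rule — a sample taken on a trail edge belongs to the
trail. Holes in a polygon exclude points; antimeridian-crossing polygons
are not supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidFeatureError

Ring = list[tuple[float, float]]  # (lon, lat) vertices


@dataclass
class GeoFeature:
    """One named geographic feature: exterior ring(s) plus optional holes."""

    name: str
    # each polygon is (exterior ring, [hole rings]); a MultiPolygon has several
    polygons: list[tuple[Ring, list[Ring]]]
    attributes: dict = field(default_factory=dict)


def _close_ring(ring: Ring) -> Ring:
    ring = [(float(x), float(y)) for x, y in ring]
    if ring and ring[0] != ring[-1]:
        ring = ring + [ring[0]]
    if len(set(ring[:-1])) < 3:
        raise InvalidFeatureError("ring has fewer than 3 distinct vertices")
    for x, y in ring:
        if not (-180.0 <= x <= 180.0 and -90.0 <= y <= 90.0):
            raise InvalidFeatureError(f"vertex ({x}, {y}) outside WGS84 bounds")
    return ring


def _on_segment(px, py, ax, ay, bx, by, eps=1e-12) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    scale = max(abs(bx - ax), abs(by - ay), 1.0)
    if abs(cross) > eps * scale:
        return False
    return min(ax, bx) - eps <= px <= max(ax, bx) + eps and (
        min(ay, by) - eps <= py <= max(ay, by) + eps
    )


def _ray_cast(px: float, py: float, ring: Ring) -> bool:
    """Even–odd rule with boundary points counted inside."""
    inside = False
    n = len(ring)
    for i in range(n - 1):
        ax, ay = ring[i]
        bx, by = ring[i + 1]
        if _on_segment(px, py, ax, ay, bx, by):
            return True
        # edge crosses the horizontal ray to the right of the point
        if (ay > py) != (by > py):
            x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
            if x_cross > px:
                inside = not inside
    return inside


def point_in_feature(lon: float, lat: float, feature: GeoFeature) -> bool:
    """True if (lon, lat) lies inside the feature (boundary inclusive).

    A point inside a hole is outside, unless it lies exactly on the hole's
    boundary (boundary points always count as belonging to the feature).
    """
    for exterior, holes in feature.polygons:
        if not _ray_cast(lon, lat, exterior):
            continue
        on_exterior_boundary = any(
            _on_segment(lon, lat, *exterior[i], *exterior[i + 1])
            for i in range(len(exterior) - 1)
        )
        if on_exterior_boundary:
            return True
        in_hole = False
        for hole in holes:
            on_hole_boundary = any(
                _on_segment(lon, lat, *hole[i], *hole[i + 1])
                for i in range(len(hole) - 1)
            )
            if on_hole_boundary:
                return True
            if _ray_cast(lon, lat, hole):
                in_hole = True
                break
        if not in_hole:
            return True
    return False


def load_features(path: Path | str) -> list[GeoFeature]:
    """Load named polygon features from a GeoJSON FeatureCollection (RFC 7946).

    Polygon and MultiPolygon geometries are supported; other geometry types
    are skipped with a warning attribute. Every feature must carry a ``name``
    property.
    """
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    raw_features = (
        data["features"] if data.get("type") == "FeatureCollection" else [data]
    )
    features: list[GeoFeature] = []
    for feat in raw_features:
        props = feat.get("properties") or {}
        if "name" not in props or props["name"] in (None, ""):
            raise InvalidFeatureError("GeoJSON feature lacks a 'name' property")
        geom = feat.get("geometry") or {}
        gtype = geom.get("type")
        if gtype == "Polygon":
            polys = [geom["coordinates"]]
        elif gtype == "MultiPolygon":
            polys = geom["coordinates"]
        else:
            continue  # non-polygon geometry: skipped
        polygons = []
        for rings in polys:
            exterior = _close_ring(rings[0])
            holes = [_close_ring(r) for r in rings[1:]]
            polygons.append((exterior, holes))
        features.append(GeoFeature(name=str(props["name"]), polygons=polygons, attributes=props))
    return features


def annotate_fulcrum(
    joined: pd.DataFrame, features: list[GeoFeature] | Path | str | None
) -> pd.DataFrame:
    """Add ``location`` / ``locations_all`` columns from feature containment.

    ``location`` is the first matching feature in file order (null when no
    match or no resolvable location); ``locations_all`` joins every match
    with semicolons. Row count is preserved; the input is not mutated.
    """
    if isinstance(features, (str, Path)):
        features = load_features(features)
    features = features or []
    out = joined.copy()
    first: list = []
    all_: list = []
    for lat, lon in zip(out["latitude"], out["longitude"]):
        if pd.isna(lat) or pd.isna(lon) or not features:
            first.append(np.nan)
            all_.append(np.nan)
            continue
        hits = [f.name for f in features if point_in_feature(float(lon), float(lat), f)]
        first.append(hits[0] if hits else np.nan)
        all_.append(";".join(hits) if hits else np.nan)
    out["location"] = first
    out["locations_all"] = all_
    return out
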