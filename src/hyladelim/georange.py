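"""Extent of occurrence and Red List suggestion heuristic.

Geographic range is estimated as the minimum convex polygon (MCP) of the
occurrence points. Area is computed on the WGS84 authalic sphere with the
spherical polygon-area formula (an equal-area treatment of the spheroid,
honest to well under 1% at continental extents), or in plain planar units
for projected/toy coordinates. The degraded-habitat fraction is simple
exact arithmetic on user-supplied areas; the Red List suggestion is a
deliberately minimal, advisory heuristic around the IUCN criterion B1
extent-of-occurrence bound.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

__all__ = [
    "AUTHALIC_RADIUS_KM",
    "OccurrenceSet",
    "RangeReport",
    "read_occurrences",
    "mcp_area_km2",
    "degraded_percent",
    "redlist_suggest",
    "assess_range",
]

#: radius of the sphere with the same surface area as the WGS84 ellipsoid
AUTHALIC_RADIUS_KM = 6371.0071810


@dataclass(frozen=True)
class OccurrenceSet:
    """Occurrence points: (longitude, latitude) in WGS84 decimal degrees."""

    points: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("points must be a (n, 2) array of lon/lat")
        if np.any(~np.isfinite(pts)):
            raise ValueError("coordinates must be finite")
        if np.any(np.abs(pts[:, 0]) > 180) or np.any(np.abs(pts[:, 1]) > 90):
            raise ValueError("lon must be in [-180, 180], lat in [-90, 90]")
        object.__setattr__(self, "points", pts)

    @property
    def n_localities(self) -> int:
        return len(np.unique(self.points, axis=0))


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read a delimited lon/lat table (columns ``lon``/``lat`` or the first
    two numeric columns)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "lon" in cols and "lat" in cols:
        pts = df[[cols["lon"], cols["lat"]]].to_numpy(dtype=float)
    elif "longitude" in cols and "latitude" in cols:
        pts = df[[cols["longitude"], cols["latitude"]]].to_numpy(dtype=float)
    else:
        pts = df.iloc[:, :2].to_numpy(dtype=float)
    labels = None
    for name in ("locality", "label", "site"):
        if name in cols:
            labels = tuple(df[cols[name]].astype(str))
            break
    return OccurrenceSet(points=pts, labels=labels)


def _spherical_polygon_area_km2(lon: np.ndarray, lat: np.ndarray) -> float:
    """Area of a simple spherical polygon (vertices in degrees, ring not
    closed) on the authalic sphere, via the signed spherical-excess sum
    over the equal-area sinusoidal-like lune terms:

        A = R^2 * |sum_i (lon_{i+1} - lon_i) * (2 + sin lat_i + sin lat_{i+1})| / 2

    This is the standard discrete geodesic-area formula for spherical
    polygons with great-ellipse edges at small edge lengths.
    """
    lam = np.radians(lon)
    phi = np.radians(lat)
    lam2 = np.roll(lam, -1)
    phi2 = np.roll(phi, -1)
    dlam = lam2 - lam
    # wrap to (-pi, pi] so polygons near the antimeridian stay sane
    dlam = (dlam + np.pi) % (2 * np.pi) - np.pi
    total = np.sum(dlam * (2 + np.sin(phi) + np.sin(phi2))) / 2.0
    return AUTHALIC_RADIUS_KM**2 * abs(total)


def mcp_area_km2(occ: OccurrenceSet, mode: str = "spherical") -> float:
    """Minimum-convex-polygon area of the occurrence points.

    ``mode="spherical"`` (default) returns km² on the WGS84 authalic
    sphere; ``mode="planar"`` treats coordinates as planar and returns the
    hull area in squared input units (useful for toy/projected data).
    Fewer than 3 distinct non-collinear points give area 0 with a warning.
    """
    hull = MultiPoint([tuple(p) for p in occ.points]).convex_hull
    if hull.geom_type != "Polygon":
        warnings.warn(
            "fewer than 3 non-collinear points: extent of occurrence is 0",
            stacklevel=2,
        )
        return 0.0
    xy = np.asarray(hull.exterior.coords)[:-1]  # drop closing vertex
    if mode == "planar":
        return float(hull.area)
    if mode != "spherical":
        raise ValueError(f"unknown mode {mode!r}")
    return _spherical_polygon_area_km2(xy[:, 0], xy[:, 1])


def degraded_percent(area_km2: float, degraded_km2: float) -> float:
    """Degraded fraction of the range, percent to one decimal.

    Computed with exact rational arithmetic before rounding, so printed
    area pairs reproduce their published percentages exactly.
    """
    if area_km2 <= 0:
        raise ValueError("area must be > 0")
    if not 0 <= degraded_km2 <= area_km2:
        raise ValueError("degraded area must be in [0, total area]")
    frac = Fraction(degraded_km2) / Fraction(area_km2) * 100
    return float(round(frac, 1))


def redlist_suggest(
    area_km2: float,
    degraded_pct: float | None = None,
    n_localities: int = 0,
) -> str:
    """Advisory Red List category suggestion.

    DD (Data Deficient) when only one locality is known or the area is
    unavailable; LC (Least Concern) when the extent of occurrence is at
    least 20,000 km² (the IUCN criterion B1 Vulnerable bound) and habitat
    degradation, when known, is below 50%; anything else is flagged
    ``review`` — a human decision. Advisory only; this rule deliberately
    encodes no more than the coarse published reasoning.
    """
    if area_km2 is None or not math.isfinite(area_km2) or area_km2 < 0:
        return "DD"
    if n_localities <= 1:
        return "DD"
    if area_km2 >= 20000 and (degraded_pct is None or degraded_pct < 50):
        return "LC"
    return "review"


@dataclass(frozen=True)
class RangeReport:
    """Extent of occurrence with the degraded fraction and suggestion."""

    area_km2: float
    n_localities: int
    degraded_km2: float | None = None
    degraded_pct: float | None = None
    suggested_category: str = "review"
    area_method: str = "convex hull, WGS84 authalic sphere"

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def assess_range(
    occ: OccurrenceSet, degraded_km2: float | None = None
) -> RangeReport:
    """MCP area, degraded fraction (when supplied), and category suggestion."""
    area = mcp_area_km2(occ)
    pct = None
    if degraded_km2 is not None and area > 0:
        pct = degraded_percent(area, degraded_km2)
    return RangeReport(
        area_km2=area,
        n_localities=occ.n_localities,
        degraded_km2=degraded_km2,
        degraded_pct=pct,
        suggested_category=redlist_suggest(area, pct, occ.n_localities),
    )
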