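"""Observation windows for spatial point patterns.

A :class:`SpatialWindow` wraps a simple planar polygon in projected metric
coordinates (x east, y north).  All point-process machinery in this package is
window-agnostic: the study region may be a survey plot rectangle or an
island outline, supplied as WKT or GeoJSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, shape as _geojson_shape
from shapely import wkt as _wkt

__all__ = ["SpatialWindow", "rectangle_window"]


@dataclass(frozen=True)
class SpatialWindow:
    """A simple (non-self-intersecting) polygonal observation region in meters."""

    boundary: Polygon
    _prepared: object = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        poly = self.boundary
        if not isinstance(poly, Polygon):
            raise TypeError("boundary must be a shapely Polygon")
        if not poly.is_valid or poly.is_empty:
            raise ValueError("window boundary must be a simple, non-empty polygon")
        if poly.area <= 0:
            raise ValueError("window area must be positive")

    @property
    def area(self) -> float:
        """Window area in m^2."""
        return float(self.boundary.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in meters."""
        return tuple(float(b) for b in self.boundary.bounds)

    def contains(self, x, y) -> np.ndarray:
        """Vectorized point-in-window test (boundary counts as inside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        pts = shapely.points(x, y)
        return np.asarray(shapely.covers(self.boundary, pts))

    # -- serialisation -------------------------------------------------
    def to_wkt(self) -> str:
        return self.boundary.wkt

    @classmethod
    def from_wkt(cls, text: str) -> "SpatialWindow":
        return cls(_wkt.loads(text))

    @classmethod
    def from_geojson(cls, obj: dict) -> "SpatialWindow":
        if obj.get("type") == "Feature":
            obj = obj["geometry"]
        return cls(_geojson_shape(obj))

    @classmethod
    def from_file(cls, path) -> "SpatialWindow":
        """Read a window from a .wkt or .geojson/.json file."""
        import json
        from pathlib import Path

        text = Path(path).read_text().strip()
        if text.startswith("{"):
            return cls.from_geojson(json.loads(text))
        return cls.from_wkt(text)


def rectangle_window(width: float, height: float, x0: float = 0.0, y0: float = 0.0) -> SpatialWindow:
    """Axis-aligned rectangular window, e.g. ``rectangle_window(1000, 500)``
    for a 50-ha census plot."""
    return SpatialWindow(
        Polygon([(x0, y0), (x0 + width, y0), (x0 + width, y0 + height), (x0, y0 + height)])
    )
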