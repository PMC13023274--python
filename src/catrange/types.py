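"""Core domain types shared across the package.

All geometry lives in a local planar metric frame (meters).  Vector data are
shapely geometries; gridded imagery is a numpy array plus a simple north-up
geotransform (origin of the top-left corner and a square pixel size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.ops import unary_union

#: The six land-cover classes used for polygon labeling.
BASE_CLASSES: tuple[str, ...] = (
    "Roads",
    "Structures",
    "Open urban",
    "Open urban natural",
    "Natural",
    "Agriculture",
)

#: Derived accounting rows built from the base classes / green flags.
DERIVED_ROWS: tuple[str, ...] = (
    "Green",
    "Not green",
    "Open all",
    "Open urban all",
    "Open outside settlement",
)

#: Composition of each derived row in terms of base classes (green rows are
#: computed from the per-polygon ``is_green`` flag instead).
DERIVED_COMPOSITION: dict[str, tuple[str, ...]] = {
    "Open all": ("Open urban", "Open urban natural", "Natural", "Agriculture"),
    "Open urban all": ("Open urban", "Open urban natural"),
    "Open outside settlement": ("Natural", "Agriculture"),
}


class InvalidConfigError(ValueError):
    """A simulation or analysis configuration violates its invariants."""


class DegenerateGeometryError(ValueError):
    """Geometry too degenerate to analyse (coincident or collinear points)."""


class CoverageError(ValueError):
    """A land-cover map does not cover the query region."""


# ---------------------------------------------------------------------------
# GPS fixes
# ---------------------------------------------------------------------------


@dataclass
class FixSet:
    """Timestamped 2-D GPS fixes for one cat.

    Parameters
    ----------
    cat_id : str
        Identifier of the tracked cat.
    fixes : pandas.DataFrame
        Columns ``timestamp`` (datetime64), ``x`` and ``y`` (meters, local
        planar frame).  An optional boolean ``is_contaminant`` column carries
        simulation ground truth.
    inlier_mask : numpy.ndarray or None
        Boolean mask aligned with ``fixes`` rows; set by outlier filtering.
    """

    cat_id: str
    fixes: pd.DataFrame
    inlier_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        required = {"timestamp", "x", "y"}
        missing = required - set(self.fixes.columns)
        if missing:
            raise ValueError(f"fix table missing columns: {sorted(missing)}")
        xy = self.fixes[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("fix coordinates must be finite")
        if self.inlier_mask is not None:
            self.inlier_mask = np.asarray(self.inlier_mask, dtype=bool)
            if self.inlier_mask.shape != (len(self.fixes),):
                raise ValueError("inlier_mask length must match number of fixes")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of fix coordinates in meters."""
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    @property
    def dates(self) -> np.ndarray:
        """Sorted unique calendar dates spanned by the fixes."""
        return np.sort(self.fixes["timestamp"].dt.normalize().unique())

    def inliers(self) -> pd.DataFrame:
        if self.inlier_mask is None:
            return self.fixes
        return self.fixes.loc[self.inlier_mask]

    def inlier_xy(self) -> np.ndarray:
        if self.inlier_mask is None:
            return self.xy
        return self.xy[self.inlier_mask]

    def with_fixes(self, fixes: pd.DataFrame, mask: np.ndarray | None = None) -> "FixSet":
        return FixSet(self.cat_id, fixes.reset_index(drop=True), mask)


# ---------------------------------------------------------------------------
# Roaming area
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AOIPolygon:
    """Convex-hull roaming area (95% MCP) of a cat's inlier fixes."""

    cat_id: str
    polygon: Polygon
    n_inliers: int

    @property
    def area_m2(self) -> float:
        return float(self.polygon.area)

    @property
    def area_ha(self) -> float:
        return float(self.polygon.area) / 10_000.0

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (float(c.x), float(c.y))


@dataclass(frozen=True)
class EqualAreaCircle:
    """Isotropic-null region: a circle at the median fix with the AOI's area."""

    center: tuple[float, float]
    radius: float
    polygon: Polygon

    @property
    def area_m2(self) -> float:
        return float(self.polygon.area)


# ---------------------------------------------------------------------------
# Session metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionDay:
    """One tracking day's weather record."""

    date: pd.Timestamp
    rain: bool
    max_temp_c: float | None


@dataclass
class SessionMetadata:
    """Per-cat covariates and the session's daily weather records."""

    cat_id: str
    sex: str  # "F" or "M"
    age: int  # years, 1-12
    session_days: list[SessionDay] = field(default_factory=list)
    season: str | None = None  # "winter" or "summer"

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if not 1 <= self.age <= 12:
            raise ValueError("age must be in [1, 12] years")


# ---------------------------------------------------------------------------
# Land cover
# ---------------------------------------------------------------------------


@dataclass
class LandCoverPolygon:
    """A labeled land-cover patch."""

    geometry: Polygon | MultiPolygon
    landcover: str | None = None
    is_green: bool = False
    cluster_id: int = -1

    @property
    def area(self) -> float:
        return float(self.geometry.area)


@dataclass
class LandCoverMap:
    """A labeled polygon partition of a mapped region."""

    polygons: list[LandCoverPolygon]
    _geom_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for p in self.polygons:
            if p.landcover is not None and p.landcover not in BASE_CLASSES:
                raise ValueError(
                    f"unknown land-cover class {p.landcover!r}; "
                    f"valid classes: {list(BASE_CLASSES)}"
                )

    def __len__(self) -> int:
        return len(self.polygons)

    @property
    def labels(self) -> set[str]:
        return {p.landcover for p in self.polygons if p.landcover is not None}

    def total_area(self) -> float:
        return float(sum(p.area for p in self.polygons))

    def extent(self) -> Polygon | MultiPolygon:
        """Union of all polygons (the mapped region)."""
        return unary_union([p.geometry for p in self.polygons])

    def class_geometry(self, landcover: str) -> MultiPolygon | Polygon:
        key = ("class", landcover)
        if key not in self._geom_cache:
            geoms = [p.geometry for p in self.polygons if p.landcover == landcover]
            self._geom_cache[key] = unary_union(geoms) if geoms else MultiPolygon([])
        return self._geom_cache[key]

    def green_geometry(self, green: bool = True) -> MultiPolygon | Polygon:
        key = ("green", green)
        if key not in self._geom_cache:
            geoms = [p.geometry for p in self.polygons if p.is_green == green]
            self._geom_cache[key] = unary_union(geoms) if geoms else MultiPolygon([])
        return self._geom_cache[key]

    # -- serialization -----------------------------------------------------

    def to_geojson(self) -> dict:
        feats = []
        for p in self.polygons:
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(p.geometry),
                    "properties": {
                        "landcover": p.landcover,
                        "is_green": bool(p.is_green),
                        "cluster_id": int(p.cluster_id),
                    },
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    @classmethod
    def from_geojson(cls, obj: Mapping) -> "LandCoverMap":
        polys = []
        for feat in obj["features"]:
            props = feat.get("properties", {}) or {}
            polys.append(
                LandCoverPolygon(
                    geometry=shape(feat["geometry"]),
                    landcover=props.get("landcover"),
                    is_green=bool(props.get("is_green", False)),
                    cluster_id=int(props.get("cluster_id", -1)),
                )
            )
        return cls(polys)


# ---------------------------------------------------------------------------
# Imagery
# ---------------------------------------------------------------------------


@dataclass
class RGBImage:
    """An RGB raster in the local planar frame.

    ``data`` is (rows, cols, 3) with band values in [0, 255]; ``origin`` is the
    world coordinate of the top-left corner of the top-left pixel and rows run
    north to south (world y decreases with row index).  ``nodata`` marks pixels
    excluded from analysis (e.g. under masked buildings).
    """

    data: np.ndarray
    origin: tuple[float, float]
    pixel_size: float
    nodata: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("RGB image must have shape (rows, cols, 3)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.data.min() < 0 or self.data.max() > 255:
            raise ValueError("band values must lie in [0, 255]")
        if self.nodata is None:
            self.nodata = np.zeros(self.data.shape[:2], dtype=bool)
        else:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.data.shape[:2]:
                raise ValueError("nodata mask shape must match image grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of all pixel centers as (X, Y) 2-D arrays."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def copy(self) -> "RGBImage":
        return RGBImage(self.data.copy(), self.origin, self.pixel_size, self.nodata.copy())
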