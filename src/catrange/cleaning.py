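"""GPS fix-stream cleaning and roaming-area (AOI) delineation.

The cleaning protocol mirrors standard practice for short owned-cat tracking
sessions: the first calendar day is discarded as harness acclimation, erroneous
fixes are rejected with a one-class SVM (RBF kernel) so that roughly the
central 95% of fixes are retained, and the roaming area is the convex hull of
the inlier fixes (a 95% minimum convex polygon).  Season is classified with a
dichotomous Mediterranean rule (winter vs. summer).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon
from sklearn.svm import OneClassSVM

from .types import AOIPolygon, DegenerateGeometryError, FixSet, SessionDay

logger = logging.getLogger(__name__)

#: Mean Earth radius in meters, for the local planar projection.
_EARTH_RADIUS_M = 6_371_008.8

#: Minimum number of fixes for which a one-class-SVM boundary is meaningful.
MIN_FIXES_FOR_CLEANING = 20


@dataclass(frozen=True)
class CleaningConfig:
    """One-class-SVM outlier-rejection settings.

    nu upper-bounds the fraction of training fixes left outside the decision
    boundary (so ~1 - nu of fixes are retained); gamma is the RBF bandwidth on
    standardized coordinates.  Both defaults retain the central 95% of fixes
    with a smooth boundary.
    """

    nu: float = 0.05
    gamma: float = 0.1
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.nu < 1.0:
            raise ValueError("nu must lie in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def project_lonlat(
    lon: np.ndarray, lat: np.ndarray, origin: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Project geographic coordinates to a local planar frame in meters.

    Uses a local tangent-plane (equirectangular) projection centered on
    ``origin`` (defaults to the centroid of the input points):
    ``x = R cos(lat0) (lon - lon0)``, ``y = R (lat - lat0)`` with angles in
    radians.  For extents under a few kilometers the distortion is well below
    GPS error, which is all the roaming-area analysis requires.

    Returns ``(x, y, origin)`` with coordinates in meters.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if origin is None:
        origin = (float(np.mean(lon)), float(np.mean(lat)))
    lon0, lat0 = origin
    x = _EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.radians(lon - lon0)
    y = _EARTH_RADIUS_M * np.radians(lat - lat0)
    return x, y, origin


def drop_acclimation_day(fix_set: FixSet) -> FixSet:
    """Remove all fixes from the first calendar day of a tracking session.

    The first day on harness is treated as acclimation and excluded from
    analysis.  Raises ``ValueError`` if the stream spans a single day (nothing
    analyzable would remain).
    """
    days = fix_set.fixes["timestamp"].dt.normalize()
    unique_days = days.unique()
    if len(unique_days) < 2:
        raise ValueError(
            "fix stream spans a single calendar day; cannot drop the acclimation day"
        )
    first = unique_days.min()
    keep = days > first
    fixes = fix_set.fixes.loc[keep]
    mask = fix_set.inlier_mask[keep.to_numpy()] if fix_set.inlier_mask is not None else None
    return fix_set.with_fixes(fixes, mask)


def classify_season(session_days: Sequence[SessionDay | tuple]) -> str:
    """Classify a tracking session as ``"winter"`` or ``"summer"``.

    A session is winter if any of three conditions holds: it touches December,
    January or February; it includes at least one rainy day; or the mean of the
    daily maximum daytime temperatures does not exceed 20.0 degC (boundary
    inclusive).  Otherwise it is summer.
    """
    if not session_days:
        raise ValueError("session_days is empty")
    days = [d if isinstance(d, SessionDay) else SessionDay(pd.Timestamp(d[0]), bool(d[1]), d[2])
            for d in session_days]
    temps = [d.max_temp_c for d in days if d.max_temp_c is not None]
    if not temps:
        raise ValueError("no daily maximum temperature available in session_days")
    in_winter_months = any(d.date.month in (12, 1, 2) for d in days)
    any_rain = any(d.rain for d in days)
    cool = float(np.mean(temps)) <= 20.0
    return "winter" if (in_winter_months or any_rain or cool) else "summer"


def filter_outliers(fix_set: FixSet, config: CleaningConfig | None = None) -> FixSet:
    """Split fixes into inliers and outliers with a one-class SVM.

    Fits an RBF-kernel one-class SVM on the (optionally per-axis standardized)
    fix coordinates and returns a copy of the fix set carrying the resulting
    boolean ``inlier_mask``.  With the default ``nu = 0.05`` roughly the
    central 95% of fixes are retained.  Deterministic for a given fix set and
    configuration.
    """
    config = config or CleaningConfig()
    xy = fix_set.xy
    n = len(xy)
    if n < MIN_FIXES_FOR_CLEANING:
        raise ValueError(
            f"need at least {MIN_FIXES_FOR_CLEANING} fixes to fit an outlier boundary, got {n}"
        )
    std = xy.std(axis=0)
    if np.all(std == 0):
        raise DegenerateGeometryError("all fixes are coincident")
    features = xy
    if config.standardize:
        if np.any(std == 0):
            raise DegenerateGeometryError(
                "fixes are collinear along an axis; cannot standardize coordinates"
            )
        features = (xy - xy.mean(axis=0)) / std
    svm = OneClassSVM(kernel="rbf", nu=config.nu, gamma=config.gamma)
    pred = svm.fit_predict(features)
    mask = pred == 1
    logger.debug(
        "filter_outliers(%s): retained %d/%d fixes (%.1f%%)",
        fix_set.cat_id, int(mask.sum()), n, 100.0 * mask.mean(),
    )
    return FixSet(fix_set.cat_id, fix_set.fixes, mask)


def _hull_of(points: np.ndarray) -> Polygon:
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise DegenerateGeometryError(
            "inlier fixes are collinear or coincident; convex hull has zero area"
        )
    return hull


def delineate_aoi(fix_set: FixSet) -> AOIPolygon:
    """Delineate the AOI as the convex hull (MCP) of the inlier fixes.

    Requires at least 3 non-collinear inlier fixes; raises
    ``DegenerateGeometryError`` otherwise.  The hull contains every inlier fix
    on or inside its boundary, and its area in hectares is the planar polygon
    area divided by 10,000.
    """
    pts = fix_set.inlier_xy()
    if len(np.unique(pts, axis=0)) < 3:
        raise DegenerateGeometryError("need at least 3 distinct inlier fixes for an AOI")
    hull = _hull_of(pts)
    return AOIPolygon(cat_id=fix_set.cat_id, polygon=hull, n_inliers=len(pts))


def daily_aoi_series(fix_set: FixSet) -> list[tuple[pd.Timestamp, AOIPolygon]]:
    """Per-day AOIs for trend and centroid-dispersion diagnostics.

    Builds one convex hull per calendar day from that day's inlier fixes.
    Days with fewer than 3 distinct non-collinear inliers are skipped with a
    logged warning.
    """
    frame = fix_set.inliers()
    out: list[tuple[pd.Timestamp, AOIPolygon]] = []
    for day, group in frame.groupby(frame["timestamp"].dt.normalize()):
        pts = group[["x", "y"]].to_numpy(dtype=float)
        try:
            if len(np.unique(pts, axis=0)) < 3:
                raise DegenerateGeometryError("fewer than 3 distinct fixes")
            hull = _hull_of(pts)
        except DegenerateGeometryError as exc:
            logger.warning("daily AOI for %s on %s skipped: %s", fix_set.cat_id, day.date(), exc)
            continue
        out.append((day, AOIPolygon(cat_id=fix_set.cat_id, polygon=hull, n_inliers=len(pts))))
    return out
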