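"""File formats: fix CSVs, GeoJSON vector layers, JSON reports, manifests.

Fix tables are CSV with columns ``cat_id, timestamp, x_m, y_m`` plus optional
``is_contaminant`` (simulation truth) and ``is_inlier`` (cleaning output).
Tables holding ``lon, lat`` instead of ``x_m, y_m`` are auto-projected to a
local planar frame on read.  Vector layers are GeoJSON feature collections.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .cleaning import project_lonlat
from .types import AOIPolygon, FixSet, LandCoverMap


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj: Any) -> Any:
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (pd.Timestamp,)):
            return obj.isoformat()
        return super().default(obj)


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


# -- fixes ------------------------------------------------------------------


def write_fixes_csv(fix_set: FixSet, path: str | Path) -> None:
    frame = fix_set.fixes.copy()
    frame.insert(0, "cat_id", fix_set.cat_id)
    frame = frame.rename(columns={"x": "x_m", "y": "y_m"})
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    if fix_set.inlier_mask is not None:
        frame["is_inlier"] = fix_set.inlier_mask
    frame.to_csv(path, index=False)


def read_fixes_csv(path: str | Path) -> FixSet:
    frame = pd.read_csv(path)
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    cat_ids = frame["cat_id"].unique() if "cat_id" in frame else ["cat"]
    if len(cat_ids) != 1:
        raise ValueError(f"fix CSV must hold a single cat, found {len(cat_ids)}")
    if "lon" in frame.columns and "lat" in frame.columns:
        x, y, _ = project_lonlat(frame["lon"].to_numpy(), frame["lat"].to_numpy())
        frame["x_m"], frame["y_m"] = x, y
    cols = {"timestamp": frame["timestamp"], "x": frame["x_m"], "y": frame["y_m"]}
    if "is_contaminant" in frame:
        cols["is_contaminant"] = frame["is_contaminant"].astype(bool)
    mask = frame["is_inlier"].to_numpy(dtype=bool) if "is_inlier" in frame else None
    return FixSet(str(cat_ids[0]), pd.DataFrame(cols), mask)


# -- vector layers ----------------------------------------------------------


def write_aoi_geojson(aoi: AOIPolygon, path: str | Path) -> None:
    feature = {
        "type": "Feature",
        "geometry": mapping(aoi.polygon),
        "properties": {
            "cat_id": aoi.cat_id,
            "area_ha": aoi.area_ha,
            "n_inliers": aoi.n_inliers,
        },
    }
    write_json({"type": "FeatureCollection", "features": [feature]}, path)


def read_aoi_geojson(path: str | Path) -> AOIPolygon:
    obj = read_json(path)
    feat = obj["features"][0]
    props = feat.get("properties", {})
    return AOIPolygon(
        cat_id=str(props.get("cat_id", "cat")),
        polygon=shape(feat["geometry"]),
        n_inliers=int(props.get("n_inliers", 0)),
    )


def write_landcover_geojson(lc_map: LandCoverMap, path: str | Path) -> None:
    write_json(lc_map.to_geojson(), path)


def read_landcover_geojson(path: str | Path) -> LandCoverMap:
    return LandCoverMap.from_geojson(read_json(path))


# -- cohort manifest --------------------------------------------------------


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Required columns: ``cat_id``, ``fixes`` (fix CSV path), ``landcover``
    (land-cover GeoJSON path), ``sex``, ``age``, ``season``.  Paths are
    resolved relative to the manifest's directory; ids must be unique and
    every referenced file must exist.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"cat_id", "fixes", "landcover", "sex", "age", "season"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if frame.empty:
        raise ValueError("manifest is empty")
    if frame["cat_id"].duplicated().any():
        raise ValueError("manifest cat_id values must be unique")
    base = path.parent
    for col in ("fixes", "landcover"):
        frame[col] = [str((base / p).resolve()) for p in frame[col]]
        absent = [p for p in frame[col] if not Path(p).exists()]
        if absent:
            raise FileNotFoundError(f"manifest references missing files: {absent[:3]}")
    return frame.set_index("cat_id")
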