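"""Synthetic cat tracks, landscapes, imagery and cohorts.

The generators emulate the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without field data:

* tracks are i.i.d. isotropic bivariate-normal fixes around a fixed activity
  center, recorded on a 3-minute cadence over consecutive days, contaminated
  by a configurable fraction of heavy-tailed GPS errors drawn on an annulus
  far from the center (reconnection-type noise);
* landscapes are patchy multi-class mosaics built by thresholding a smoothed
  Gaussian random field at class-weight quantiles and polygonizing the result;
* an optional habitat preference biases fixes toward one land-cover class by
  acceptance-rejection (off-target proposals survive with probability
  1/(1+strength)), with strength 0 reproducing the isotropic generator
  exactly;
* cohorts bundle per-cat tracks, landscapes and metadata with per-cat seeds
  derived deterministically from a single master seed.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .cleaning import classify_season
from .landcover import Segmentation, polygonize
from .types import (
    BASE_CLASSES,
    FixSet,
    InvalidConfigError,
    LandCoverMap,
    LandCoverPolygon,
    RGBImage,
    SessionDay,
    SessionMetadata,
)

#: Land-cover classes carrying the vegetation flag in synthetic landscapes.
GREEN_CLASSES = frozenset({"Open urban", "Open urban natural", "Natural", "Agriculture"})

#: Default flat-color palette for synthetic imagery, one distinct RGB color
#: (and distinct luminance) per class; vegetation classes are green-dominant.
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "Roads": (100, 100, 105),
    "Structures": (190, 120, 110),
    "Open urban": (100, 150, 80),
    "Open urban natural": (120, 160, 95),
    "Natural": (70, 130, 60),
    "Agriculture": (140, 160, 90),
}

_FIX_CADENCE = pd.Timedelta(minutes=3)

#: Default landscape composition: a Mediterranean residential neighborhood
#: where built/modified covers dominate, natural patches occur at the edges
#: and agriculture is rare (so some cats have no natural or agricultural
#: cover in range, as in real cohorts).
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "Roads": 0.12,
    "Structures": 0.18,
    "Open urban": 0.35,
    "Open urban natural": 0.15,
    "Natural": 0.15,
    "Agriculture": 0.05,
}


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackSimConfig:
    """Isotropic track-generator settings.

    The activity center is fixed; displacements are i.i.d. isotropic bivariate
    normal with standard deviation ``dispersion_sigma`` (m).  A fraction
    ``outlier_fraction`` of fixes is replaced by contamination drawn uniformly
    in radius on the annulus [3 sigma, ``outlier_scale``] (GPS reconnection
    errors).  Fixes are stamped every 3 minutes starting at local midnight of
    ``start``, ``fixes_per_day`` per day for ``n_days`` days.
    """

    center: tuple[float, float] = (0.0, 0.0)
    n_days: int = 8
    fixes_per_day: int = 480
    dispersion_sigma: float = 20.0
    outlier_fraction: float = 0.05
    outlier_scale: float | None = None  # default: 20 * dispersion_sigma
    start: str = "2019-06-15"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion_sigma <= 0:
            raise InvalidConfigError("dispersion_sigma must be positive")
        if self.n_days < 1 or self.fixes_per_day < 1:
            raise InvalidConfigError("n_days and fixes_per_day must be positive")
        if self.fixes_per_day > 480:
            raise InvalidConfigError("at a 3-minute cadence a day holds at most 480 fixes")
        if not 0.0 <= self.outlier_fraction < 0.5:
            raise InvalidConfigError("outlier_fraction must lie in [0, 0.5)")
        if self.outlier_scale is not None and self.outlier_scale <= 3 * self.dispersion_sigma:
            raise InvalidConfigError("outlier_scale must exceed 3 * dispersion_sigma")

    @property
    def n_fixes(self) -> int:
        return self.n_days * self.fixes_per_day

    @property
    def annulus(self) -> tuple[float, float]:
        outer = self.outlier_scale or 20.0 * self.dispersion_sigma
        return 3.0 * self.dispersion_sigma, outer


@dataclass(frozen=True)
class LandscapeSimConfig:
    """Patchy-landscape generator settings.

    ``extent`` is (xmin, ymin, xmax, ymax) in meters; ``class_weights`` maps
    land-cover classes to nonnegative area weights (realized area fractions
    converge to the normalized weights); ``patch_scale`` is the spatial
    correlation length of the underlying Gaussian random field, i.e. the
    typical patch size in meters.
    """

    extent: tuple[float, float, float, float] = (-160.0, -160.0, 160.0, 160.0)
    pixel_size: float = 0.6
    class_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    patch_scale: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise InvalidConfigError("extent must have positive width and height")
        if self.pixel_size <= 0:
            raise InvalidConfigError("pixel_size must be positive")
        if self.patch_scale <= 0:
            raise InvalidConfigError("patch_scale must be positive")
        if not self.class_weights:
            raise InvalidConfigError("class_weights must not be empty")
        unknown = set(self.class_weights) - set(BASE_CLASSES)
        if unknown:
            raise InvalidConfigError(f"unknown land-cover classes in weights: {sorted(unknown)}")
        w = np.array(list(self.class_weights.values()), dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise InvalidConfigError("class weights must be nonnegative with positive sum")


@dataclass(frozen=True)
class PreferenceSpec:
    """Habitat preference for one land-cover class.

    ``strength`` 0 means isotropic roaming; larger values increase attraction:
    proposed fixes landing off the target class are kept with probability
    1/(1+strength), so on a landscape where the target has availability p the
    expected on-target occupancy is p(1+strength) / (p(1+strength) + 1 - p).
    """

    target_class: str
    strength: float = 0.0

    def __post_init__(self) -> None:
        if self.target_class not in BASE_CLASSES:
            raise InvalidConfigError(f"unknown target class {self.target_class!r}")
        if self.strength < 0:
            raise InvalidConfigError("strength must be nonnegative")


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------


def _timestamps(cfg: TrackSimConfig) -> pd.DatetimeIndex:
    start = np.datetime64(pd.Timestamp(cfg.start), "ns")
    day = np.timedelta64(1, "D").astype("timedelta64[ns]")
    step = np.timedelta64(3, "m").astype("timedelta64[ns]")
    offsets = (
        np.repeat(np.arange(cfg.n_days), cfg.fixes_per_day) * day
        + np.tile(np.arange(cfg.fixes_per_day), cfg.n_days) * step
    )
    return pd.DatetimeIndex(start + offsets)


def _assemble(cfg: TrackSimConfig, cat_id: str, xy: np.ndarray,
              contaminant: np.ndarray) -> FixSet:
    frame = pd.DataFrame(
        {
            "timestamp": _timestamps(cfg),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "is_contaminant": contaminant,
        }
    )
    return FixSet(cat_id=cat_id, fixes=frame)


def _draw_outliers(rng: np.random.Generator, cfg: TrackSimConfig, k: int) -> np.ndarray:
    r_in, r_out = cfg.annulus
    r = rng.uniform(r_in, r_out, size=k)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=k)
    return np.column_stack((r * np.cos(theta), r * np.sin(theta)))


def simulate_track(cfg: TrackSimConfig, cat_id: str = "cat") -> FixSet:
    """Simulate an isotropic GPS fix stream for one cat.

    Returns ``n_days * fixes_per_day`` fixes whose expected contamination
    fraction equals ``outlier_fraction``; the ``is_contaminant`` column holds
    the ground truth.  Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_fixes
    contaminant = rng.random(n) < cfg.outlier_fraction
    disp = rng.standard_normal((n, 2)) * cfg.dispersion_sigma
    k = int(contaminant.sum())
    if k:
        disp[contaminant] = _draw_outliers(rng, cfg, k)
    xy = np.asarray(cfg.center, dtype=float) + disp
    return _assemble(cfg, cat_id, xy, contaminant)


def simulate_biased_track(
    cfg: TrackSimConfig,
    landscape: LandCoverMap,
    pref: PreferenceSpec,
    cat_id: str = "cat",
    max_rounds: int = 1000,
) -> FixSet:
    """Simulate a track attracted to one land-cover class.

    Non-contaminant fixes are drawn by acceptance-rejection: a proposed
    displacement landing on ``pref.target_class`` is always kept, one landing
    elsewhere survives with probability 1/(1+strength).  With ``strength = 0``
    this is exactly :func:`simulate_track` (same seed, same fixes).
    Contamination fixes are unaffected by preference.
    """
    if pref.strength == 0:
        target = landscape.class_geometry(pref.target_class)
        if target.is_empty:
            raise ValueError(f"target class {pref.target_class!r} absent from landscape")
        return simulate_track(cfg, cat_id)
    target = landscape.class_geometry(pref.target_class)
    if target.is_empty:
        raise ValueError(f"target class {pref.target_class!r} absent from landscape")
    shapely.prepare(target)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_fixes
    center = np.asarray(cfg.center, dtype=float)
    contaminant = rng.random(n) < cfg.outlier_fraction
    n_in = int((~contaminant).sum())
    accepted: list[np.ndarray] = []
    got = 0
    keep_prob = 1.0 / (1.0 + pref.strength)
    for _ in range(max_rounds):
        if got >= n_in:
            break
        m = max(32, 2 * (n_in - got))
        pts = center + rng.standard_normal((m, 2)) * cfg.dispersion_sigma
        on_target = shapely.contains_xy(target, pts[:, 0], pts[:, 1])
        u = rng.random(m)
        keep = on_target | (u < keep_prob)
        pts = pts[keep]
        accepted.append(pts)
        got += len(pts)
    else:
        raise RuntimeError("acceptance-rejection failed to converge; check landscape coverage")
    inlier_xy = np.concatenate(accepted)[:n_in]
    xy = np.empty((n, 2), dtype=float)
    xy[~contaminant] = inlier_xy
    k = int(contaminant.sum())
    if k:
        xy[contaminant] = center + _draw_outliers(rng, cfg, k)
    return _assemble(cfg, cat_id, xy, contaminant)


# ---------------------------------------------------------------------------
# Landscapes and imagery
# ---------------------------------------------------------------------------


def _landscape_labels(cfg: LandscapeSimConfig) -> tuple[np.ndarray, list[str], tuple[float, float]]:
    """Labeled pixel grid of a smoothed-Gaussian-field landscape.

    The field is thresholded at the empirical quantiles given by the
    normalized class weights, so realized pixel fractions match the weights up
    to integer rounding.
    """
    xmin, ymin, xmax, ymax = cfg.extent
    cols = max(1, round((xmax - xmin) / cfg.pixel_size))
    rows = max(1, round((ymax - ymin) / cfg.pixel_size))
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal((rows, cols))
    field_ = ndimage.gaussian_filter(noise, sigma=cfg.patch_scale / cfg.pixel_size, mode="wrap")
    classes = list(cfg.class_weights)
    w = np.array([cfg.class_weights[c] for c in classes], dtype=float)
    w = w / w.sum()
    n_pix = field_.size
    counts = np.diff(np.round(np.concatenate(([0.0], np.cumsum(w))) * n_pix).astype(int))
    order = np.argsort(field_, axis=None, kind="stable")
    labels_flat = np.empty(n_pix, dtype=int)
    labels_flat[order] = np.repeat(np.arange(len(classes)), counts)
    return labels_flat.reshape(rows, cols), classes, (xmin, ymax)


def simulate_landscape(cfg: LandscapeSimConfig) -> LandCoverMap:
    """Generate a patchy multi-class polygonal landscape.

    Every point of the extent belongs to exactly one class polygon, and
    realized class-area fractions converge to the normalized ``class_weights``
    as the extent grows.  Vegetation flags follow the generator convention
    that all open classes except Roads and Structures are green.
    """
    labels, classes, origin = _landscape_labels(cfg)
    seg = Segmentation(
        labels=labels,
        cluster_colors=np.zeros((len(classes), 3)),
        origin=origin,
        pixel_size=cfg.pixel_size,
    )
    polys = polygonize(seg)
    out = [
        LandCoverPolygon(
            p.geometry,
            landcover=classes[p.cluster_id],
            is_green=classes[p.cluster_id] in GREEN_CLASSES,
            cluster_id=p.cluster_id,
        )
        for p in polys
    ]
    return LandCoverMap(out)


def simulate_imagery(
    cfg: LandscapeSimConfig,
    palette: Mapping[str, tuple[int, int, int]] | None = None,
    noise_sigma: float = 0.0,
    noise_seed: int = 0,
) -> tuple[RGBImage, LandCoverMap]:
    """Render a synthetic landscape to an RGB image plus its ground truth map.

    Each class is painted in a flat palette color; optional additive Gaussian
    pixel noise (``noise_sigma``, band units) emulates sensor speckle.  The
    returned map is generated from the same label grid, so image and truth are
    pixel-consistent.
    """
    palette = dict(palette or DEFAULT_PALETTE)
    labels, classes, origin = _landscape_labels(cfg)
    missing = [c for c in classes if c not in palette]
    if missing:
        raise InvalidConfigError(f"palette missing colors for classes: {missing}")
    lut = np.array([palette[c] for c in classes], dtype=float)
    data = lut[labels]
    if noise_sigma > 0:
        rng = np.random.default_rng(noise_seed)
        data = np.clip(data + rng.normal(0.0, noise_sigma, size=data.shape), 0, 255)
    img = RGBImage(data=data, origin=origin, pixel_size=cfg.pixel_size)
    return img, simulate_landscape(cfg)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCat:
    """One simulated cat: its fix stream, landscape and session metadata."""

    fix_set: FixSet
    landscape: LandCoverMap
    metadata: SessionMetadata
    preference: PreferenceSpec | None = None


def _session_days(rng: np.random.Generator, start: pd.Timestamp, n_days: int,
                  season: str) -> list[SessionDay]:
    days = []
    for d in range(n_days):
        date = start + pd.Timedelta(days=d)
        if season == "winter":
            rain = bool(rng.random() < 0.35)
            temp = float(np.clip(rng.normal(16.0, 2.5), 8.0, 19.5))
        else:
            rain = False
            temp = float(np.clip(rng.normal(29.0, 2.0), 22.0, 38.0))
        days.append(SessionDay(date=date, rain=rain, max_temp_c=temp))
    return days


def simulate_cohort(
    n_cats: int,
    track_template: TrackSimConfig | None = None,
    landscape_template: LandscapeSimConfig | None = None,
    pref: PreferenceSpec | None = None,
    seed: int = 0,
) -> list[SimulatedCat]:
    """Simulate an independent cohort of cats.

    Per-cat seeds are derived deterministically from the master seed via a
    seed sequence, so the same master seed reproduces the identical cohort.
    Metadata are drawn as sex ~ Bernoulli(0.5) over {F, M}, age ~ uniform
    integer 1-12 years, season ~ Bernoulli(0.5) over {winter, summer} with
    session dates and weather consistent with the season rule.  Each cat gets
    its own landscape realization centered on its activity center.
    """
    if n_cats < 2:
        raise InvalidConfigError("a cohort needs at least 2 cats")
    track_template = track_template or TrackSimConfig()
    landscape_template = landscape_template or LandscapeSimConfig()
    children = np.random.SeedSequence(seed).spawn(n_cats)
    cohort: list[SimulatedCat] = []
    for i, child in enumerate(children):
        cat_id = f"cat{i + 1:03d}"
        meta_rng = np.random.default_rng(child)
        sex = "F" if meta_rng.random() < 0.5 else "M"
        age = int(meta_rng.integers(1, 13))
        season = "winter" if meta_rng.random() < 0.5 else "summer"
        start = pd.Timestamp("2020-01-10") if season == "winter" else pd.Timestamp("2019-06-15")
        track_seed, land_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2)
        )
        cfg = dataclasses.replace(
            track_template, seed=track_seed, start=str(start.date())
        )
        xmin, ymin, xmax, ymax = landscape_template.extent
        half_w, half_h = (xmax - xmin) / 2.0, (ymax - ymin) / 2.0
        cx, cy = cfg.center
        land_cfg = dataclasses.replace(
            landscape_template,
            seed=land_seed,
            extent=(cx - half_w, cy - half_h, cx + half_w, cy + half_h),
        )
        landscape = simulate_landscape(land_cfg)
        if pref is not None and pref.strength > 0:
            fix_set = simulate_biased_track(cfg, landscape, pref, cat_id=cat_id)
        else:
            fix_set = simulate_track(cfg, cat_id=cat_id)
        days = _session_days(meta_rng, start, cfg.n_days, season)
        meta = SessionMetadata(cat_id=cat_id, sex=sex, age=age, session_days=days,
                               season=classify_season(days))
        assert meta.season == season  # construction keeps the season rule consistent
        cohort.append(SimulatedCat(fix_set, landscape, meta, preference=pref))
    return cohort
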