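"""Fine-scale land-cover mapping from RGB aerial imagery.

The workflow converts an RGB raster into a labeled polygon land-cover map in
five stages: building masking, non-local-means denoising, K-means color
segmentation (default K = 7), polygonization of the label grid (4-connected
components become polygons; masked buildings re-enter as Structures), and
finally per-polygon vegetation flagging plus land-cover labeling from a
cluster-to-class table.  All stages conserve mapped area and are deterministic
under a fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union
from skimage.restoration import denoise_nl_means
from sklearn.cluster import KMeans

from .types import BASE_CLASSES, LandCoverMap, LandCoverPolygon, RGBImage

logger = logging.getLogger(__name__)

#: 4-connectivity structuring element (no diagonal leakage between classes).
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SegmentationConfig:
    """Color-segmentation settings.

    k is the number of K-means color clusters (default 7); denoise_strength is
    the non-local-means filtering parameter h in band units (0 disables
    denoising); green_margin is the color-dominance threshold: a cluster is
    vegetation if its mean green band exceeds both red and blue by at least
    this margin.
    """

    k: int = 7
    denoise_strength: float = 5.0
    seed: int = 0
    green_margin: float = 10.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.denoise_strength < 0:
            raise ValueError("denoise_strength must be nonnegative")


@dataclass
class Segmentation:
    """K-means label grid plus per-cluster mean colors.

    ``labels`` uses -1 for nodata pixels; cluster ids are re-indexed by mean
    luminance (0 = darkest) so outputs are comparable across runs.
    """

    labels: np.ndarray
    cluster_colors: np.ndarray  # (k, 3) mean RGB per cluster
    origin: tuple[float, float]
    pixel_size: float


def _image_bounds(img: RGBImage) -> Polygon:
    rows, cols = img.shape
    x0, y0 = img.origin
    return box(x0, y0 - rows * img.pixel_size, x0 + cols * img.pixel_size, y0)


def mask_buildings(img: RGBImage, buildings: Sequence[Polygon | MultiPolygon]) -> RGBImage:
    """Mark pixels under building footprints as nodata.

    A pixel is masked when its center falls inside a building polygon (the
    center rule; documented so pixel-count expectations are reproducible).
    Building polygons are kept by the caller for later re-insertion as
    Structures.  Raises ``ValueError`` when a non-empty building set does not
    intersect the image extent at all, which indicates a coordinate-frame
    mismatch.
    """
    out = img.copy()
    geoms = [g for g in buildings if g is not None and not g.is_empty]
    if not geoms:
        return out
    union = unary_union(geoms)
    if not union.intersects(_image_bounds(img)):
        raise ValueError(
            "building footprints do not intersect the image extent; "
            "are they in the same planar frame?"
        )
    X, Y = img.pixel_centers()
    shapely.prepare(union)
    inside = shapely.contains_xy(union, X.ravel(), Y.ravel()).reshape(img.shape)
    out.nodata |= inside
    return out


def denoise(img: RGBImage, config: SegmentationConfig | None = None) -> RGBImage:
    """Apply non-local-means denoising so similar land covers form continuous
    color segments.

    With ``denoise_strength = 0`` the image is returned unchanged; nodata
    pixels keep their original values and mask.
    """
    config = config or SegmentationConfig()
    out = img.copy()
    if config.denoise_strength == 0:
        return out
    smoothed = denoise_nl_means(
        img.data,
        h=config.denoise_strength,
        patch_size=5,
        patch_distance=6,
        fast_mode=True,
        channel_axis=-1,
        preserve_range=True,
    )
    out.data = np.clip(smoothed, 0, 255)
    out.data[img.nodata] = img.data[img.nodata]
    return out


def kmeans_segment(img: RGBImage, config: SegmentationConfig | None = None) -> Segmentation:
    """Cluster non-nodata pixels into at most k classes by RGB color.

    Cluster labels are re-indexed by cluster mean luminance so the label grid
    is stable across runs.  If the image holds fewer distinct colors than k,
    k is reduced with a warning.
    """
    config = config or SegmentationConfig()
    valid = ~img.nodata
    pixels = img.data[valid].reshape(-1, 3)
    if pixels.size == 0:
        raise ValueError("image has no valid (non-nodata) pixels to segment")
    n_unique = len(np.unique(pixels, axis=0))
    k = config.k
    if n_unique < k:
        warnings.warn(
            f"image has only {n_unique} distinct colors; reducing k from {k} to {n_unique}",
            stacklevel=2,
        )
        k = n_unique
    km = KMeans(n_clusters=k, random_state=config.seed, n_init=4)
    raw = km.fit_predict(pixels)
    centers = km.cluster_centers_
    luminance = centers @ np.array([0.299, 0.587, 0.114])
    order = np.argsort(luminance, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = np.full(img.shape, -1, dtype=int)
    labels[valid] = relabel[raw]
    return Segmentation(
        labels=labels,
        cluster_colors=centers[order],
        origin=img.origin,
        pixel_size=img.pixel_size,
    )


def _trace_component_polygons(
    comp: np.ndarray, n_comp: int, origin: tuple[float, float], ps: float
) -> list[Polygon | MultiPolygon]:
    """Exact polygon boundary of every labeled component of a pixel grid.

    Boundary edges between unlike pixels are oriented with the component's
    interior on the left and chained into rings; counter-clockwise rings are
    shells, clockwise rings holes.  At the rare corner where a component
    touches itself diagonally, the sharpest-left-turn rule keeps rings simple.
    Runs in O(total boundary length).
    """
    rows, cols = comp.shape
    x0, y0 = origin
    padded = np.pad(comp, 1, constant_values=-1)
    w = cols + 1  # corner-grid width; corner (r, c) -> id r * w + c
    n_corners = (rows + 1) * w
    starts_l, ends_l, dirs_l, owner_l = [], [], [], []
    # edge types: (difference mask, start corner, end corner, direction code)
    # direction codes in the corner lattice: 0 = +c, 1 = +r, 2 = -c, 3 = -r
    for mask, s_off, e_off, d in (
        (comp != padded[:-2, 1:-1], (0, 1), (0, 0), 2),   # top edge, leftward
        (comp != padded[2:, 1:-1], (1, 0), (1, 1), 0),    # bottom edge, rightward
        (comp != padded[1:-1, :-2], (0, 0), (1, 0), 1),   # left edge, downward
        (comp != padded[1:-1, 2:], (1, 1), (0, 1), 3),    # right edge, upward
    ):
        r, c = np.nonzero(mask & (comp >= 0))
        starts_l.append((r + s_off[0]) * w + (c + s_off[1]))
        ends_l.append((r + e_off[0]) * w + (c + e_off[1]))
        dirs_l.append(np.full(r.size, d, dtype=np.int64))
        owner_l.append(comp[r, c])
    starts = np.concatenate(starts_l)
    ends = np.concatenate(ends_l)
    dirs = np.concatenate(dirs_l)
    owners = np.concatenate(owner_l)
    n_edges = len(starts)
    # successor lookup keyed by (owner, corner): each edge continues along an
    # outgoing edge of the same component at its end corner
    start_keys = owners * n_corners + starts
    order = np.argsort(start_keys, kind="stable")
    sorted_keys = start_keys[order]
    end_keys = owners * n_corners + ends
    lo = np.searchsorted(sorted_keys, end_keys, side="left")
    hi = np.searchsorted(sorted_keys, end_keys, side="right")
    unique_next = (hi - lo) == 1
    next_edge = np.full(n_edges, -1, dtype=np.int64)
    next_edge[unique_next] = order[lo[unique_next]]

    used = np.zeros(n_edges, dtype=bool)
    ring_edges: list[np.ndarray] = []
    ring_owner: list[int] = []
    for i0 in range(n_edges):
        if used[i0]:
            continue
        ring: list[int] = []
        i = i0
        while not used[i]:
            used[i] = True
            ring.append(i)
            nx = next_edge[i]
            if nx < 0:  # diagonal self-touch: take the sharpest left turn
                cand = [j for j in order[lo[i]:hi[i]] if not used[j]]
                if not cand:
                    break  # ring closed at a junction corner
                want = ((dirs[i] - 1) % 4, dirs[i], (dirs[i] + 1) % 4)
                cand.sort(key=lambda j: want.index(dirs[j]))
                nx = cand[0]
            i = nx
        ring_edges.append(np.asarray(ring))
        ring_owner.append(int(owners[i0]))

    shells: list[list] = [[] for _ in range(n_comp)]
    holes: list[list] = [[] for _ in range(n_comp)]
    for ring, owner in zip(ring_edges, ring_owner):
        ids = starts[ring]
        x = x0 + (ids % w) * ps
        y = y0 - (ids // w) * ps
        coords = np.column_stack((x, y))
        area2 = float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
        (shells if area2 > 0 else holes)[owner].append(coords)  # CCW = shell
    geoms: list[Polygon | MultiPolygon] = []
    for k in range(n_comp):
        if len(shells[k]) == 1:
            geom: Polygon | MultiPolygon = Polygon(shells[k][0], holes[k])
        else:
            shell_polys = [Polygon(s) for s in shells[k]]
            if holes[k]:
                grouped: list[list] = [[] for _ in shell_polys]
                for h in holes[k]:
                    probe = Polygon(h).representative_point()
                    for gi, sp in enumerate(shell_polys):
                        if sp.contains(probe):
                            grouped[gi].append(h)
                            break
                shell_polys = [Polygon(s, g) for s, g in zip(shells[k], grouped)]
            geom = MultiPolygon(shell_polys)
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
        geoms.append(geom)
    return geoms


def polygonize(
    segmentation: Segmentation,
    buildings: Sequence[Polygon | MultiPolygon] = (),
) -> list[LandCoverPolygon]:
    """Turn a label grid into GIS polygons, one per 4-connected component.

    Component boundaries are traced exactly along pixel edges, so the total
    polygon area equals the non-nodata raster area (area is conserved through
    vectorization).  Building footprints, if given, are appended as polygons
    pre-labeled ``Structures`` with ``cluster_id = -1``.  Raises
    ``ValueError`` on an empty grid.
    """
    labels = segmentation.labels
    if labels.size == 0 or not np.any(labels >= 0):
        raise ValueError("label grid is empty; nothing to polygonize")
    # one global component id per 4-connected equal-label region
    comp = np.full(labels.shape, -1, dtype=np.int64)
    comp_label: list[int] = []
    offset = 0
    for lab in np.unique(labels[labels >= 0]):
        lab_comp, n_comp = ndimage.label(labels == lab, structure=_CROSS)
        sel = lab_comp > 0
        comp[sel] = lab_comp[sel] - 1 + offset
        comp_label.extend([int(lab)] * n_comp)
        offset += n_comp
    geoms = _trace_component_polygons(comp, offset, segmentation.origin,
                                      segmentation.pixel_size)
    out = [
        LandCoverPolygon(geometry=g, cluster_id=comp_label[cid])
        for cid, g in enumerate(geoms)
    ]
    for b in buildings:
        if b is None or b.is_empty:
            continue
        out.append(LandCoverPolygon(geometry=b, landcover="Structures", cluster_id=-1))
    return out


def flag_green(
    polygons: Iterable[LandCoverPolygon],
    cluster_colors: np.ndarray,
    config: SegmentationConfig | None = None,
    overrides: Mapping[int, bool] | None = None,
) -> list[LandCoverPolygon]:
    """Flag vegetation polygons from their cluster's mean color.

    A cluster is green when its mean green band exceeds both the red and the
    blue band by at least ``green_margin``.  ``overrides`` maps cluster ids to
    explicit flags and wins regardless of color (the programmatic stand-in for
    choosing the green cluster(s) by eye).
    """
    config = config or SegmentationConfig()
    overrides = dict(overrides or {})
    green_by_color = {
        i: (c[1] > c[0] + config.green_margin and c[1] > c[2] + config.green_margin)
        for i, c in enumerate(np.asarray(cluster_colors))
    }
    out = []
    for p in polygons:
        flag = overrides.get(p.cluster_id, green_by_color.get(p.cluster_id, False))
        out.append(
            LandCoverPolygon(p.geometry, landcover=p.landcover, is_green=bool(flag),
                             cluster_id=p.cluster_id)
        )
    return out


def assign_labels(
    polygons: Sequence[LandCoverPolygon],
    label_table: Mapping[int, str],
) -> LandCoverMap:
    """Apply land-cover class labels from a cluster-to-class table.

    Every polygon must end up labeled: polygons already labeled (re-inserted
    buildings) keep their label, all others take the table entry for their
    cluster id.  Raises ``ValueError`` listing the offending cluster ids when
    any polygon is left unlabeled, or naming the valid classes when the table
    contains an unknown class string.
    """
    bad = sorted(set(label_table.values()) - set(BASE_CLASSES))
    if bad:
        raise ValueError(
            f"unknown land-cover classes {bad}; valid labels: {list(BASE_CLASSES)}"
        )
    labeled = []
    missing: set[int] = set()
    for p in polygons:
        cls = p.landcover if p.landcover is not None else label_table.get(p.cluster_id)
        if cls is None:
            missing.add(p.cluster_id)
            continue
        labeled.append(LandCoverPolygon(p.geometry, landcover=cls, is_green=p.is_green,
                                        cluster_id=p.cluster_id))
    if missing:
        raise ValueError(f"no land-cover label for cluster ids {sorted(missing)}")
    return LandCoverMap(labeled)


def label_table_from_truth(
    polygons: Sequence[LandCoverPolygon], truth: LandCoverMap
) -> dict[int, str]:
    """Build a cluster-to-class table by majority area overlap with a ground
    truth map (used to close the loop on synthetic imagery; replaces the
    manual labeling pass)."""
    table: dict[int, str] = {}
    clusters = sorted({p.cluster_id for p in polygons if p.landcover is None})
    for cid in clusters:
        geom = unary_union([p.geometry for p in polygons if p.cluster_id == cid])
        best_cls, best_area = None, -1.0
        for cls in BASE_CLASSES:
            tgeom = truth.class_geometry(cls)
            if tgeom.is_empty:
                continue
            a = geom.intersection(tgeom).area
            if a > best_area:
                best_cls, best_area = cls, a
        if best_cls is None:
            raise ValueError(f"cluster {cid} does not overlap the truth map")
        table[cid] = best_cls
    return table


def clip_to_region(lc_map: LandCoverMap, region: Polygon | MultiPolygon) -> LandCoverMap:
    """Intersect a land-cover map with a query region.

    The clipped class areas sum to the area of ``region`` intersected with the
    mapped extent.  An empty intersection yields an empty map with a warning.
    """
    if region.is_empty or not region.is_valid:
        raise ValueError("clip region must be a valid non-empty polygon")
    out = []
    for p in lc_map.polygons:
        inter = p.geometry.intersection(region)
        if inter.is_empty:
            continue
        if inter.geom_type == "GeometryCollection":
            polys = [g for g in inter.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
            if not polys:
                continue
            inter = unary_union(polys)
        if inter.geom_type not in ("Polygon", "MultiPolygon") or inter.area == 0:
            continue
        out.append(LandCoverPolygon(inter, landcover=p.landcover, is_green=p.is_green,
                                    cluster_id=p.cluster_id))
    if not out:
        warnings.warn("clip region does not overlap the land-cover map", stacklevel=2)
    return LandCoverMap(out)


def segment_image(
    img: RGBImage,
    buildings: Sequence[Polygon | MultiPolygon] = (),
    config: SegmentationConfig | None = None,
    label_table: Mapping[int, str] | None = None,
    green_overrides: Mapping[int, bool] | None = None,
) -> tuple[list[LandCoverPolygon], Segmentation] | LandCoverMap:
    """Run the full imagery workflow: mask, denoise, segment, polygonize, flag.

    When ``label_table`` is given the result is a complete ``LandCoverMap``;
    otherwise the unlabeled polygons and the segmentation are returned so a
    labeling table can be built (e.g. with :func:`label_table_from_truth`).
    """
    config = config or SegmentationConfig()
    masked = mask_buildings(img, buildings)
    smoothed = denoise(masked, config)
    seg = kmeans_segment(smoothed, config)
    polys = polygonize(seg, buildings=buildings)
    polys = flag_green(polys, seg.cluster_colors, config, overrides=green_overrides)
    if label_table is None:
        return polys, seg
    return assign_labels(polys, label_table)
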