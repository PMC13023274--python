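"""Equal-area-circle null model and range-bias statistics.

A cat's realized roaming area (AOI) is compared with an "equal-area circle":
a circle centered at the coordinate-wise median of the cleaned fixes whose
area equals the AOI's.  The circle represents isotropic, non-selective
roaming around the activity center.  For each land-cover class the range bias
is the difference (area in AOI) - (area in circle); positive bias means the
class is over-represented in the realized range.  Cohort-level inference uses
paired tests on log-transformed areas (paired t when the paired differences
pass a normality check, Wilcoxon signed-rank otherwise), plus group and
covariate tests on AOI size.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import MultiPolygon, Point, Polygon

from .types import (
    BASE_CLASSES,
    CoverageError,
    DERIVED_COMPOSITION,
    DERIVED_ROWS,
    EqualAreaCircle,
    FixSet,
    LandCoverMap,
)

logger = logging.getLogger(__name__)

#: Number of segments used to discretize circles.  A regular 256-gon has a
#: relative area error of about 8e-5, well under the 1e-3 bookkeeping
#: tolerance used throughout.
CIRCLE_SEGMENTS = 256

#: All accounting rows: the six base classes plus derived groupings.
ALL_ROWS: tuple[str, ...] = BASE_CLASSES + DERIVED_ROWS

_REL_TOL = 1e-3


def radius_for_area(area_m2: float) -> float:
    """Radius (m) of the circle with the given area (m^2): sqrt(area / pi)."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    return math.sqrt(area_m2 / math.pi)


def equal_area_circle(fix_set: FixSet | np.ndarray, aoi_area_m2: float) -> EqualAreaCircle:
    """Construct the isotropic-null circle for a cat.

    The circle is centered at the coordinate-wise median of the inlier fixes
    and has area equal to the AOI's.  ``fix_set`` may be a FixSet (its inlier
    fixes are used) or an (n, 2) coordinate array.
    """
    if aoi_area_m2 <= 0:
        raise ValueError("AOI area must be positive")
    xy = fix_set.inlier_xy() if isinstance(fix_set, FixSet) else np.asarray(fix_set, float)
    if xy.ndim != 2 or xy.shape[0] < 1 or xy.shape[1] != 2:
        raise ValueError("need at least one inlier fix with (x, y) coordinates")
    center = (float(np.median(xy[:, 0])), float(np.median(xy[:, 1])))
    radius = radius_for_area(aoi_area_m2)
    poly = Point(center).buffer(radius, quad_segs=CIRCLE_SEGMENTS // 4)
    return EqualAreaCircle(center=center, radius=radius, polygon=poly)


def class_areas(lc_map: LandCoverMap, region: Polygon | MultiPolygon) -> pd.Series:
    """Per-class areas (m^2) of a query region, with derived grouping rows.

    Base-class areas are intersections of the region with each class's
    polygons; derived rows are Green / Not green (from the vegetation flag)
    and the open-area groupings.  Raises ``CoverageError`` when the map covers
    less than 99.9% of the region.
    """
    region_area = region.area
    if region_area <= 0:
        raise ValueError("query region has zero area")
    out = pd.Series(0.0, index=list(ALL_ROWS))
    # map polygons have disjoint interiors, so per-class intersection areas
    # are additive over polygons; no unions needed
    geoms = np.array([p.geometry for p in lc_map.polygons], dtype=object)
    shapely.prepare(region)
    candidates = np.flatnonzero(shapely.intersects(region, geoms))
    areas = shapely.area(shapely.intersection(geoms[candidates], region))
    for idx, a in zip(candidates, areas):
        if a <= 0:
            continue
        p = lc_map.polygons[idx]
        if p.landcover is not None:
            out[p.landcover] += a
        if p.is_green:
            out["Green"] += a
    covered = sum(out[c] for c in BASE_CLASSES)
    uncovered = 1.0 - covered / region_area
    if uncovered > _REL_TOL:
        raise CoverageError(
            f"land-cover map leaves {uncovered:.2%} of the query region uncovered"
        )
    out["Not green"] = covered - out["Green"]
    for row, members in DERIVED_COMPOSITION.items():
        out[row] = sum(out[m] for m in members)
    return out


def range_bias(aoi_table: pd.DataFrame, circle_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cat, per-class range bias: area in AOI minus area in circle (m^2).

    Tables are indexed by cat id with one column per accounting row.  Cats
    missing from either table are skipped with a warning.  Because AOI and
    circle have equal total area, each cat's six base-class biases sum to
    zero up to discretization tolerance.
    """
    common = aoi_table.index.intersection(circle_table.index)
    dropped = set(aoi_table.index).symmetric_difference(circle_table.index)
    for cat in sorted(dropped):
        warnings.warn(f"cat {cat!r} missing an AOI or circle row; skipped", stacklevel=2)
    return aoi_table.loc[common] - circle_table.loc[common]


# ---------------------------------------------------------------------------
# Paired comparisons (the land-cover preference test)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of one class's AOI-vs-circle paired comparison.

    ``statistic`` is the paired-t statistic or, for the signed-rank test, the
    centered signed-rank S = R+ - n(n+1)/4 (R+ = sum of ranks of positive
    differences, zeros dropped); ``z`` additionally reports the signed-rank
    normal approximation.  Means are of ln(area_m2 + 1).
    """

    variable: str
    n: int
    circle_mean: float
    aoi_mean: float
    test: str  # "paired t" | "wilcoxon" | "insufficient data"
    statistic: float
    z: float | None
    p: float
    mean_bias_m2: float


def _log_area(a: np.ndarray) -> np.ndarray:
    return np.log(a + 1.0)


def _signed_rank(d: np.ndarray) -> tuple[float, float]:
    """Centered signed-rank statistic S and its normal approximation z."""
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 0.0
    ranks = stats.rankdata(np.abs(d))
    r_plus = float(ranks[d > 0].sum())
    s = r_plus - n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    z = s / math.sqrt(var) if var > 0 else 0.0
    return s, z


def paired_compare(
    aoi_table: pd.DataFrame,
    circle_table: pd.DataFrame,
    variable: str,
    alpha_normality: float = 0.05,
    min_pairs: int = 5,
) -> PairedTestResult:
    """Paired AOI-vs-circle test for one accounting row.

    Areas are transformed as ln(area_m2 + 1).  A cat contributes a pair only
    when the class is present (positive area) in its AOI or its circle, which
    is what makes per-class n vary across rare classes.  The paired
    differences are tested for normality (Shapiro-Wilk at
    ``alpha_normality``): normal differences get a paired t-test, otherwise a
    Wilcoxon signed-rank test with zero differences dropped.  Fewer than
    ``min_pairs`` usable pairs yields an "insufficient data" result rather
    than an exception; identically zero differences yield statistic 0 and
    p = 1.
    """
    common = aoi_table.index.intersection(circle_table.index)
    a = aoi_table.loc[common, variable].to_numpy(dtype=float)
    c = circle_table.loc[common, variable].to_numpy(dtype=float)
    present = (a > 0) | (c > 0)
    a, c = a[present], c[present]
    n = len(a)
    mean_bias = float(np.mean(a - c)) if n else float("nan")
    la, lc = _log_area(a), _log_area(c)
    if n < min_pairs:
        return PairedTestResult(variable, n, float(np.mean(lc)) if n else float("nan"),
                                float(np.mean(la)) if n else float("nan"),
                                "insufficient data", float("nan"), None, float("nan"),
                                mean_bias)
    d = la - lc
    if np.all(d == 0):
        return PairedTestResult(variable, n, float(lc.mean()), float(la.mean()),
                                "wilcoxon", 0.0, 0.0, 1.0, mean_bias)
    if np.ptp(d) > 0:
        normal = stats.shapiro(d).pvalue > alpha_normality
    else:
        normal = False  # constant nonzero differences: no variance for a t-test
    if normal:
        t = stats.ttest_rel(la, lc)
        return PairedTestResult(variable, n, float(lc.mean()), float(la.mean()),
                                "paired t", float(t.statistic), None, float(t.pvalue),
                                mean_bias)
    nz = d[d != 0]
    if len(nz) == 0:
        return PairedTestResult(variable, n, float(lc.mean()), float(la.mean()),
                                "wilcoxon", 0.0, 0.0, 1.0, mean_bias)
    res = stats.wilcoxon(nz, zero_method="wilcox")
    s, z = _signed_rank(d)
    return PairedTestResult(variable, n, float(lc.mean()), float(la.mean()),
                            "wilcoxon", s, z, float(res.pvalue), mean_bias)


def compare_all_classes(
    aoi_table: pd.DataFrame,
    circle_table: pd.DataFrame,
    rows: tuple[str, ...] = ALL_ROWS,
    holm: bool = False,
) -> pd.DataFrame:
    """Paired comparison for every accounting row, shaped like a results table.

    Returns one row per land-cover variable with n, the circle and AOI means
    of ln(area+1), the chosen test, its statistic and p-value.  With
    ``holm=True`` an extra column of Holm-adjusted p-values is included
    (unadjusted p-values are always reported).
    """
    results = [paired_compare(aoi_table, circle_table, v) for v in rows]
    frame = pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "n": [r.n for r in results],
            "circle_mean": [r.circle_mean for r in results],
            "aoi_mean": [r.aoi_mean for r in results],
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "z": [r.z for r in results],
            "p": [r.p for r in results],
            "mean_bias_m2": [r.mean_bias_m2 for r in results],
        }
    ).set_index("variable")
    if holm:
        valid = frame["p"].notna()
        padj = pd.Series(np.nan, index=frame.index)
        ps = frame.loc[valid, "p"].sort_values()
        m = len(ps)
        adj = np.minimum.accumulate(((m - np.arange(m)) * ps.to_numpy())[::-1])[::-1]
        padj.loc[ps.index] = np.minimum(adj, 1.0)
        frame["p_holm"] = padj
    return frame


# ---------------------------------------------------------------------------
# Group and covariate tests on AOI size
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupTestResult:
    """Mann-Whitney comparison of AOI size between two cat groups."""

    test: str
    statistic: float
    p: float
    n_with: int
    n_without: int
    mean_with: float
    mean_without: float
    median_with: float
    median_without: float
    n_excluded: int


def natural_area_group_test(
    aoi_table: pd.DataFrame, aoi_areas: pd.Series
) -> GroupTestResult:
    """Does having natural open areas in the AOI go with larger roaming areas?

    Cats whose AOI contains any Agriculture are excluded first (agricultural
    open space is structurally different and rare).  The remaining cats split
    into those whose AOI contains Open urban natural or Natural versus those
    with neither, and AOI areas are compared with a Mann-Whitney U test.
    Returns an "insufficient data" result when either group is empty.
    """
    cats = aoi_table.index.intersection(aoi_areas.index)
    tab = aoi_table.loc[cats]
    areas = aoi_areas.loc[cats]
    keep = tab["Agriculture"] <= 0
    n_excluded = int((~keep).sum())
    tab, areas = tab.loc[keep], areas.loc[keep]
    has_natural = (tab["Open urban natural"] > 0) | (tab["Natural"] > 0)
    a = areas[has_natural].to_numpy(dtype=float)
    b = areas[~has_natural].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        return GroupTestResult("insufficient data", float("nan"), float("nan"),
                               len(a), len(b), float("nan"), float("nan"),
                               float("nan"), float("nan"), n_excluded)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupTestResult(
        "Mann-Whitney U", float(res.statistic), float(res.pvalue),
        len(a), len(b), float(a.mean()), float(b.mean()),
        float(np.median(a)), float(np.median(b)), n_excluded,
    )


def covariate_tests(metadata: pd.DataFrame, aoi_areas: pd.Series) -> dict[str, dict]:
    """Effects of sex, season and age on AOI size.

    Sex and season use the Wilcoxon rank-sum test (normal-approximation Z);
    age uses a Spearman correlation.  ``metadata`` is indexed by cat id with
    columns ``sex`` (F/M), ``season`` (winter/summer) and ``age`` (years).
    Constant covariates are skipped with a warning.
    """
    cats = metadata.index.intersection(aoi_areas.index)
    meta = metadata.loc[cats]
    areas = aoi_areas.loc[cats].to_numpy(dtype=float)
    out: dict[str, dict] = {}
    for covar, (lo, hi) in (("sex", ("F", "M")), ("season", ("winter", "summer"))):
        values = meta[covar].to_numpy()
        if len(set(values)) < 2:
            warnings.warn(f"covariate {covar!r} is constant; test skipped", stacklevel=2)
            out[covar] = {"test": "skipped (constant covariate)"}
            continue
        res = stats.ranksums(areas[values == lo], areas[values == hi])
        out[covar] = {
            "test": "Wilcoxon rank-sum",
            "groups": f"{lo} vs {hi}",
            "z": float(res.statistic),
            "p": float(res.pvalue),
        }
    ages = meta["age"].to_numpy(dtype=float)
    if np.ptp(ages) == 0:
        warnings.warn("covariate 'age' is constant; test skipped", stacklevel=2)
        out["age"] = {"test": "skipped (constant covariate)"}
    else:
        rho, p = stats.spearmanr(ages, areas)
        out["age"] = {"test": "Spearman correlation", "rho": float(rho), "p": float(p)}
    return out
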