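"""End-to-end pipeline: fixes -> cleaning -> AOI -> null circle -> statistics.

The per-cat stage chain is: drop the acclimation day, reject outlier fixes
with the one-class SVM, delineate the AOI (convex hull), build the equal-area
circle at the median fix, and account class areas inside both regions.  The
cohort stage then runs the paired land-cover comparisons, the natural-open-
area group test and the sex/season/age covariate tests.  Per-cat failures are
quarantined and reported; cohort statistics run on the survivors.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io as crio
from .bias import (
    GroupTestResult,
    class_areas,
    compare_all_classes,
    covariate_tests,
    equal_area_circle,
    natural_area_group_test,
    range_bias,
)
from .cleaning import CleaningConfig, delineate_aoi, drop_acclimation_day, filter_outliers
from .landcover import SegmentationConfig
from .simulate import SimulatedCat
from .types import AOIPolygon, EqualAreaCircle, FixSet, LandCoverMap, SessionMetadata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of the whole pipeline.

    Statistical options: ``alpha`` is the significance level used when
    summarising tests, ``holm`` switches on Holm-adjusted p-values alongside
    the unadjusted ones.  ``drop_first_day`` applies the acclimation-day
    exclusion (on by default; single-day streams are quarantined).
    """

    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    alpha: float = 0.05
    holm: bool = False
    drop_first_day: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, obj: Mapping) -> "PipelineConfig":
        obj = dict(obj or {})
        cleaning = CleaningConfig(**obj.pop("cleaning", {}))
        segmentation = SegmentationConfig(**obj.pop("segmentation", {}))
        return cls(cleaning=cleaning, segmentation=segmentation, **obj)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return {
            "cleaning": dataclasses.asdict(self.cleaning),
            "segmentation": dataclasses.asdict(self.segmentation),
            "alpha": self.alpha,
            "holm": self.holm,
            "drop_first_day": self.drop_first_day,
            "seed": self.seed,
        }


@dataclass
class CatResult:
    """Everything the pipeline derives for one cat."""

    cat_id: str
    fix_set: FixSet  # cleaned, with inlier mask
    aoi: AOIPolygon
    circle: EqualAreaCircle
    aoi_areas: pd.Series
    circle_areas: pd.Series


@dataclass
class PipelineResult:
    """Results bundle for a cohort run."""

    per_cat: list[CatResult]
    summary: pd.DataFrame  # per-cat bookkeeping: fix counts, areas, radius
    aoi_table: pd.DataFrame  # cats x accounting rows, areas in AOI (m^2)
    circle_table: pd.DataFrame  # cats x accounting rows, areas in circle (m^2)
    bias_table: pd.DataFrame  # AOI minus circle
    landcover_tests: pd.DataFrame  # paired comparisons per accounting row
    group_test: GroupTestResult
    covariates: dict[str, dict]
    failures: list[dict]
    run_log: list[dict]
    config: PipelineConfig

    def write(self, out_dir: str | Path) -> None:
        """Write the bundle: CSV tables, GeoJSON regions, JSON reports."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "per_cat_summary.csv")
        self.aoi_table.to_csv(out / "aoi_class_areas.csv")
        self.circle_table.to_csv(out / "circle_class_areas.csv")
        self.bias_table.to_csv(out / "range_bias.csv")
        self.landcover_tests.to_csv(out / "landcover_tests.csv")
        crio.write_json(dataclasses.asdict(self.group_test), out / "group_test.json")
        crio.write_json(self.covariates, out / "covariate_tests.json")
        crio.write_json({"failures": self.failures, "log": self.run_log,
                         "config": self.config.to_dict()}, out / "run_log.json")
        regions = out / "regions"
        regions.mkdir(exist_ok=True)
        for r in self.per_cat:
            crio.write_aoi_geojson(r.aoi, regions / f"{r.cat_id}_aoi.geojson")


def analyze_cat(
    fix_set: FixSet, landscape: LandCoverMap, config: PipelineConfig | None = None
) -> CatResult:
    """Run the per-cat stage chain on one fix stream and its land-cover map."""
    config = config or PipelineConfig()
    if config.drop_first_day:
        fix_set = drop_acclimation_day(fix_set)
    cleaned = filter_outliers(fix_set, config.cleaning)
    aoi = delineate_aoi(cleaned)
    circle = equal_area_circle(cleaned, aoi.area_m2)
    return CatResult(
        cat_id=cleaned.cat_id,
        fix_set=cleaned,
        aoi=aoi,
        circle=circle,
        aoi_areas=class_areas(landscape, aoi.polygon),
        circle_areas=class_areas(landscape, circle.polygon),
    )


def _as_record(cat) -> tuple[FixSet, LandCoverMap, SessionMetadata | None]:
    if isinstance(cat, SimulatedCat):
        return cat.fix_set, cat.landscape, cat.metadata
    fix_set, landscape = cat[0], cat[1]
    meta = cat[2] if len(cat) > 2 else None
    return fix_set, landscape, meta


def analyze_cohort(
    cats: Sequence[SimulatedCat | tuple], config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full pipeline on an in-memory cohort.

    ``cats`` holds (FixSet, LandCoverMap, SessionMetadata) triples (or
    ``SimulatedCat`` records).  Cats whose per-cat stage fails are quarantined
    with the failing stage and message; cohort statistics use the survivors.
    """
    if len(cats) == 0:
        raise ValueError("cohort is empty")
    config = config or PipelineConfig()
    results: list[CatResult] = []
    metas: dict[str, SessionMetadata] = {}
    failures: list[dict] = []
    run_log: list[dict] = []
    for cat in cats:
        fix_set, landscape, meta = _as_record(cat)
        try:
            res = analyze_cat(fix_set, landscape, config)
        except Exception as exc:  # quarantine, keep going
            failures.append({"cat_id": fix_set.cat_id, "error": str(exc),
                             "stage": type(exc).__name__})
            logger.warning("cat %s quarantined: %s", fix_set.cat_id, exc)
            continue
        results.append(res)
        if meta is not None:
            metas[res.cat_id] = meta
        run_log.append(
            {
                "cat_id": res.cat_id,
                "n_fixes_raw": len(fix_set),
                "n_after_cleaning": int(res.fix_set.inlier_mask.sum()),
                "aoi_area_ha": res.aoi.area_ha,
                "circle_radius_m": res.circle.radius,
                "seed": config.seed,
            }
        )
    if not results:
        raise ValueError("every cat failed the per-cat pipeline; nothing to analyze")
    ids = [r.cat_id for r in results]
    aoi_table = pd.DataFrame([r.aoi_areas for r in results], index=ids)
    circle_table = pd.DataFrame([r.circle_areas for r in results], index=ids)
    summary = pd.DataFrame(
        {
            "n_fixes": [len(r.fix_set) for r in results],
            "n_inliers": [int(r.fix_set.inlier_mask.sum()) for r in results],
            "aoi_area_ha": [r.aoi.area_ha for r in results],
            "circle_radius_m": [r.circle.radius for r in results],
        },
        index=pd.Index(ids, name="cat_id"),
    )
    aoi_areas = summary["aoi_area_ha"] * 10_000.0
    tests = compare_all_classes(aoi_table, circle_table, holm=config.holm)
    group = natural_area_group_test(aoi_table, aoi_areas)
    if metas:
        meta_frame = pd.DataFrame(
            {
                "sex": {k: m.sex for k, m in metas.items()},
                "season": {k: m.season for k, m in metas.items()},
                "age": {k: m.age for k, m in metas.items()},
            }
        )
        covars = covariate_tests(meta_frame, aoi_areas)
    else:
        covars = {}
    return PipelineResult(
        per_cat=results,
        summary=summary,
        aoi_table=aoi_table,
        circle_table=circle_table,
        bias_table=range_bias(aoi_table, circle_table),
        landcover_tests=tests,
        group_test=group,
        covariates=covars,
        failures=failures,
        run_log=run_log,
        config=config,
    )


def run_pipeline(
    manifest: str | Path | pd.DataFrame, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the pipeline from a cohort manifest of on-disk inputs.

    The manifest (CSV path or pre-validated frame from
    :func:`catrange.io.read_manifest`) references per-cat fix CSVs and
    land-cover GeoJSONs plus metadata columns.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = crio.read_manifest(manifest)
    cats = []
    for cat_id, row in manifest.iterrows():
        fix_set = crio.read_fixes_csv(row["fixes"])
        landscape = crio.read_landcover_geojson(row["landcover"])
        meta = SessionMetadata(
            cat_id=str(cat_id), sex=str(row["sex"]), age=int(row["age"]),
            season=str(row["season"]),
        )
        cats.append((fix_set, landscape, meta))
    return analyze_cohort(cats, config)
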