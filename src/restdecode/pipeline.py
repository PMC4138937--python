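"""End-to-end orchestration: simulate -> fALFF -> select -> decode -> report.

A run is driven by one :class:`RunConfig` (optionally read from YAML)
and writes a self-contained artifact directory:

    config.yaml            frozen resolved configuration
    features_EC.tsv        subjects x ROIs normalized fALFF, eyes closed
    features_EO.tsv        ... eyes open
    zscores.tsv            per-ROI signed-rank Z report + selection flags
    pattern_<crit>.tsv     one file per non-empty criterion
    decoding_results.tsv   criterion / n_rois / seed / accuracy / auc
    roc_<crit>.tsv         FPR-TPR points per criterion (first seed)
    manifest.tsv           subject_id, condition for every recording
    run.log                stage log with versions and seeds

All tabular output is TSV (UTF-8, header row); reruns with the same
config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decode import run_criterion_comparison
from .falff import FalffExtractor, falff_feature_table
from .selection import (
    RoiZScores,
    module_composition,
    score_all_rois,
    select_pattern,
    study_criteria,
)
from .simulate import SimulationConfig, simulate_cohort
from .template import RoiTemplate, generate_roi_template

logger = logging.getLogger("restdecode")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    template_source: str = "dosenbach160"
    roi_radius: float = 5.0
    low_band: tuple[float, float] = (0.01, 0.08)
    svm_regularization: float = 1.0
    split_seed: int = 0
    output_dir: str = "restdecode_run"
    mode: str = "roi"  # 'roi' | 'volumetric'
    nested_audit: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("roi", "volumetric"):
            raise ValueError("mode must be 'roi' or 'volumetric'")
        if self.svm_regularization <= 0:
            raise ValueError("svm_regularization must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**{k: (tuple(v) if k == "effect_rois" and v is not None else v)
                                  for k, v in (raw.pop("simulation", {}) or {}).items()})
        if "low_band" in raw:
            raw["low_band"] = tuple(raw["low_band"])
        return cls(simulation=sim, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["low_band"] = list(self.low_band)
        if d["simulation"]["effect_rois"] is not None:
            d["simulation"]["effect_rois"] = list(d["simulation"]["effect_rois"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _setup_logging(out: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(out / "run.log")):
        h.setFormatter(fmt)
        logger.addHandler(h)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a manifest dict of written artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    logger.info("restdecode %s | seed=%d split_seed=%d mode=%s",
                __version__, config.simulation.seed, config.split_seed, config.mode)
    config.to_yaml(out / "config.yaml")
    artifacts: dict[str, str] = {"config": str(out / "config.yaml")}

    stage = "template"
    try:
        template = generate_roi_template(config.template_source, radius=config.roi_radius)
        logger.info("template: %d ROIs from %s", len(template), config.template_source)

        stage = "simulate"
        cohort = simulate_cohort(config.simulation, template)
        logger.info("cohort: %d recordings (%d subjects x 2 conditions)",
                    len(cohort), config.simulation.n_subjects)
        manifest = pd.DataFrame({"subject_id": [r.subject_id for r in cohort],
                                 "condition": [r.condition for r in cohort]})
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        artifacts["manifest"] = str(out / "manifest.tsv")

        stage = "falff"
        extractor = FalffExtractor(tr=config.simulation.tr, low_band=config.low_band,
                                   n_discard=config.simulation.n_discard)
        if config.mode == "volumetric":
            tables = _volumetric_feature_tables(cohort, template, config, extractor)
        else:
            tables = falff_feature_table(cohort, template, extractor)
        for cond, df in tables.items():
            p = out / f"features_{cond}.tsv"
            df.to_csv(p, sep="\t", float_format="%.10g")
            artifacts[f"features_{cond}"] = str(p)
        logger.info("fALFF feature tables written (%d x %d)",
                    *tables["EC"].shape)

        stage = "selection"
        scores = score_all_rois(tables["EC"], tables["EO"], template)
        scores.to_frame().to_csv(out / "zscores.tsv", sep="\t", index=False,
                                 float_format="%.6g")
        artifacts["zscores"] = str(out / "zscores.tsv")
        for crit in study_criteria():
            pattern = select_pattern(scores, crit)
            logger.info("criterion %s: %d ROIs", crit.label, len(pattern))
            if len(pattern):
                p = out / f"pattern_{crit.name}.tsv"
                pattern.to_frame().to_csv(p, sep="\t", index=False, float_format="%.6g")
                artifacts[f"pattern_{crit.name}"] = str(p)

        stage = "decode"
        summary, results = run_criterion_comparison(
            tables["EC"], tables["EO"], scores,
            split_seeds=[config.split_seed],
            regularization=config.svm_regularization,
            nested=config.nested_audit,
        )
        summary.to_csv(out / "decoding_results.tsv", sep="\t", index=False,
                       float_format="%.6g")
        artifacts["decoding_results"] = str(out / "decoding_results.tsv")
        for name, rlist in results.items():
            if rlist:
                p = out / f"roc_{name}.tsv"
                pd.DataFrame(rlist[0].roc_points, columns=["fpr", "tpr"]).to_csv(
                    p, sep="\t", index=False, float_format="%.6g")
                artifacts[f"roc_{name}"] = str(p)
        for _, row in summary.iterrows():
            logger.info("decode %-12s n_rois=%-3d accuracy=%5.1f%% auc=%.3f",
                        row["criterion"], row["n_rois"], row["accuracy"], row["auc"])
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts


def _volumetric_feature_tables(cohort, template, config: RunConfig,
                               extractor: FalffExtractor) -> dict[str, pd.DataFrame]:
    from .falff import roi_aggregate
    from .volume import default_affine, falff_volume, paint_recording

    shape, affine = default_affine(template)
    by_cond: dict[str, dict[str, np.ndarray]] = {"EC": {}, "EO": {}}
    for rec in cohort:
        vol, _ = paint_recording(rec, template, shape, affine)
        fmap = falff_volume(vol, rec.tr,
                            n_discard=config.simulation.n_discard,
                            fwhm_mm=6.0, voxel_size_mm=float(affine[0, 0]))
        by_cond[rec.condition][rec.subject_id] = roi_aggregate(fmap, template, affine)
    out = {}
    for cond, d in by_cond.items():
        df = pd.DataFrame.from_dict(d, orient="index", columns=template.roi_names)
        df.index.name = "subject_id"
        out[cond] = df.sort_index()
    return out


# ---------------------------------------------------------------- fixture


def validate_against_fixture() -> tuple[bool, pd.DataFrame]:
    """Check every published-table-derived count the package relies on.

    Applies the four selection criteria to the 28 published Z values
    and checks pattern sizes, the sensorimotor share of the Z > 1.96
    pattern, module counts among positive rows, and the disjoint-union
    property.  Returns ``(all_ok, report)``; the report lists each
    check with expected/observed values.
    """
    from .template import table1_template

    template = table1_template()
    scores = RoiZScores.from_template(template)
    checks: list[dict] = []

    def check(name: str, expected, observed) -> None:
        checks.append({"check": name, "expected": expected, "observed": observed,
                       "ok": expected == observed})

    sizes = {}
    for crit in study_criteria():
        pattern = select_pattern(scores, crit)
        sizes[crit.name] = len(pattern)
    check("n(|Z|>1.96)", 28, sizes["abs_gt"])
    check("n(Z>1.96)", 21, sizes["pos_gt"])
    check("n(Z>2.25)", 13, sizes["pos_gt_strict"])
    check("n(Z<-1.96)", 7, sizes["neg_lt"])
    check("disjoint union", sizes["abs_gt"], sizes["pos_gt"] + sizes["neg_lt"])

    pos = select_pattern(scores, study_criteria()[1])
    comp = module_composition(pos)
    check("sensorimotor count in Z>1.96", 18, int(comp.loc["sensorimotor", "count"]))
    check("sensorimotor share in Z>1.96 (%)", 86,
          int(round(comp.loc["sensorimotor", "percent"])))
    check("positive-row modules",
          {"sensorimotor": 18, "default": 1, "cingulo-opercular": 2},
          {k: int(v) for k, v in comp["count"].items()})
    report = pd.DataFrame(checks)
    return bool(report["ok"].all()), report
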