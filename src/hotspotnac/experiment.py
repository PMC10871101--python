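"""End-to-end experiment orchestration.

Runs the full pipeline — register IHC channels onto the H&E frame,
phenotype tumor cells, tile regions into patches, select hotspots under
each metric, split patients, grid-search the classifier, predict and
evaluate — across the metric x feature-configuration grid, with one
shared patient split per seed so the grid cells are directly comparable.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import pandas as pd

from . import evaluation
from .cohort import (
    CHANNEL_HE,
    CHANNEL_KI67,
    CHANNEL_PH3,
    ClassRates,
    CohortSpec,
    MisalignmentTransform,
    SyntheticCohort,
    default_rates,
    generate_cohort,
)
from .exceptions import ValidationError
from .hotspots import COUNT_COLUMNS, DEFAULT_K, METRICS, build_patch_grid, hotspot_feature_table
from .phenotyping import DEFAULT_RADIUS_PX, phenotype_cohort_detections
from .registration import estimate_transform
from .response import HotspotResponseModel, stratified_split

__all__ = [
    "DEFAULT_FEATURE_CONFIGS",
    "ExperimentConfig",
    "ExperimentResult",
    "register_cohort",
    "prepare_patches",
    "run_experiment",
    "run_replicates",
]

logger = logging.getLogger(__name__)

# The feature combinations evaluated per hotspot metric: each count on its
# own informational tier — all five counts, the four biomarker/TIL counts,
# and the metric-matched single feature are the canonical comparisons.
DEFAULT_FEATURE_CONFIGS: tuple[tuple[str, ...], ...] = (
    ("tTILs", "sTILs", "P", "M", "TCs"),
    ("tTILs", "sTILs", "P", "M"),
)


@dataclass
class ExperimentConfig:
    """Configuration of one experiment grid run."""

    spec: CohortSpec = field(default_factory=CohortSpec)
    rates_pcr: ClassRates = field(default_factory=lambda: default_rates("pCR"))
    rates_rd: ClassRates = field(default_factory=lambda: default_rates("RD"))
    transform: MisalignmentTransform = field(default_factory=MisalignmentTransform)
    metrics: tuple[str, ...] = METRICS
    feature_configs: tuple[tuple[str, ...], ...] = DEFAULT_FEATURE_CONFIGS
    k: int = DEFAULT_K
    radius_px: float = DEFAULT_RADIUS_PX
    train_frac: float = 0.75
    folds: int = 3
    seed: int = 0
    register: bool = True

    def __post_init__(self) -> None:
        for m in self.metrics:
            if m not in METRICS:
                raise ValidationError(f"unknown metric {m!r}; valid: {list(METRICS)}")
        for fc in self.feature_configs:
            unknown = set(fc) - set(COUNT_COLUMNS)
            if unknown:
                raise ValidationError(
                    f"unknown features {sorted(unknown)}; valid: {COUNT_COLUMNS}"
                )
            if not fc:
                raise ValidationError("feature configs must be non-empty")


@dataclass
class ExperimentResult:
    """Summary table (one row per grid cell) plus per-cell reports."""

    summary: pd.DataFrame
    reports: dict[tuple[str, tuple[str, ...]], dict[str, evaluation.EvaluationReport]]
    split: object
    registration_reports: pd.DataFrame | None


def register_cohort(cohort: SyntheticCohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate and apply per-patient, per-channel transforms.

    For every patient and IHC channel, one similarity transform is
    estimated by ICP against the patient's H&E tumor-cell points, pooling
    all regions (correspondences stay within-region). Returns the
    registered IHC detections and a per-(patient, channel) report of the
    recovered transform and residual.
    """
    he = cohort.he_detections()
    he_tc = he[he["cell_type"] == "TC"]
    ihc_groups = {
        key: grp
        for key, grp in cohort.detections[
            cohort.detections["channel"] != CHANNEL_HE
        ].groupby(["patient_id", "channel"])
    }
    registered = []
    reports = []
    for pid, he_grp in he_tc.groupby("patient_id"):
        ref_pts = he_grp[["x", "y"]].to_numpy()
        ref_regions = he_grp["region_id"].to_numpy()
        for channel in (CHANNEL_KI67, CHANNEL_PH3):
            ihc = ihc_groups.get((pid, channel))
            if ihc is None:
                continue
            if len(ihc) < 3:
                logger.warning(
                    "patient %s channel %s has %d points; skipping registration",
                    pid,
                    channel,
                    len(ihc),
                )
                registered.append(ihc.copy())
                continue
            result = estimate_transform(
                ihc[["x", "y"]].to_numpy(),
                ref_pts,
                moving_regions=ihc["region_id"].to_numpy(),
                reference_regions=ref_regions,
            )
            mapped = result.transform.apply(ihc[["x", "y"]].to_numpy())
            out = ihc.copy()
            out["x"] = mapped[:, 0]
            out["y"] = mapped[:, 1]
            registered.append(out)
            reports.append(
                {
                    "patient_id": pid,
                    "channel": channel,
                    "rotation": result.transform.rotation,
                    "scale": result.transform.scale,
                    "tx": result.transform.tx,
                    "ty": result.transform.ty,
                    "residual_px": result.residual,
                    "n_iter": result.n_iter,
                    "converged": result.converged,
                }
            )
    reg_df = (
        pd.concat(registered, ignore_index=True)
        if registered
        else cohort.detections.iloc[0:0].copy()
    )
    return reg_df, pd.DataFrame(reports)


def prepare_patches(
    cohort: SyntheticCohort,
    radius_px: float = DEFAULT_RADIUS_PX,
    register: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Registration + phenotyping + patch grid for a whole cohort.

    Returns the patch count table and the registration report (None when
    ``register`` is False, in which case IHC coordinates are trusted
    as already being in the H&E frame).
    """
    t0 = time.perf_counter()
    if register:
        ihc, reg_reports = register_cohort(cohort)
    else:
        ihc = cohort.detections[cohort.detections["channel"] != "HE"]
        reg_reports = None
    t1 = time.perf_counter()
    phenotyped = phenotype_cohort_detections(cohort.he_detections(), ihc, radius_px)
    t2 = time.perf_counter()
    regions = pd.DataFrame(
        [
            {"patient_id": pid, "region_id": rid}
            for pid in cohort.labels["patient_id"]
            for rid in range(cohort.spec.regions_per_patient)
        ]
    )
    patches = build_patch_grid(
        phenotyped, cohort.spec.region_size_px, cohort.spec.patch_size_px, regions
    )
    t3 = time.perf_counter()
    logger.info(
        "prepare_patches: registration %.2fs, phenotyping %.2fs, grid %.2fs",
        t1 - t0,
        t2 - t1,
        t3 - t2,
    )
    return patches, reg_reports


def run_experiment(
    config: ExperimentConfig, cohort: SyntheticCohort | None = None
) -> ExperimentResult:
    """Run the full metric x feature-configuration grid on one cohort.

    The cohort is generated from ``config`` unless supplied. All grid
    cells share the same patient split and CV seed so their results are
    comparable.
    """
    if cohort is None:
        cohort = generate_cohort(
            config.spec, config.rates_pcr, config.rates_rd, config.transform
        )
    patches, reg_reports = prepare_patches(cohort, config.radius_px, config.register)
    split = stratified_split(cohort.labels, config.train_frac, config.seed)
    label_map = cohort.labels.set_index("patient_id")["label"]

    rows = []
    reports: dict = {}
    for metric in config.metrics:
        cell_id = f"metric={metric}"
        try:
            table = hotspot_feature_table(patches, cohort.labels, metric, config.k)
        except Exception as exc:
            raise RuntimeError(f"hotspot stage failed for {cell_id}: {exc}") from exc
        train_tab = table[table["patient_id"].isin(split.train_ids)]
        test_tab = table[table["patient_id"].isin(split.test_ids)]
        for fc in config.feature_configs:
            cell_id = f"metric={metric}, features={'+'.join(fc)}"
            t0 = time.perf_counter()
            try:
                model = HotspotResponseModel.from_hotspots(train_tab, fc)
                results = model.fit(folds=config.folds, seed=config.seed)
                pred = results.predict(test_tab)
            except Exception as exc:
                raise RuntimeError(f"classifier stage failed for {cell_id}: {exc}") from exc

            patch_truth = test_tab["label"].to_numpy()
            patch_rep = evaluation.report(
                "patch",
                patch_truth,
                pred.hotspots["predicted"].to_numpy(),
                pred.hotspots["score"].to_numpy(),
            )
            pat = pred.patients
            pat_truth = label_map.loc[pat["patient_id"]].to_numpy()
            patient_rep = evaluation.report(
                "patient",
                pat_truth,
                pat["predicted"].to_numpy(),
                pat["pcr_vote_fraction"].to_numpy(),
            )
            reports[(metric, fc)] = {"patch": patch_rep, "patient": patient_rep}
            rows.append(
                {
                    "metric": metric,
                    "features": "; ".join(fc),
                    "algorithm": results.algorithm,
                    "patch_accuracy": patch_rep.accuracy,
                    "patient_accuracy": patient_rep.accuracy,
                    "patch_precision": patch_rep.precision,
                    "patch_recall": patch_rep.recall,
                    "patch_f1": patch_rep.f1,
                    "patient_precision": patient_rep.precision,
                    "patient_recall": patient_rep.recall,
                    "patient_f1": patient_rep.f1,
                    "patch_auc": patch_rep.auc,
                    "patient_auc": patient_rep.auc,
                    "cv_accuracy": results.cv_accuracy,
                }
            )
            logger.info("cell %s done in %.1fs", cell_id, time.perf_counter() - t0)
    return ExperimentResult(
        summary=pd.DataFrame(rows),
        reports=reports,
        split=split,
        registration_reports=reg_reports,
    )


def run_replicates(config: ExperimentConfig, seeds: list[int]) -> pd.DataFrame:
    """Replicate the experiment over seeds; report mean and sd per cell.

    A fresh cohort is generated per seed (the cohort seed and the
    split/CV seed both follow the replicate seed), so the spread reflects
    both sampling and split variability — single-split results on a
    19-patient test set are high-variance.
    """
    frames = []
    for seed in seeds:
        cfg = dataclasses.replace(
            config, spec=dataclasses.replace(config.spec, seed=seed), seed=seed
        )
        res = run_experiment(cfg)
        frame = res.summary.copy()
        frame["seed"] = seed
        frames.append(frame)
    allruns = pd.concat(frames, ignore_index=True)
    value_cols = [
        c for c in allruns.columns if c not in ("metric", "features", "algorithm", "seed")
    ]
    agg = allruns.groupby(["metric", "features"])[value_cols].agg(["mean", "std"])
    agg.columns = [f"{a}_{b}" for a, b in agg.columns]
    return agg.reset_index()
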