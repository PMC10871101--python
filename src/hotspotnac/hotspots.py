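"""Patch-grid construction and density-ranked hotspot selection.

Each 8000x8000 px image region is tiled into non-overlapping 1000x1000 px
patches (so cell count per patch equals cell density), and each patient's
patches — pooled across all of their regions — are ranked in descending
order under one of six selection metrics (tTILs, sTILs, sTILs+tTILs, P,
M, TCs). The top k patches (k = 21 by default; an odd k guarantees a
strict majority when hotspot votes are later aggregated per patient)
become that patient's hotspots, each summarised by its five cell counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "COUNT_COLUMNS",
    "METRICS",
    "DEFAULT_K",
    "HotspotSet",
    "build_patch_grid",
    "select_hotspots",
    "hotspot_feature_table",
    "metric_values",
]

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["tTILs", "sTILs", "P", "M", "TCs"]
METRICS = ("tTILs", "sTILs", "sTILs+tTILs", "P", "M", "TCs")
DEFAULT_K = 21

PATCH_COLUMNS = ["patient_id", "region_id", "row", "col"] + COUNT_COLUMNS


def metric_values(patches: pd.DataFrame, metric: str) -> pd.Series:
    """The ranking value of each patch under ``metric``."""
    if metric == "sTILs+tTILs":
        return patches["sTILs"] + patches["tTILs"]
    if metric in COUNT_COLUMNS:
        return patches[metric]
    raise ValidationError(
        f"unknown hotspot metric {metric!r}; valid metrics are {list(METRICS)}"
    )


def build_patch_grid(
    detections: pd.DataFrame,
    region_size_px: int,
    patch_size_px: int,
    regions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Count cells of each class per non-overlapping patch.

    Parameters
    ----------
    detections : phenotyped H&E detections with columns ``patient_id,
        region_id, cell_type, x, y`` and boolean ``is_P, is_M``.
    region_size_px, patch_size_px : region and patch edge lengths;
        the former must be divisible by the latter.
    regions : optional DataFrame with columns ``patient_id, region_id``
        enumerating the regions the grid should cover; defaults to the
        regions present in ``detections``. Supplying it keeps fully empty
        regions represented.

    Returns one row per patch — every patch of every region, including
    empty ones — with the five class counts. Cells are assigned to
    patches by the half-open convention [x0, x0 + patch) so each cell
    lands in exactly one patch; per-class patch sums therefore equal the
    region totals.
    """
    if region_size_px % patch_size_px != 0:
        raise ValidationError(
            "region_size_px must be divisible by patch_size_px "
            f"({region_size_px} % {patch_size_px} != 0)"
        )
    g = region_size_px // patch_size_px

    if regions is None:
        regions = detections[["patient_id", "region_id"]].drop_duplicates()
    regions = regions[["patient_id", "region_id"]].drop_duplicates()

    det = detections
    if len(det):
        oob = (
            (det["x"] < 0)
            | (det["x"] >= region_size_px)
            | (det["y"] < 0)
            | (det["y"] >= region_size_px)
        )
        if oob.any():
            raise ValidationError(
                f"{int(oob.sum())} detections fall outside [0, {region_size_px}) bounds"
            )

    rows_out: list[pd.DataFrame] = []
    grid_index = pd.MultiIndex.from_product(
        [range(g), range(g)], names=["row", "col"]
    )
    grouped = dict(iter(det.groupby(["patient_id", "region_id"]))) if len(det) else {}
    for rec in regions.itertuples(index=False):
        key = (rec.patient_id, rec.region_id)
        grp = grouped.get(key)
        counts = pd.DataFrame(0, index=grid_index, columns=COUNT_COLUMNS)
        if grp is not None and len(grp):
            row = (grp["y"] // patch_size_px).astype(int)
            col = (grp["x"] // patch_size_px).astype(int)
            tall = pd.DataFrame(
                {
                    "row": row,
                    "col": col,
                    "tTILs": (grp["cell_type"] == "tTIL").astype(int),
                    "sTILs": (grp["cell_type"] == "sTIL").astype(int),
                    "P": grp["is_P"].astype(int),
                    "M": grp["is_M"].astype(int),
                    "TCs": (grp["cell_type"] == "TC").astype(int),
                }
            )
            agg = tall.groupby(["row", "col"]).sum()
            counts.loc[agg.index] = agg
        counts = counts.reset_index()
        counts.insert(0, "region_id", rec.region_id)
        counts.insert(0, "patient_id", rec.patient_id)
        rows_out.append(counts)

    if not rows_out:
        return pd.DataFrame(columns=PATCH_COLUMNS)
    out = pd.concat(rows_out, ignore_index=True)
    return out[PATCH_COLUMNS].astype({c: "int64" for c in COUNT_COLUMNS})


@dataclass
class HotspotSet:
    """The top-k density-ranked patches of one patient under one metric."""

    patient_id: str
    metric: str
    patches: pd.DataFrame  # ordered; includes a ``metric_value`` column
    k_requested: int
    k_obtained: int


def select_hotspots(patches: pd.DataFrame, metric: str, k: int = DEFAULT_K) -> HotspotSet:
    """Select one patient's top-k patches under ``metric``.

    Patches (pooled across the patient's regions) are sorted by the
    metric value in descending order; ties are broken deterministically
    by ascending (region_id, row, col), which also makes the selection
    invariant to input row order. If fewer than k patches exist, all of
    them are returned (logged); an even k is allowed but draws a warning
    because it permits majority-vote ties downstream.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k % 2 == 0:
        warnings.warn(
            f"k={k} is even; an odd k guarantees strict patient-level majorities",
            UserWarning,
            stacklevel=2,
        )
    pids = patches["patient_id"].unique()
    if len(pids) != 1:
        raise ValidationError(
            f"select_hotspots expects one patient's patches, got {len(pids)} patients"
        )
    values = metric_values(patches, metric)
    ordered = patches.assign(metric_value=values).sort_values(
        by=["metric_value", "region_id", "row", "col"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    k_obtained = min(k, len(ordered))
    if k_obtained < k:
        logger.info(
            "patient %s has only %d patches (< k=%d); using all of them",
            pids[0],
            len(ordered),
            k,
        )
    return HotspotSet(
        patient_id=pids[0],
        metric=metric,
        patches=ordered.head(k_obtained).reset_index(drop=True),
        k_requested=k,
        k_obtained=k_obtained,
    )


def hotspot_feature_table(
    patches: pd.DataFrame,
    labels: pd.DataFrame,
    metric: str,
    k: int = DEFAULT_K,
) -> pd.DataFrame:
    """One row per hotspot for every patient, with counts and outcome label.

    This is the dataset the response classifier consumes: for each
    patient in ``labels``, their top-k patches under ``metric``, each row
    carrying the five cell counts and the patient's pCR/RD label.
    """
    frames = []
    for rec in labels.itertuples(index=False):
        pp = patches[patches["patient_id"] == rec.patient_id]
        if pp.empty:
            raise ValidationError(f"patient_id {rec.patient_id!r} has no patches")
        hs = select_hotspots(pp, metric, k)
        frame = hs.patches.copy()
        frame["label"] = rec.label
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
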