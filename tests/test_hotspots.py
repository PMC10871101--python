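"""Patch-grid counting and top-k hotspot selection against sort oracles."""

import numpy as np
import pandas as pd
import pytest

from hotspotnac.exceptions import ValidationError
from hotspotnac.hotspots import (
    COUNT_COLUMNS,
    METRICS,
    build_patch_grid,
    hotspot_feature_table,
    metric_values,
    select_hotspots,
)


def _detections(rows):
    df = pd.DataFrame(
        rows, columns=["patient_id", "region_id", "cell_type", "x", "y", "is_P", "is_M"]
    )
    return df


def _random_detections(rng, n, patient="P1", region=0, size=8000.0):
    cell_type = rng.choice(["TC", "sTIL", "tTIL"], size=n, p=[0.7, 0.15, 0.15])
    is_tc = cell_type == "TC"
    is_p = is_tc & (rng.random(n) < 0.3)
    return pd.DataFrame(
        {
            "patient_id": patient,
            "region_id": region,
            "cell_type": cell_type,
            "x": rng.random(n) * size,
            "y": rng.random(n) * size,
            "is_P": is_p,
            "is_M": is_p & (rng.random(n) < 0.2),
        }
    )


class TestBuildPatchGrid:
    def test_standard_geometry_gives_64_patches(self, rng):
        det = _random_detections(rng, 500)
        patches = build_patch_grid(det, 8000, 1000)
        assert len(patches) == 64
        assert set(patches["row"]) == set(range(8))

    def test_half_open_boundary_assignment(self):
        det = _detections([["P1", 0, "TC", 1000.0, 0.0, False, False]])
        patches = build_patch_grid(det, 8000, 1000)
        hit = patches[patches["TCs"] > 0]
        assert len(hit) == 1
        assert (hit.iloc[0]["row"], hit.iloc[0]["col"]) == (0, 1)

    def test_count_conservation(self, rng):
        det = _random_detections(rng, 500)
        patches = build_patch_grid(det, 8000, 1000)
        assert patches["TCs"].sum() == (det["cell_type"] == "TC").sum()
        assert patches["tTILs"].sum() == (det["cell_type"] == "tTIL").sum()
        assert patches["sTILs"].sum() == (det["cell_type"] == "sTIL").sum()
        assert patches["P"].sum() == det["is_P"].sum()
        assert patches["M"].sum() == det["is_M"].sum()

    def test_non_divisible_sizes_rejected(self, rng):
        with pytest.raises(ValidationError, match="divisible"):
            build_patch_grid(_random_detections(rng, 10), 8000, 3000)

    def test_out_of_bounds_cells_rejected(self):
        det = _detections([["P1", 0, "TC", 8000.0, 10.0, False, False]])
        with pytest.raises(ValidationError, match="outside"):
            build_patch_grid(det, 8000, 1000)

    def test_empty_region_kept_when_enumerated(self):
        regions = pd.DataFrame({"patient_id": ["P1", "P1"], "region_id": [0, 1]})
        det = _detections([["P1", 0, "TC", 5.0, 5.0, False, False]])
        patches = build_patch_grid(det, 2000, 1000, regions)
        assert len(patches) == 8  # 4 patches x 2 regions
        assert patches[patches["region_id"] == 1]["TCs"].sum() == 0


def _patch_table(values, patient="P1"):
    n = len(values)
    return pd.DataFrame(
        {
            "patient_id": patient,
            "region_id": 0,
            "row": np.arange(n) // 8,
            "col": np.arange(n) % 8,
            "tTILs": values,
            "sTILs": 0,
            "P": 0,
            "M": 0,
            "TCs": 0,
        }
    )


class TestSelectHotspots:
    def test_top_21_of_64_descending(self, rng):
        patches = _patch_table(rng.integers(0, 50, size=64))
        hs = select_hotspots(patches, "tTILs", k=21)
        assert hs.k_obtained == 21
        vals = hs.patches["metric_value"].to_numpy()
        assert (np.diff(vals) <= 0).all()

    def test_sort_oracle_30_patches(self):
        patches = _patch_table(np.arange(30, 0, -1))
        hs = select_hotspots(patches, "tTILs", k=21)
        assert list(hs.patches["metric_value"]) == list(range(30, 9, -1))

    def test_total_tie_uses_patch_identity_order(self):
        patches = _patch_table(np.zeros(64, dtype=int)).sample(frac=1, random_state=0)
        hs = select_hotspots(patches, "tTILs", k=21)
        assert (hs.patches["metric_value"] == 0).all()
        keys = list(zip(hs.patches["region_id"], hs.patches["row"], hs.patches["col"]))
        assert keys == sorted(keys)[:21]

    def test_selection_invariant_to_row_order(self, rng):
        patches = _patch_table(rng.integers(0, 10, size=64))
        a = select_hotspots(patches, "tTILs", k=21).patches
        b = select_hotspots(
            patches.sample(frac=1, random_state=3), "tTILs", k=21
        ).patches
        pd.testing.assert_frame_equal(a, b)

    def test_min_inside_geq_max_outside(self, rng):
        for metric in METRICS:
            patches = _patch_table(rng.integers(0, 40, size=64))
            patches["sTILs"] = rng.integers(0, 40, size=64)
            hs = select_hotspots(patches, metric, k=21)
            inside = metric_values(hs.patches, metric)
            key = patches.merge(
                hs.patches[["region_id", "row", "col"]],
                on=["region_id", "row", "col"],
                how="left",
                indicator=True,
            )
            outside = metric_values(key[key["_merge"] == "left_only"], metric)
            if len(outside):
                assert inside.min() >= outside.max()

    def test_fewer_patches_than_k_returns_all(self):
        patches = _patch_table(np.arange(5))
        hs = select_hotspots(patches, "tTILs", k=21)
        assert hs.k_obtained == 5

    def test_even_k_warns(self):
        patches = _patch_table(np.arange(30))
        with pytest.warns(UserWarning, match="odd"):
            select_hotspots(patches, "tTILs", k=20)

    def test_unknown_metric_lists_valid_ones(self):
        patches = _patch_table(np.arange(5))
        with pytest.raises(ValidationError, match="tTILs"):
            select_hotspots(patches, "nonsense", k=3)

    def test_combined_metric_sorts_by_sum(self, rng):
        patches = _patch_table(rng.integers(0, 10, size=64))
        patches["sTILs"] = rng.integers(0, 10, size=64)
        hs = select_hotspots(patches, "sTILs+tTILs", k=11)
        expected = (patches["sTILs"] + patches["tTILs"]).sort_values(ascending=False)
        assert list(hs.patches["metric_value"]) == list(expected.head(11))


def test_hotspot_feature_table_labels_and_rows(rng):
    patches = pd.concat(
        [_patch_table(rng.integers(0, 9, size=64), patient=f"P{i}") for i in range(3)],
        ignore_index=True,
    )
    labels = pd.DataFrame(
        {"patient_id": ["P0", "P1", "P2"], "label": ["pCR", "RD", "pCR"]}
    )
    table = hotspot_feature_table(patches, labels, "tTILs", k=21)
    assert len(table) == 63
    assert set(table.columns) >= set(COUNT_COLUMNS) | {"label", "patient_id"}
    assert (table.groupby("patient_id").size() == 21).all()
    with pytest.raises(ValidationError, match="no patches"):
        hotspot_feature_table(
            patches, pd.DataFrame({"patient_id": ["PX"], "label": ["RD"]}), "tTILs"
        )
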