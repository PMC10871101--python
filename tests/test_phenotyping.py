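"""Radius-based phenotype assignment against the all-pairs oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from hotspotnac.exceptions import ValidationError
from hotspotnac.phenotyping import (
    assign_phenotypes,
    phenotype_cohort_detections,
    phenotype_recovery_report,
)


def brute_force_flags(cells, points, radius):
    """All-pairs distance-matrix thresholding: the contractual definition."""
    if len(points) == 0:
        return np.zeros(len(cells), dtype=bool)
    return (cdist(cells, points) <= radius).any(axis=1)


def test_boundary_is_inclusive():
    out = assign_phenotypes([[0.0, 0.0]], [[40.0, 0.0]], [[40.01, 0.0]], radius_px=40)
    assert bool(out["is_P"].iloc[0]) is True
    assert bool(out["is_M"].iloc[0]) is False


def test_no_ihc_points_means_all_negative(rng):
    cells = rng.random((30, 2)) * 1000
    out = assign_phenotypes(cells, np.empty((0, 2)), np.empty((0, 2)))
    assert not out["is_P"].any()
    assert not out["is_M"].any()


@pytest.mark.parametrize("radius", [5.0, 40.0, 200.0])
@pytest.mark.parametrize("n_cells, n_points", [(200, 50), (1000, 200)])
def test_matches_all_pairs_oracle(rng, radius, n_cells, n_points):
    cells = rng.random((n_cells, 2)) * 2000
    ki67 = rng.random((n_points, 2)) * 2000
    ph3 = rng.random((max(1, n_points // 4), 2)) * 2000
    out = assign_phenotypes(cells, ki67, ph3, radius_px=radius)
    np.testing.assert_array_equal(out["is_P"], brute_force_flags(cells, ki67, radius))
    np.testing.assert_array_equal(out["is_M"], brute_force_flags(cells, ph3, radius))


def test_flags_monotone_in_radius(rng):
    cells = rng.random((300, 2)) * 2000
    pts = rng.random((60, 2)) * 2000
    previous = np.zeros(300, dtype=bool)
    for radius in (10, 20, 40, 80, 160):
        flags = assign_phenotypes(cells, pts, pts, radius_px=radius)["is_P"].to_numpy()
        assert (previous <= flags).all()
        previous = flags


def test_negative_radius_rejected():
    with pytest.raises(ValidationError, match="radius"):
        assign_phenotypes([[0, 0]], [[1, 1]], [[1, 1]], radius_px=-1)


def test_tils_are_never_phenotyped():
    he = pd.DataFrame(
        {
            "patient_id": ["P1"] * 3,
            "region_id": [0] * 3,
            "cell_type": ["TC", "sTIL", "tTIL"],
            "cell_id": [0, 1, 2],
            "x": [100.0, 100.0, 100.0],
            "y": [100.0, 100.0, 100.0],
        }
    )
    ihc = pd.DataFrame(
        {
            "patient_id": ["P1"] * 2,
            "region_id": [0] * 2,
            "channel": ["KI67", "PH3"],
            "cell_type": ["KI67_POS", "PH3_POS"],
            "cell_id": [0, 0],
            "x": [100.0, 100.0],
            "y": [100.0, 100.0],
        }
    )
    out = phenotype_cohort_detections(he, ihc)
    tc = out[out["cell_type"] == "TC"].iloc[0]
    assert bool(tc.is_P) and bool(tc.is_M)
    tils = out[out["cell_type"] != "TC"]
    assert not tils["is_P"].any() and not tils["is_M"].any()


def test_one_ihc_point_can_flag_multiple_cells():
    cells = [[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]
    out = assign_phenotypes(cells, [[5.0, 5.0]], np.empty((0, 2)), radius_px=40)
    assert out["is_P"].all()


class TestRecoveryReport:
    def _cohort_tables(self, aligned_cohort):
        ihc = aligned_cohort.detections[aligned_cohort.detections["channel"] != "HE"]
        return aligned_cohort.he_detections(), ihc, aligned_cohort.truth_phenotypes

    def test_recall_is_perfect_without_jitter(self, aligned_cohort):
        he, ihc, truth = self._cohort_tables(aligned_cohort)
        assigned = phenotype_cohort_detections(he, ihc, radius_px=40)
        rep = phenotype_recovery_report(assigned, truth)
        assert rep["P"]["recall"] == 1.0
        assert rep["M"]["recall"] == 1.0

    def test_perfect_recovery_without_jitter_on_sparse_tissue(self):
        """Exact IHC/H&E correspondence gives precision = recall = 1.0 when
        tumor cells sit farther apart than the 40 px radius; at realistic
        density the proximity rule legitimately flags coincidental
        neighbours of a stained cell, so only recall stays exact."""
        from hotspotnac.cohort import (
            ClassRates,
            CohortSpec,
            MisalignmentTransform,
            generate_cohort,
        )

        cohort = generate_cohort(
            CohortSpec(n_patients=3, n_pcr=2, n_rd=1, seed=13),
            rates_pcr=ClassRates(tc=1.0, stil=0, ttil=0, ki67_fraction=0.5, ph3_fraction=0.2),
            rates_rd=ClassRates(tc=1.0, stil=0, ttil=0, ki67_fraction=0.5, ph3_fraction=0.2),
            transform=MisalignmentTransform.identity(),
        )
        he = cohort.he_detections()
        ihc = cohort.detections[cohort.detections["channel"] != "HE"]
        assigned = phenotype_cohort_detections(he, ihc, radius_px=40)
        rep = phenotype_recovery_report(assigned, cohort.truth_phenotypes)
        assert rep["P"]["precision"] == 1.0 and rep["P"]["recall"] == 1.0
        assert rep["M"]["precision"] == 1.0 and rep["M"]["recall"] == 1.0

    def test_jittered_points_recovered_at_default_radius(self):
        """2 px isotropic jitter vs a 40 px radius: recall >= 0.99 on
        >=1000 tumor cells (the 40/2 = 20 sigma Gaussian tail is negligible;
        precision can dip only through coincidental neighbours)."""
        from hotspotnac.cohort import CohortSpec, MisalignmentTransform, generate_cohort

        cohort = generate_cohort(
            CohortSpec(n_patients=2, n_pcr=1, n_rd=1, seed=5),
            transform=MisalignmentTransform.identity(jitter_sd=2.0),
        )
        assert len(cohort.truth_phenotypes) >= 1000
        he = cohort.he_detections()
        ihc = cohort.detections[cohort.detections["channel"] != "HE"]
        assigned = phenotype_cohort_detections(he, ihc, radius_px=40)
        rep = phenotype_recovery_report(assigned, cohort.truth_phenotypes)
        assert rep["P"]["recall"] >= 0.99
        assert rep["M"]["recall"] >= 0.99

    def test_degenerate_radius_recovers_nothing(self):
        from hotspotnac.cohort import CohortSpec, MisalignmentTransform, generate_cohort

        cohort = generate_cohort(
            CohortSpec(n_patients=1, n_pcr=1, n_rd=0, region_size_px=4000, seed=5),
            transform=MisalignmentTransform.identity(jitter_sd=2.0),
        )
        he = cohort.he_detections()
        ihc = cohort.detections[cohort.detections["channel"] != "HE"]
        assigned = phenotype_cohort_detections(he, ihc, radius_px=0.001)
        rep = phenotype_recovery_report(assigned, cohort.truth_phenotypes)
        assert rep["P"]["recall"] <= 0.05

    def test_id_mismatch_rejected(self, aligned_cohort):
        he, ihc, truth = self._cohort_tables(aligned_cohort)
        assigned = phenotype_cohort_detections(he, ihc)
        with pytest.raises(ValidationError, match="mismatch"):
            phenotype_recovery_report(assigned, truth.assign(cell_id=truth.cell_id + 1))
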