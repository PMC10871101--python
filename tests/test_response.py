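"""Response classifier: splits, CV model selection, voting, persistence."""

import numpy as np
import pandas as pd
import pytest

from hotspotnac import model_io
from hotspotnac.exceptions import NotFittedError, ValidationError
from hotspotnac.response import (
    HotspotResponseModel,
    default_candidate_grid,
    predict_patients,
    stratified_split,
)


def _labels(n_pcr, n_rd):
    return pd.DataFrame(
        {
            "patient_id": [f"A{i}" for i in range(n_pcr)] + [f"B{i}" for i in range(n_rd)],
            "label": ["pCR"] * n_pcr + ["RD"] * n_rd,
        }
    )


def _separable_table(rng, n_pcr=6, n_rd=6, per_patient=5):
    """Hotspots where tTILs alone separates the classes perfectly."""
    rows = []
    for i in range(n_pcr + n_rd):
        label = "pCR" if i < n_pcr else "RD"
        for _ in range(per_patient):
            base = 100 if label == "pCR" else 10
            rows.append(
                {
                    "patient_id": f"P{i:02d}",
                    "label": label,
                    "tTILs": base + rng.integers(0, 5),
                    "sTILs": rng.integers(0, 10),
                    "P": rng.integers(0, 10),
                    "M": rng.integers(0, 3),
                    "TCs": rng.integers(80, 120),
                }
            )
    return pd.DataFrame(rows)


class TestStratifiedSplit:
    def test_canonical_76_patient_split(self):
        split = stratified_split(_labels(44, 32), 0.75, seed=0)
        labels = _labels(44, 32).set_index("patient_id")["label"]
        train = labels.loc[list(split.train_ids)]
        test = labels.loc[list(split.test_ids)]
        assert (train == "pCR").sum() == 33 and (train == "RD").sum() == 24
        assert (test == "pCR").sum() == 11 and (test == "RD").sum() == 8

    def test_exact_fractions(self):
        split = stratified_split(_labels(4, 4), 0.5, seed=1)
        assert len(split.train_ids) == 4 and len(split.test_ids) == 4

    def test_full_training_fraction_flagged_not_fatal(self):
        split = stratified_split(_labels(3, 3), 1.0, seed=0)
        assert len(split.test_ids) == 0

    def test_disjoint_and_exhaustive(self):
        labels = _labels(10, 7)
        split = stratified_split(labels, 0.6, seed=5)
        assert not set(split.train_ids) & set(split.test_ids)
        assert set(split.train_ids) | set(split.test_ids) == set(labels["patient_id"])

    def test_reproducible_and_seed_sensitive(self):
        a = stratified_split(_labels(20, 20), 0.75, seed=3)
        b = stratified_split(_labels(20, 20), 0.75, seed=3)
        c = stratified_split(_labels(20, 20), 0.75, seed=4)
        assert a.train_ids == b.train_ids
        assert a.train_ids != c.train_ids

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValidationError, match="2 patients"):
            stratified_split(_labels(1, 5), 0.75, seed=0)


class TestFitAndSelect:
    def test_separable_classes_reach_perfect_cv_accuracy(self, rng):
        table = _separable_table(rng)
        model = HotspotResponseModel.from_hotspots(table, ("tTILs",))
        results = model.fit(folds=3, seed=0)
        assert results.cv_accuracy == 1.0
        assert results.cv_table["mean_val_accuracy"].max() == 1.0

    def test_patient_disjoint_folds(self, rng):
        table = _separable_table(rng, n_pcr=9, n_rd=9)
        model = HotspotResponseModel.from_hotspots(table, ("tTILs", "sTILs"))
        pids = model.patients.to_numpy()
        for train_idx, val_idx in model._patient_folds(3, seed=2):
            assert not set(pids[train_idx]) & set(pids[val_idx])
            assert len(train_idx) + len(val_idx) == len(pids)

    def test_deterministic_selection_and_predictions(self, rng):
        table = _separable_table(rng, n_pcr=8, n_rd=8)
        model = HotspotResponseModel.from_hotspots(table, ("tTILs", "sTILs", "P", "M"))
        r1 = model.fit(folds=3, seed=9)
        r2 = model.fit(folds=3, seed=9)
        assert (r1.algorithm, r1.params) == (r2.algorithm, r2.params)
        p1 = r1.predict(table).patients
        p2 = r2.predict(table).patients
        pd.testing.assert_frame_equal(p1, p2)

    def test_tie_break_prefers_canonical_order(self, rng):
        # On perfectly separable data many candidates reach accuracy 1.0;
        # the first grid entry (LDA, svd) must win the tie.
        table = _separable_table(rng)
        results = HotspotResponseModel.from_hotspots(table, ("tTILs",)).fit(seed=0)
        assert results.algorithm == "LDA"
        assert results.params == {"solver": "svd"}

    def test_empty_grid_rejected(self, rng):
        table = _separable_table(rng)
        model = HotspotResponseModel.from_hotspots(table, ("tTILs",))
        with pytest.raises(ValidationError, match="grid"):
            model.fit(grid=[])

    def test_too_few_patients_for_folds(self, rng):
        table = _separable_table(rng, n_pcr=2, n_rd=2)
        model = HotspotResponseModel.from_hotspots(table, ("tTILs",))
        with pytest.raises(ValidationError, match="3-fold"):
            model.fit(folds=3)

    def test_invalid_features_rejected(self, rng):
        table = _separable_table(rng)
        with pytest.raises(ValidationError, match="unknown features"):
            HotspotResponseModel.from_hotspots(table, ("tTILs", "bogus"))
        with pytest.raises(ValidationError, match="non-empty"):
            HotspotResponseModel.from_hotspots(table, ())

    def test_standardization_exposed_for_scaled_families(self, rng):
        table = _separable_table(rng)
        model = HotspotResponseModel.from_hotspots(table, ("tTILs", "sTILs"))
        svm = model.fit(grid=[("SVM", {"kernel": "linear", "C": 1.0})])
        assert svm.standardization is not None
        assert len(svm.standardization["mean"]) == 2
        lda = model.fit(grid=[("LDA", {"solver": "svd"})])
        assert lda.standardization is None

    def test_summary_mentions_selection(self, rng):
        table = _separable_table(rng)
        results = HotspotResponseModel.from_hotspots(table, ("tTILs",)).fit(seed=0)
        text = results.summary()
        assert "LDA" in text and "CV accuracy" in text and "pCR" in text


class TestMajorityVoting:
    def _fitted(self, rng):
        table = _separable_table(rng)
        return HotspotResponseModel.from_hotspots(table, ("tTILs",)).fit(seed=0)

    def _vote_table(self, ttils):
        return pd.DataFrame(
            {
                "patient_id": "T1",
                "tTILs": ttils,
                "sTILs": 0,
                "P": 0,
                "M": 0,
                "TCs": 100,
            }
        )

    def test_11_of_21_votes_give_pcr(self, rng):
        results = self._fitted(rng)
        table = self._vote_table([100] * 11 + [10] * 10)
        pred = results.predict(table)
        assert pred.patients.iloc[0]["predicted"] == "pCR"
        assert pred.patients.iloc[0]["pcr_vote_fraction"] == pytest.approx(11 / 21)

    def test_unanimous_rd_scores_zero(self, rng):
        results = self._fitted(rng)
        pred = results.predict(self._vote_table([10] * 21))
        assert pred.patients.iloc[0]["predicted"] == "RD"
        assert pred.patients.iloc[0]["pcr_vote_fraction"] == 0.0

    def test_even_split_tie_goes_to_pcr(self, rng):
        results = self._fitted(rng)
        pred = results.predict(self._vote_table([100] * 10 + [10] * 10))
        assert pred.patients.iloc[0]["predicted"] == "pCR"
        pred_rd = results.predict(
            self._vote_table([100] * 10 + [10] * 10), tie_label="RD"
        )
        assert pred_rd.patients.iloc[0]["predicted"] == "RD"

    def test_unfitted_model_rejected(self, rng):
        with pytest.raises(NotFittedError):
            predict_patients(None, self._vote_table([1] * 3))


class TestModelPersistence:
    @pytest.mark.parametrize(
        "algorithm, params",
        [
            ("LDA", {"solver": "svd"}),
            ("LDA", {"solver": "lsqr", "shrinkage": "auto"}),
            ("SVM", {"kernel": "linear", "C": 1.0}),
            ("SVM", {"kernel": "rbf", "C": 10.0, "gamma": "scale"}),
            (
                "MLP",
                {
                    "hidden_layer_sizes": (16,),
                    "alpha": 1e-4,
                    "solver": "lbfgs",
                    "max_iter": 300,
                    "random_state": 0,
                },
            ),
        ],
    )
    def test_json_round_trip_reproduces_predictions(self, rng, tmp_path, algorithm, params):
        table = _separable_table(rng, n_pcr=8, n_rd=8)
        model = HotspotResponseModel.from_hotspots(table, ("tTILs", "sTILs", "P", "M"))
        results = model.fit(grid=[(algorithm, params)], seed=0)
        path = model_io.save_model(results, tmp_path / "model.json")
        loaded = model_io.load_model(path)
        X = table[["tTILs", "sTILs", "P", "M"]].to_numpy(dtype=float)
        sk_pred = results.predict(table).hotspots["predicted"].to_numpy()
        np.testing.assert_array_equal(loaded.predict(X), sk_pred)
        # scores must rank identically (MLP stores logits, sklearn probabilities)
        sk_scores = results._scores(X)
        np.testing.assert_array_equal(
            np.argsort(loaded.decision_scores(X)), np.argsort(sk_scores)
        )

    def test_rejects_foreign_json(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text("{}")
        with pytest.raises(ValidationError, match="model file"):
            model_io.load_model(path)


def test_default_grid_order_and_size():
    grid = default_candidate_grid(seed=0)
    assert [a for a, _ in grid[:2]] == ["LDA", "LDA"]
    assert grid[-1][0] == "MLP"
    algorithms = [a for a, _ in grid]
    # canonical family order, no interleaving
    assert algorithms == sorted(algorithms, key=["LDA", "SVM", "MLP"].index)
    assert len(grid) == 26
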