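"""Patient NAC-response classification from hotspot features.

The modelling object follows the statsmodels convention: build a
:class:`HotspotResponseModel` from a hotspot feature table (one row per
hotspot, five cell counts, a patient id and a pCR/RD label), call
``fit()`` to run the hyperparameter search, and receive a
:class:`HotspotResponseResults` carrying the selected estimator, the
full cross-validation table, and ``predict()`` / ``summary()``.

Model selection replicates the study protocol: candidate families are
linear discriminant analysis, support vector machines (linear and RBF)
and a one-hidden-layer multilayer perceptron, each scored by mean
hotspot-level accuracy under patient-disjoint stratified 3-fold
cross-validation; the globally best configuration is refitted on all
training hotspots. Patients are classified by maximum voting over their
hotspot predictions, with pCR as the positive class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import NotFittedError, ValidationError
from .hotspots import COUNT_COLUMNS

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "CohortSplit",
    "stratified_split",
    "default_candidate_grid",
    "HotspotResponseModel",
    "HotspotResponseResults",
    "PredictionResult",
    "predict_patients",
]

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "pCR"
NEGATIVE_LABEL = "RD"
ALGORITHM_ORDER = ("LDA", "SVM", "MLP")


# ---------------------------------------------------------------------------
# Patient-level stratified train/test split


@dataclass(frozen=True)
class CohortSplit:
    """A patient-disjoint train/test partition."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_frac: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValidationError("train and test patient sets overlap")


def stratified_split(
    labels: pd.DataFrame, train_frac: float = 0.75, seed: int = 0
) -> CohortSplit:
    """Split patients into train/test, stratified by outcome class.

    Each class contributes floor(train_frac * class size) patients to
    training; if the resulting total falls short of
    floor(train_frac * n), remaining slots are filled by largest
    fractional remainder (ties broken by class name). With 44 pCR and
    32 RD patients at 0.75 this yields the canonical 33 + 24 = 57
    training and 11 + 8 = 19 testing patients. Deterministic in ``seed``.
    """
    if not 0 < train_frac <= 1:
        raise ValidationError(f"train_frac must be in (0, 1], got {train_frac}")
    class_sizes = labels["label"].value_counts()
    if train_frac < 1.0 and (class_sizes < 2).any():
        small = class_sizes[class_sizes < 2]
        raise ValidationError(
            f"need >= 2 patients per class to split, got {small.to_dict()}"
        )
    rng = np.random.default_rng(seed)
    n_total = len(labels)
    target = int(np.floor(train_frac * n_total))

    per_class: dict[str, list[str]] = {}
    base: dict[str, int] = {}
    remainders: dict[str, float] = {}
    for cls in sorted(class_sizes.index):
        ids = sorted(labels.loc[labels["label"] == cls, "patient_id"])
        rng.shuffle(ids)
        per_class[cls] = ids
        exact = train_frac * len(ids)
        base[cls] = int(np.floor(exact))
        remainders[cls] = exact - base[cls]
    shortfall = target - sum(base.values())
    for cls in sorted(remainders, key=lambda c: (-remainders[c], c)):
        if shortfall <= 0:
            break
        if base[cls] < len(per_class[cls]):
            base[cls] += 1
            shortfall -= 1

    train: list[str] = []
    test: list[str] = []
    for cls, ids in per_class.items():
        train.extend(ids[: base[cls]])
        test.extend(ids[base[cls] :])
    if not test:
        logger.warning("train_frac=%s leaves an empty test set", train_frac)
    return CohortSplit(
        train_ids=tuple(sorted(train)),
        test_ids=tuple(sorted(test)),
        train_frac=train_frac,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Candidate grid


def default_candidate_grid(seed: int = 0) -> list[tuple[str, dict]]:
    """The explicit hyperparameter grid searched during ``fit``.

    Returned in the canonical tie-break order: LDA before SVM before
    MLP, each family's configurations in a fixed lexicographic order.
    """
    grid: list[tuple[str, dict]] = [
        ("LDA", {"solver": "svd"}),
        ("LDA", {"solver": "lsqr", "shrinkage": "auto"}),
    ]
    for c in (0.1, 1.0, 10.0, 100.0):
        grid.append(("SVM", {"kernel": "linear", "C": c}))
    for c in (0.1, 1.0, 10.0, 100.0):
        for gamma in ("scale", 0.01, 0.1, 1.0):
            grid.append(("SVM", {"kernel": "rbf", "C": c, "gamma": gamma}))
    for hidden in (16, 64):
        for alpha in (1e-4, 1e-2):
            grid.append(
                (
                    "MLP",
                    {
                        "hidden_layer_sizes": (hidden,),
                        "alpha": alpha,
                        "solver": "lbfgs",
                        "max_iter": 500,
                        "random_state": seed,
                    },
                )
            )
    return grid


def _make_estimator(algorithm: str, params: dict):
    """Instantiate a candidate; SVM/MLP are standardized, LDA sees raw counts."""
    if algorithm == "LDA":
        return LinearDiscriminantAnalysis(**params)
    if algorithm == "SVM":
        return Pipeline([("scale", StandardScaler()), ("clf", SVC(**params))])
    if algorithm == "MLP":
        return Pipeline([("scale", StandardScaler()), ("clf", MLPClassifier(**params))])
    raise ValidationError(f"unknown algorithm {algorithm!r}; valid: {ALGORITHM_ORDER}")


# ---------------------------------------------------------------------------
# Model / Results


@dataclass
class PredictionResult:
    """Hotspot-level predictions and their patient-level aggregation.

    ``hotspots``: one row per hotspot with predicted label and a
    positive-class (pCR) score. ``patients``: one row per patient with
    the majority-vote label and the fraction of pCR votes (the
    patient-level ROC score).
    """

    hotspots: pd.DataFrame
    patients: pd.DataFrame


class HotspotResponseModel:
    """NAC-response model over a hotspot feature table.

    Parameters
    ----------
    features : (n_hotspots, n_features) numeric DataFrame.
    labels : per-hotspot outcome labels ('pCR'/'RD'); every hotspot of a
        patient carries the patient's label.
    patients : per-hotspot patient ids.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: pd.Series,
        patients: pd.Series,
    ) -> None:
        if features.empty:
            raise ValidationError("features table is empty")
        if len(features) != len(labels) or len(features) != len(patients):
            raise ValidationError("features, labels and patients must align")
        bad = set(labels.unique()) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise ValidationError(f"labels must be pCR/RD, got extras {sorted(bad)}")
        self.features = features.reset_index(drop=True)
        self.labels = labels.reset_index(drop=True)
        self.patients = patients.reset_index(drop=True).astype(str)
        self.feature_names = list(features.columns)
        # one label per patient, for stratified folding
        pl = (
            pd.DataFrame({"patient_id": self.patients, "label": self.labels})
            .drop_duplicates()
        )
        if pl["patient_id"].duplicated().any():
            raise ValidationError("a patient carries conflicting labels")
        self.patient_labels = pl.reset_index(drop=True)

    @classmethod
    def from_hotspots(
        cls,
        hotspot_table: pd.DataFrame,
        feature_config: tuple[str, ...] = tuple(COUNT_COLUMNS),
        label_col: str = "label",
        patient_col: str = "patient_id",
    ) -> "HotspotResponseModel":
        """Build from a hotspot feature table (see ``hotspot_feature_table``).

        ``feature_config`` is the subset of the five counts the classifier
        sees — e.g. ``('tTILs',)`` or ``('tTILs', 'sTILs', 'P', 'M')``.
        """
        feature_config = tuple(feature_config)
        if not feature_config:
            raise ValidationError("feature_config must be a non-empty subset of counts")
        unknown = set(feature_config) - set(COUNT_COLUMNS)
        if unknown:
            raise ValidationError(
                f"unknown features {sorted(unknown)}; valid: {COUNT_COLUMNS}"
            )
        return cls(
            features=hotspot_table[list(feature_config)].astype(float),
            labels=hotspot_table[label_col],
            patients=hotspot_table[patient_col],
        )

    # -- fitting ----------------------------------------------------------

    def _patient_folds(self, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
        """Patient-disjoint stratified folds, returned as hotspot-row masks."""
        pl = self.patient_labels
        class_sizes = pl["label"].value_counts()
        if (class_sizes < folds).any():
            raise ValidationError(
                f"need >= {folds} patients per class for {folds}-fold CV, "
                f"got {class_sizes.to_dict()}"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        out = []
        pid_arr = self.patients.to_numpy()
        for train_idx, val_idx in skf.split(pl["patient_id"], pl["label"]):
            train_pids = set(pl["patient_id"].iloc[train_idx])
            val_pids = set(pl["patient_id"].iloc[val_idx])
            assert not train_pids & val_pids
            out.append(
                (
                    np.flatnonzero(np.isin(pid_arr, list(train_pids))),
                    np.flatnonzero(np.isin(pid_arr, list(val_pids))),
                )
            )
        return out

    def fit(
        self,
        folds: int = 3,
        seed: int = 0,
        grid: list[tuple[str, dict]] | None = None,
    ) -> "HotspotResponseResults":
        """Grid-search the candidate families and refit the winner.

        Every (algorithm, hyperparameters) candidate is scored by its
        mean hotspot-level validation accuracy over patient-disjoint
        stratified ``folds``-fold CV; the best candidate (ties resolved
        by canonical grid order) is refitted on all training hotspots.
        """
        if grid is None:
            grid = default_candidate_grid(seed=seed)
        if not grid:
            raise ValidationError("candidate grid is empty")
        fold_indices = self._patient_folds(folds, seed)
        X = self.features.to_numpy(dtype=float)
        y = (self.labels == POSITIVE_LABEL).to_numpy(dtype=int)

        records = []
        best_idx = -1
        best_acc = -np.inf
        for i, (algorithm, params) in enumerate(grid):
            accs = []
            for train_idx, val_idx in fold_indices:
                est = _make_estimator(algorithm, params)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # MLP iteration-cap warnings
                    est.fit(X[train_idx], y[train_idx])
                accs.append(float((est.predict(X[val_idx]) == y[val_idx]).mean()))
            mean_acc = float(np.mean(accs))
            records.append(
                {
                    "algorithm": algorithm,
                    "params": repr(params),
                    "mean_val_accuracy": mean_acc,
                }
            )
            if mean_acc > best_acc:
                best_acc = mean_acc
                best_idx = i

        algorithm, params = grid[best_idx]
        estimator = _make_estimator(algorithm, params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            estimator.fit(X, y)
        return HotspotResponseResults(
            model=self,
            algorithm=algorithm,
            params=dict(params),
            cv_accuracy=best_acc,
            cv_table=pd.DataFrame.from_records(records),
            estimator=estimator,
            folds=folds,
            seed=seed,
        )


@dataclass
class HotspotResponseResults:
    """Fitted response model: selected candidate, CV table, predictions."""

    model: HotspotResponseModel
    algorithm: str
    params: dict
    cv_accuracy: float
    cv_table: pd.DataFrame
    estimator: object
    folds: int
    seed: int

    @property
    def standardization(self) -> dict[str, list[float]] | None:
        """Per-feature mean/sd learned on training data (None for LDA)."""
        if isinstance(self.estimator, Pipeline):
            scaler = self.estimator.named_steps["scale"]
            return {
                "mean": scaler.mean_.tolist(),
                "scale": scaler.scale_.tolist(),
            }
        return None

    def _scores(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(X), dtype=float)
        return np.asarray(est.predict_proba(X)[:, 1], dtype=float)

    def predict(
        self,
        hotspot_table: pd.DataFrame,
        patient_col: str = "patient_id",
        tie_label: str = POSITIVE_LABEL,
    ) -> PredictionResult:
        """Predict hotspot labels and aggregate per patient by max voting.

        A patient's label is the most frequent label among their hotspot
        predictions; an exact tie (possible only for an even hotspot
        count) resolves to ``tie_label`` (pCR by default). The patient
        score reported for ROC analysis is the fraction of pCR votes.
        """
        if self.estimator is None:
            raise NotFittedError("model has not been fitted")
        X = hotspot_table[self.model.feature_names].to_numpy(dtype=float)
        pred = np.asarray(self.estimator.predict(X), dtype=int)
        scores = self._scores(X)
        hotspots = pd.DataFrame(
            {
                "patient_id": hotspot_table[patient_col].astype(str).to_numpy(),
                "predicted": np.where(pred == 1, POSITIVE_LABEL, NEGATIVE_LABEL),
                "score": scores,
            }
        )
        tie_break = 1 if tie_label == POSITIVE_LABEL else 0
        rows = []
        for pid, grp in hotspots.groupby("patient_id", sort=True):
            votes = (grp["predicted"] == POSITIVE_LABEL).to_numpy()
            frac = float(votes.mean())
            if frac > 0.5:
                label = POSITIVE_LABEL
            elif frac < 0.5:
                label = NEGATIVE_LABEL
            else:
                label = POSITIVE_LABEL if tie_break else NEGATIVE_LABEL
            rows.append(
                {"patient_id": pid, "predicted": label, "pcr_vote_fraction": frac}
            )
        return PredictionResult(hotspots=hotspots, patients=pd.DataFrame(rows))

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels style)."""
        n_hotspots = len(self.model.features)
        n_patients = self.model.patient_labels.shape[0]
        lines = [
            "Hotspot NAC-Response Model Results",
            "=" * 46,
            f"{'Selected algorithm:':<28}{self.algorithm}",
            f"{'Hyperparameters:':<28}{self.params}",
            f"{'Mean CV accuracy:':<28}{self.cv_accuracy:.3f} ({self.folds}-fold, patient-disjoint)",
            f"{'Hotspots (train):':<28}{n_hotspots}",
            f"{'Patients (train):':<28}{n_patients}",
            f"{'Features:':<28}{', '.join(self.model.feature_names)}",
            f"{'Candidates evaluated:':<28}{len(self.cv_table)}",
            f"{'Positive class:':<28}{POSITIVE_LABEL}",
            "=" * 46,
        ]
        return "\n".join(lines)


def predict_patients(
    results: HotspotResponseResults | None, hotspot_table: pd.DataFrame
) -> PredictionResult:
    """Functional wrapper around :meth:`HotspotResponseResults.predict`."""
    if results is None or getattr(results, "estimator", None) is None:
        raise NotFittedError("predict_patients requires a fitted model")
    return results.predict(hotspot_table)
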