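"""Train, select and apply the three binary mechanism classifiers.

Each mechanism (PB, TPI, ALCB) gets its own binary classifier chosen from a
bank of five families — random forest (RF), gradient-boosted decision trees
(GBDT), extreme gradient boosting (XGB), support-vector machine (SVM) and
logistic regression (LR).  Every model is a pipeline of training-median
imputation (feature circles can miss the iris, leaving NaN markers),
per-feature standardization fitted on the training rows only, and the
classifier with the hyperparameters pinned in ``data/hyperparams.yaml``.

Dataset splitting is patient-grouped: images from the same patient never
straddle the train/test boundary.  Model selection ranks by MCC, with ties
broken by F1, accuracy, sensitivity, and finally the fixed algorithm order
RF < GBDT < XGB < SVM < LR, making selection total and deterministic.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import yaml
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FEATURE_COLUMNS, FeatureRow
from .geometry import AngleMechError
from .metrics import binary_metrics, confusion

__all__ = [
    "AlgorithmId",
    "Mechanism",
    "LabeledDataset",
    "TrainedModel",
    "MechanismCall",
    "SplitError",
    "DegenerateLabelsError",
    "SchemaError",
    "split_dataset",
    "train_model",
    "predict_mechanism",
    "select_best_model",
    "selection_rank_key",
    "TEST_FRACTION",
]

TEST_FRACTION = 0.25
DEFAULT_THRESHOLD = 0.5


class SplitError(AngleMechError):
    pass


class DegenerateLabelsError(AngleMechError):
    pass


class SchemaError(AngleMechError):
    pass


class AlgorithmId(str, Enum):
    RF = "RF"
    GBDT = "GBDT"
    XGB = "XGB"
    SVM = "SVM"
    LR = "LR"


#: fixed tie-break order for model selection
ALGORITHM_ORDER = [AlgorithmId.RF, AlgorithmId.GBDT, AlgorithmId.XGB,
                   AlgorithmId.SVM, AlgorithmId.LR]


class Mechanism(str, Enum):
    PB = "pb"
    TPI = "tpi"
    ALCB = "alcb"


def _hyperparams() -> dict:
    with importlib.resources.files("anglemech").joinpath("data/hyperparams.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class LabeledDataset:
    """Aligned feature rows, boolean mechanism labels and patient groups."""

    features: pd.DataFrame  # must contain FEATURE_COLUMNS
    labels: np.ndarray
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.patient_ids = np.asarray(self.patient_ids)
        n = len(self.features)
        if not (len(self.labels) == len(self.patient_ids) == n):
            raise SchemaError("features, labels and patient ids must be aligned")
        missing = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing:
            raise SchemaError(f"feature table lacks columns {missing}")

    @classmethod
    def from_feature_rows(
        cls, rows: Sequence[FeatureRow], labels: Sequence[bool], patient_ids: Sequence[str]
    ) -> "LabeledDataset":
        table = pd.DataFrame([r.to_dict() for r in rows])
        return cls(features=table, labels=np.asarray(labels), patient_ids=np.asarray(patient_ids))

    @property
    def X(self) -> np.ndarray:
        return self.features[FEATURE_COLUMNS].to_numpy(dtype=float)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            patient_ids=self.patient_ids[idx],
        )

    def __len__(self) -> int:
        return len(self.features)


def split_dataset(ds: LabeledDataset, seed: int) -> tuple[LabeledDataset, LabeledDataset]:
    """Patient-grouped random 3:1 split, reproducible for a fixed seed."""
    if len(np.unique(ds.patient_ids)) < 2:
        raise SplitError("at least two patients are required for a grouped split")
    splitter = GroupShuffleSplit(n_splits=1, test_size=TEST_FRACTION, random_state=seed)
    train_idx, test_idx = next(splitter.split(ds.X, ds.labels, groups=ds.patient_ids))
    return ds.subset(train_idx), ds.subset(test_idx)


def _make_classifier(algorithm: AlgorithmId, seed: int, min_class_count: int = 3):
    hp = _hyperparams()[algorithm.value]
    if algorithm is AlgorithmId.RF:
        return RandomForestClassifier(random_state=seed, **hp)
    if algorithm is AlgorithmId.GBDT:
        return GradientBoostingClassifier(random_state=seed, **hp)
    if algorithm is AlgorithmId.XGB:
        return XGBClassifier(random_state=seed, **hp)
    if algorithm is AlgorithmId.SVM:
        # sigmoid-calibrated SVC provides the probability surface; fold count
        # bounded by the rarer class so tiny cohorts remain trainable
        cv = max(2, min(3, min_class_count))
        return CalibratedClassifierCV(SVC(random_state=seed, **hp), cv=cv, ensemble=False)
    if algorithm is AlgorithmId.LR:
        return LogisticRegression(random_state=seed, **hp)
    raise ValueError(algorithm)


@dataclass
class TrainedModel:
    """Fitted imputation/standardization/classifier pipeline with provenance."""

    algorithm: AlgorithmId
    target: Mechanism
    pipeline: Pipeline
    feature_schema: list[str]
    threshold: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise SchemaError("decision threshold must lie in (0, 1)")

    @property
    def imputation_medians(self) -> np.ndarray:
        return self.pipeline.named_steps["impute"].statistics_

    @property
    def standardization(self) -> tuple[np.ndarray, np.ndarray]:
        sc = self.pipeline.named_steps["scale"]
        return sc.mean_, sc.scale_

    # -- persistence: JSON metadata + joblib parameter blob ---------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "algorithm": self.algorithm.value,
            "target": self.target.value,
            "feature_schema": self.feature_schema,
            "threshold": self.threshold,
            "seed": self.seed,
            "blob": path.with_suffix(".joblib").name,
        }
        path.write_text(json.dumps(meta, indent=2))
        joblib.dump(self.pipeline, path.with_suffix(".joblib"))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.read_text())
        pipeline = joblib.load(path.parent / meta["blob"])
        return cls(
            algorithm=AlgorithmId(meta["algorithm"]),
            target=Mechanism(meta["target"]),
            pipeline=pipeline,
            feature_schema=meta["feature_schema"],
            threshold=meta["threshold"],
            seed=meta["seed"],
        )


def train_model(
    train: LabeledDataset,
    algorithm: AlgorithmId,
    target: Mechanism,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> TrainedModel:
    """Fit one mechanism classifier on training rows only.

    Pipeline: median imputation of NaN markers -> per-feature
    standardization -> classifier; all constants estimated from ``train``,
    so the test set can never leak into them.
    """
    y = train.labels
    if y.all() or not y.any():
        raise DegenerateLabelsError(
            f"training labels for {target.value} contain a single class"
        )
    min_class_count = int(min(y.sum(), (~y).sum()))
    pipe = Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", _make_classifier(algorithm, seed, min_class_count)),
        ]
    )
    pipe.fit(train.X, y)
    return TrainedModel(
        algorithm=algorithm,
        target=target,
        pipeline=pipe,
        feature_schema=list(FEATURE_COLUMNS),
        threshold=threshold,
        seed=seed,
    )


def _row_matrix(model: TrainedModel, row) -> np.ndarray:
    if isinstance(row, FeatureRow):
        values = row.to_dict()
    elif isinstance(row, pd.Series):
        values = row.to_dict()
    elif isinstance(row, dict):
        values = row
    else:
        raise SchemaError(f"unsupported feature row type {type(row)!r}")
    try:
        return np.array([[float(values[c]) for c in model.feature_schema]])
    except KeyError as exc:
        raise SchemaError(f"feature row lacks column {exc}") from exc


def predict_mechanism(model: TrainedModel, row) -> tuple[float, bool]:
    """Probability of mechanism presence and the thresholded call.

    The boolean uses the >= convention: probability exactly at threshold is
    a positive call."""
    X = _row_matrix(model, row)
    prob = float(model.pipeline.predict_proba(X)[0, 1])
    return prob, bool(prob >= model.threshold)


def predict_probabilities(model: TrainedModel, ds: LabeledDataset) -> np.ndarray:
    return model.pipeline.predict_proba(ds.features[model.feature_schema].to_numpy(float))[:, 1]


@dataclass(frozen=True)
class MechanismCall:
    """Three mechanism verdicts with their probabilities."""

    pb: bool
    tpi: bool
    alcb: bool
    p_pb: float
    p_tpi: float
    p_alcb: float


def selection_rank_key(
    mcc: float, f1: float, accuracy: float, sensitivity: float, algorithm: AlgorithmId
) -> tuple:
    """Total, deterministic ranking key: MCC first, ties broken by F1, then
    accuracy, then sensitivity, then the fixed algorithm order.  Lower keys
    rank better; undefined (NaN) metrics rank below any defined value."""

    def safe(v: float) -> float:
        return v if np.isfinite(v) else -np.inf

    return (
        -safe(mcc),
        -safe(f1),
        -safe(accuracy),
        -safe(sensitivity),
        ALGORITHM_ORDER.index(algorithm),
    )


def _selection_key(model: TrainedModel, validation: LabeledDataset):
    probs = predict_probabilities(model, validation)
    pred = probs >= model.threshold
    rep = binary_metrics(confusion(validation.labels, pred))
    return selection_rank_key(rep.mcc, rep.f1, rep.accuracy, rep.sensitivity, model.algorithm)


def select_best_model(
    candidates: Sequence[TrainedModel], validation: LabeledDataset
) -> TrainedModel:
    """Highest-MCC model on the validation set.

    Ties broken by F1, then accuracy, then sensitivity, then the fixed
    algorithm order; the result is deterministic."""
    if not candidates:
        raise AngleMechError("empty candidate list")
    keyed = sorted(range(len(candidates)),
                   key=lambda i: _selection_key(candidates[i], validation))
    return candidates[keyed[0]]
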