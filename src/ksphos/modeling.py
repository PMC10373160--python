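"""Per-cluster classifiers: training, evaluation, persistence, scoring.

Two algorithms are supported: gradient-boosted trees (xgboost, the
default) and an RBF support-vector machine with calibrated probability
outputs.  Evaluation follows the standard confusion-matrix metric suite
(accuracy, recall, precision, F1), their support-weighted two-class
variants, and the ROC AUC, under stratified k-fold cross-validation
(k = 10 by default).

The statsmodels-style entry points are :class:`PhosphositeModel` (built
from a :class:`~ksphos.dataset.SiteCluster`) and the
:class:`PhosphositeResults` object its ``fit`` returns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .dataset import SiteCluster
from .encoding import encode_batch, feature_layout, load_blosum62
from .seqio import ProteinRecord, SiteRecord
from .windowing import (
    DEFAULT_FLANK,
    ResidueClass,
    Window,
    enumerate_candidates,
    extract_window,
)

REGISTRY_VERSION = 1

DEFAULT_HYPERPARAMETERS = {
    "gbtree": {"n_estimators": 300, "max_depth": 6, "learning_rate": 0.1},
    "svm": {"C": 1.0, "kernel": "rbf", "gamma": "scale"},
}


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice, hyperparameters, seed and decision threshold."""

    algorithm: str = "gbtree"  # "gbtree" | "svm"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.algorithm not in ("gbtree", "svm"):
            raise ValueError(
                f"algorithm must be 'gbtree' or 'svm', got {self.algorithm!r}"
            )

    def resolved_hyperparameters(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        params.update(self.hyperparameters)
        return params

    def build_estimator(self):
        params = self.resolved_hyperparameters()
        if self.algorithm == "gbtree":
            return XGBClassifier(
                random_state=self.seed,
                n_jobs=1,
                tree_method="hist",
                eval_metric="logloss",
                **params,
            )
        # probability outputs via internal sigmoid (Platt) calibration
        return CalibratedClassifierCV(
            SVC(random_state=self.seed, **params),
            method="sigmoid",
            cv=5,
            ensemble=False,
        )


@dataclass
class TrainedModel:
    """A fitted per-cluster classifier with its feature-layout provenance."""

    spec: ModelSpec
    estimator: object
    cluster_id: str
    level: str
    residue_class: ResidueClass
    flank: int
    n_pos: int
    n_neg: int

    @property
    def model_id(self) -> str:
        return f"{self.level}:{self.cluster_id}:{self.residue_class.name}"

    @property
    def layout(self) -> list[tuple[int, str]]:
        return feature_layout(self.flank)

    @property
    def n_features(self) -> int:
        return (2 * self.flank + 1) * 20

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive (phosphosite) class per row."""
        return np.asarray(self.estimator.predict_proba(X))[:, 1]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(
        cls, y_true: Sequence[int], y_pred: Sequence[int], positive: int = 1
    ) -> "ConfusionMatrix":
        yt = np.asarray(y_true) == positive
        yp = np.asarray(y_pred) == positive
        return cls(
            tp=int((yt & yp).sum()),
            tn=int((~yt & ~yp).sum()),
            fp=int((~yt & yp).sum()),
            fn=int((yt & ~yp).sum()),
        )


def compute_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, recall, precision and F1 from a confusion matrix.

    Degenerate denominators follow the zero convention: a metric whose
    denominator is zero is reported as 0 (and F1 is 0 when
    precision + recall = 0).
    """
    if cm.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return {
        "accuracy": accuracy,
        "recall": recall,
        "precision": precision,
        "f1": f1,
    }


def weighted_metrics(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> dict[str, float]:
    """Support-weighted means of the per-class metric suite.

    Each class is treated in turn as the positive class; its metrics are
    averaged with weights equal to the class's share of the true labels.
    Note that support-weighted recall telescopes to plain accuracy.
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.size == 0:
        raise ValueError("empty label vectors")
    if yt.shape != yp.shape:
        raise ValueError("label vectors differ in length")
    totals = {k: 0.0 for k in ("accuracy", "recall", "precision", "f1")}
    for cls in np.unique(yt):
        weight = (yt == cls).mean()
        cm = ConfusionMatrix.from_labels(yt, yp, positive=cls)
        for key, value in compute_metrics(cm).items():
            totals[key] += weight * value
    return {f"weighted_{k}": v for k, v in totals.items()}


def auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve: P(random positive outscores a random
    negative), ties counted half."""
    yt = np.asarray(y_true)
    if len(np.unique(yt)) < 2:
        raise ValueError("AUC requires both classes to be present")
    return float(roc_auc_score(yt, np.asarray(scores)))


@dataclass
class MetricsReport:
    """Cross-validation metric summary with the per-fold breakdown."""

    accuracy: float
    recall: float
    precision: float
    f1: float
    weighted_accuracy: float
    weighted_recall: float
    weighted_precision: float
    weighted_f1: float
    auc: float
    folds: Optional[pd.DataFrame] = None

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in (
                "accuracy",
                "recall",
                "precision",
                "f1",
                "weighted_accuracy",
                "weighted_recall",
                "weighted_precision",
                "weighted_f1",
                "auc",
            )
        }


def cluster_features(cluster: SiteCluster) -> tuple[np.ndarray, np.ndarray]:
    """Encode a cluster's windows: positives first, then negatives."""
    matrix = load_blosum62()
    X = encode_batch(cluster.positives + cluster.negatives, matrix)
    y = np.concatenate(
        [np.ones(cluster.n_pos, dtype=int), np.zeros(cluster.n_neg, dtype=int)]
    )
    return X, y


def train(cluster: SiteCluster, spec: Optional[ModelSpec] = None) -> TrainedModel:
    """Fit a classifier on the cluster's encoded windows."""
    spec = spec or ModelSpec()
    X, y = cluster_features(cluster)
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"cluster {cluster.cluster_id!r} has a single class "
            f"(n_pos={cluster.n_pos}, n_neg={cluster.n_neg}); cannot train"
        )
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in encoded features")
    estimator = spec.build_estimator()
    estimator.fit(X, y)
    return TrainedModel(
        spec=spec,
        estimator=estimator,
        cluster_id=cluster.cluster_id,
        level=cluster.level,
        residue_class=cluster.residue_class,
        flank=cluster.flank,
        n_pos=cluster.n_pos,
        n_neg=cluster.n_neg,
    )


def cross_validate(
    cluster: SiteCluster,
    spec: Optional[ModelSpec] = None,
    k: int = 10,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold cross-validation of the full metric suite."""
    spec = spec or ModelSpec()
    if k < 2:
        raise ValueError(f"cross-validation needs k >= 2, got k={k}")
    X, y = cluster_features(cluster)
    class_counts = np.bincount(y)
    if (class_counts[class_counts > 0] < k).any():
        raise ValueError(
            f"smallest class has {class_counts[class_counts > 0].min()} "
            f"samples; cannot stratify into k={k} folds"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    template = spec.build_estimator()
    rows = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        est = clone(template)
        est.fit(X[train_idx], y[train_idx])
        scores = np.asarray(est.predict_proba(X[test_idx]))[:, 1]
        y_pred = (scores >= spec.decision_threshold).astype(int)
        y_test = y[test_idx]
        cm = ConfusionMatrix.from_labels(y_test, y_pred)
        row = {"fold": fold, **compute_metrics(cm), **weighted_metrics(y_test, y_pred)}
        row["auc"] = auc(y_test, scores)
        rows.append(row)
    folds = pd.DataFrame(rows)
    means = folds.drop(columns="fold").mean()
    return MetricsReport(folds=folds, **{k_: float(v) for k_, v in means.items()})


@dataclass(frozen=True)
class SitePrediction:
    protein_id: str
    position: int
    residue: str
    window: str
    cluster_id: str
    level: str
    residue_class: str
    score: float
    call: str  # "phospho" | "non-phospho"
    source: str  # "Exp." | "Pred."


def predict_sites(
    proteins: list[ProteinRecord],
    models: list[TrainedModel],
    known_sites: Optional[list[SiteRecord]] = None,
    include_all: bool = False,
) -> list[SitePrediction]:
    """Score every candidate site of each model's residue class.

    By default only sites called phospho (score >= threshold) are
    emitted; ``include_all`` emits every candidate.  Sites present in
    ``known_sites`` are flagged "Exp.", others "Pred.".
    """
    if not models:
        raise ValueError("no models supplied")
    flanks = {m.flank for m in models}
    if len(flanks) > 1:
        raise ValueError(f"models disagree on flank: {sorted(flanks)}")
    matrix = load_blosum62()
    known = {
        (s.substrate_id, s.position) for s in known_sites or []
    }
    out: list[SitePrediction] = []
    for model in models:
        for protein in proteins:
            positions = enumerate_candidates(protein, model.residue_class)
            if not positions:
                continue
            windows = [
                extract_window(protein, p, flank=model.flank) for p in positions
            ]
            X = encode_batch(windows, matrix)
            scores = model.predict_proba(X)
            for w, score in zip(windows, scores):
                call = "phospho" if score >= model.spec.decision_threshold else "non-phospho"
                if call == "non-phospho" and not include_all:
                    continue
                out.append(
                    SitePrediction(
                        protein_id=protein.id,
                        position=w.position,
                        residue=w.center_residue,
                        window=w.sequence,
                        cluster_id=model.cluster_id,
                        level=model.level,
                        residue_class=model.residue_class.name,
                        score=float(score),
                        call=call,
                        source="Exp." if (protein.id, w.position) in known else "Pred.",
                    )
                )
    return out


PREDICTION_COLUMNS = [
    "protein_id",
    "position",
    "residue",
    "window",
    "cluster_id",
    "level",
    "residue_class",
    "score",
    "call",
    "source",
]


def predictions_frame(predictions: list[SitePrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                p.protein_id,
                p.position,
                p.residue,
                p.window,
                p.cluster_id,
                p.level,
                p.residue_class,
                f"{p.score:.6f}",
                p.call,
                p.source,
            )
            for p in predictions
        ],
        columns=PREDICTION_COLUMNS,
    )


def write_predictions(predictions: list[SitePrediction], path: Union[str, Path]) -> None:
    predictions_frame(predictions).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# model registry

def save_registry(models: list[TrainedModel], path: Union[str, Path]) -> None:
    """Persist models in a directory: JSON index + one file per predictor."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, model in enumerate(models):
        stem = f"model_{i:04d}"
        if model.spec.algorithm == "gbtree":
            fname = f"{stem}.xgb.json"
            model.estimator.get_booster().save_model(str(path / fname))
        else:
            fname = f"{stem}.joblib"
            joblib.dump(model.estimator, path / fname)
        entries.append(
            {
                "model_id": model.model_id,
                "file": fname,
                "algorithm": model.spec.algorithm,
                "hyperparameters": model.spec.resolved_hyperparameters(),
                "seed": model.spec.seed,
                "decision_threshold": model.spec.decision_threshold,
                "cluster_id": model.cluster_id,
                "level": model.level,
                "residue_class": model.residue_class.name,
                "flank": model.flank,
                "n_pos": model.n_pos,
                "n_neg": model.n_neg,
            }
        )
    index = {"version": REGISTRY_VERSION, "models": entries}
    (path / "index.json").write_text(json.dumps(index, indent=2))


def load_registry(path: Union[str, Path]) -> list[TrainedModel]:
    path = Path(path)
    try:
        index = json.loads((path / "index.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read registry index at {path}: {exc}") from exc
    if index.get("version") != REGISTRY_VERSION:
        raise ValueError(
            f"registry version {index.get('version')!r} does not match "
            f"supported version {REGISTRY_VERSION}"
        )
    models: list[TrainedModel] = []
    for entry in index["models"]:
        spec = ModelSpec(
            algorithm=entry["algorithm"],
            hyperparameters=entry["hyperparameters"],
            seed=entry["seed"],
            decision_threshold=entry["decision_threshold"],
        )
        if entry["algorithm"] == "gbtree":
            estimator = XGBClassifier()
            estimator.load_model(str(path / entry["file"]))
        else:
            estimator = joblib.load(path / entry["file"])
        models.append(
            TrainedModel(
                spec=spec,
                estimator=estimator,
                cluster_id=entry["cluster_id"],
                level=entry["level"],
                residue_class=ResidueClass[entry["residue_class"]],
                flank=entry["flank"],
                n_pos=entry["n_pos"],
                n_neg=entry["n_neg"],
            )
        )
    return models


# ---------------------------------------------------------------------------
# statsmodels-style front end

class PhosphositeModel:
    """A per-cluster phosphosite classifier specification.

    Built from a :class:`SiteCluster`; ``fit()`` trains the classifier
    and returns a :class:`PhosphositeResults`.
    """

    def __init__(self, cluster: SiteCluster, spec: Optional[ModelSpec] = None):
        self.cluster = cluster
        self.spec = spec or ModelSpec()

    @classmethod
    def from_tables(
        cls,
        sites: list[SiteRecord],
        substrates: list[ProteinRecord],
        cluster_id: str,
        level: str = "family",
        residue_class: ResidueClass = ResidueClass.ST,
        spec: Optional[ModelSpec] = None,
        **assemble_kwargs,
    ) -> "PhosphositeModel":
        from .dataset import assemble_cluster, ClusterRejection

        cluster = assemble_cluster(
            sites, substrates, cluster_id, level, residue_class, **assemble_kwargs
        )
        if isinstance(cluster, ClusterRejection):
            raise ValueError(
                f"cluster {cluster_id!r} rejected: {cluster.n_positives} unique "
                f"positive sites < required {cluster.min_positives}"
            )
        return cls(cluster, spec=spec)

    def fit(self) -> "PhosphositeResults":
        trained = train(self.cluster, self.spec)
        return PhosphositeResults(self, trained)


class PhosphositeResults:
    """Results of fitting a :class:`PhosphositeModel`.

    Carries the trained classifier; evaluation, prediction and
    explanation hang off this object.
    """

    def __init__(self, model: PhosphositeModel, trained: TrainedModel):
        self.model = model
        self.trained = trained
        self._cv: Optional[MetricsReport] = None

    def cross_validate(self, k: int = 10, seed: int = 0) -> MetricsReport:
        self._cv = cross_validate(self.model.cluster, self.model.spec, k=k, seed=seed)
        return self._cv

    def predict(
        self,
        proteins: list[ProteinRecord],
        known_sites: Optional[list[SiteRecord]] = None,
        include_all: bool = False,
    ) -> pd.DataFrame:
        preds = predict_sites(
            proteins, [self.trained], known_sites=known_sites, include_all=include_all
        )
        return predictions_frame(preds)

    def explain(self, windows: Optional[list[Window]] = None, **kwargs):
        """Position-grouped Shapley attribution (see :mod:`ksphos.explain`)."""
        from . import explain as _explain

        cluster = self.model.cluster
        matrix = load_blosum62()
        targets = windows if windows is not None else cluster.positives
        instances = encode_batch(targets, matrix)
        background = encode_batch(cluster.negatives, matrix)
        explanations = _explain.explain_instances(
            self.trained, instances, background, **kwargs
        )
        return _explain.group_by_position(explanations, self.trained.layout)

    def summary(self) -> str:
        cluster = self.model.cluster
        spec = self.model.spec
        lines = [
            "Phosphosite classifier results",
            "=" * 34,
            f"cluster:        {cluster.cluster_id} ({cluster.level})",
            f"residue class:  {cluster.residue_class.name}",
            f"algorithm:      {spec.algorithm}",
            f"positives:      {cluster.n_pos}",
            f"negatives:      {cluster.n_neg}",
            f"flank:          {cluster.flank} (window length {2 * cluster.flank + 1})",
            f"features:       {(2 * cluster.flank + 1) * 20}",
            f"seed:           {spec.seed}",
        ]
        if self._cv is not None:
            lines.append("")
            lines.append(f"{self._cv.folds.shape[0]}-fold cross-validation (means)")
            lines.append("-" * 34)
            for key, value in self._cv.as_dict().items():
                lines.append(f"{key:<20s}{value:.3f}")
        return "\n".join(lines)
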