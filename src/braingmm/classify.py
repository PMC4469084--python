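"""Three benchmark classifiers, leave-one-out CV and the shared-denominator metrics.

Classifiers: kernel naive Bayes (per-feature Gaussian KDE, Silverman
bandwidth), soft-margin SVM with an RBF kernel, and a probabilistic neural
network (Parzen-window posterior with isotropic Gaussian kernels).  All
three are scale-sensitive, so features are z-scored by default using
statistics of the training fold only.

Metrics share one denominator (the total sample count):

    accuracy         = correctly classified / total
    false alarm      = normal misclassified as tumor / total
    missed detection = tumor misclassified as normal / total

so accuracy + false alarm + missed detection = 100% identically.  ROC/AUC
come from the score sweep; AUC equals the Mann-Whitney pair statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "LabeledDataset",
    "EvalReport",
    "fit_predict_nb",
    "fit_predict_svm",
    "fit_predict_pnn",
    "loocv",
    "compute_metrics",
    "roc_auc",
    "evaluate",
]

POS_LABEL = "GBM"


@dataclass
class LabeledDataset:
    """n x d features with two-class labels and optional patient group ids."""

    features: np.ndarray
    labels: np.ndarray
    groups: Optional[np.ndarray] = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("labels must match feature rows")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape[0] != self.features.shape[0]:
                raise ValueError("groups must match feature rows")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @classmethod
    def from_feature_matrix(cls, fm, group_key: str = "patient") -> "LabeledDataset":
        groups = None
        if fm.provenance and all(group_key in p for p in fm.provenance):
            groups = np.array([p[group_key] for p in fm.provenance])
        return cls(features=fm.values, labels=np.array(fm.labels), groups=groups)


def _check_two_classes(y):
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes in the training set, got {classes.tolist()}")
    return classes


def _silverman_bandwidth(x: np.ndarray, floor: float) -> float:
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    spread = min(spread_candidates) if spread_candidates else 0.0
    h = 0.9 * spread * n ** (-0.2)
    return max(h, floor)


def fit_predict_nb(train: LabeledDataset, test_X, pos_label: str = POS_LABEL):
    """Kernel naive Bayes: prior x product of per-feature Gaussian KDEs.

    Returns (predicted labels, posterior of the positive class).  Features
    with zero training spread fall back to a minimum-bandwidth floor.
    """
    classes = _check_two_classes(train.labels)
    X, y = train.features, train.labels
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    d = X.shape[1]
    global_sd = X.std(axis=0, ddof=0)
    floors = np.maximum(1e-3 * np.where(global_sd > 0, global_sd, 1.0), 1e-9)

    log_post = np.zeros((test_X.shape[0], 2))
    for ci, c in enumerate(classes):
        Xc = X[y == c]
        log_prior = np.log(Xc.shape[0] / X.shape[0])
        ll = np.full(test_X.shape[0], log_prior)
        for j in range(d):
            h = _silverman_bandwidth(Xc[:, j], floors[j])
            z = (test_X[:, j][:, None] - Xc[:, j][None, :]) / h
            # mean of Gaussian kernels, in log space
            ll += logsumexp(-0.5 * z**2, axis=1) - np.log(Xc.shape[0]) - 0.5 * np.log(2 * np.pi) - np.log(h)
        log_post[:, ci] = ll
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    pred = classes[np.argmax(log_post, axis=1)]
    pos_idx = int(np.flatnonzero(classes == pos_label)[0]) if pos_label in classes else 1
    return pred, post[:, pos_idx]


def fit_predict_svm(train: LabeledDataset, test_X, rbf_gamma="scale", cost: float = 1.0,
                    pos_label: str = POS_LABEL):
    """RBF soft-margin SVM; returns (labels, signed decision values).

    Default gamma is 1 / (d x pooled feature variance); decision values are
    oriented so positive means the positive (tumor) class.
    """
    from sklearn.svm import SVC

    _check_two_classes(train.labels)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    y01 = (train.labels == pos_label).astype(int)
    clf = SVC(kernel="rbf", gamma=rbf_gamma, C=cost)
    clf.fit(train.features, y01)
    dec = clf.decision_function(test_X)
    pred01 = clf.predict(test_X)
    neg = np.unique(train.labels[y01 == 0])[0]
    pred = np.where(pred01 == 1, pos_label, neg)
    return pred, dec


def fit_predict_pnn(train: LabeledDataset, test_X, spread: float = 0.1,
                    pos_label: str = POS_LABEL):
    """Probabilistic neural network: Parzen-window class posteriors.

    Per class, the pattern layer averages isotropic Gaussian kernels of
    bandwidth ``spread`` centered at the class's training points; the
    decision is the argmax posterior.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    classes = _check_two_classes(train.labels)
    X, y = train.features, train.labels
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    log_score = np.zeros((test_X.shape[0], 2))
    for ci, c in enumerate(classes):
        Xc = X[y == c]
        d2 = ((test_X[:, None, :] - Xc[None, :, :]) ** 2).sum(axis=2)
        log_score[:, ci] = logsumexp(-d2 / (2.0 * spread**2), axis=1) - np.log(Xc.shape[0])
    log_score -= logsumexp(log_score, axis=1, keepdims=True)
    post = np.exp(log_score)
    pred = classes[np.argmax(log_score, axis=1)]
    pos_idx = int(np.flatnonzero(classes == pos_label)[0]) if pos_label in classes else 1
    return pred, post[:, pos_idx]


_CLASSIFIERS = {
    "nb": fit_predict_nb,
    "svm": fit_predict_svm,
    "pnn": fit_predict_pnn,
}

ClassifierSpec = Union[str, Callable]


def _resolve_classifier(classifier: ClassifierSpec) -> Callable:
    if callable(classifier):
        return classifier
    try:
        return _CLASSIFIERS[classifier]
    except KeyError:
        raise ValueError(f"unknown classifier {classifier!r}; choose from {sorted(_CLASSIFIERS)}")


def loocv(
    data: LabeledDataset,
    classifier: ClassifierSpec = "nb",
    standardize: bool = True,
    group_by_patient: bool = False,
    pca_components: Optional[int] = None,
    pos_label: str = POS_LABEL,
    **clf_kwargs,
):
    """Leave-one-out (or leave-one-patient-out) predictions.

    Each sample is predicted exactly once by a model trained on the rest.
    Standardization statistics — and, when ``pca_components`` is set, the
    pooled PCA basis — are computed from the training fold only.
    Returns (predicted labels, positive-class scores).
    """
    if data.n < 3:
        raise ValueError("need at least 3 samples for leave-one-out CV")
    fn = _resolve_classifier(classifier)
    if group_by_patient:
        if data.groups is None:
            raise ValueError("group_by_patient requires group ids")
        fold_ids = data.groups
    else:
        fold_ids = np.arange(data.n)

    preds = np.empty(data.n, dtype=object)
    scores = np.empty(data.n, dtype=float)
    for fid in np.unique(fold_ids):
        test_idx = np.flatnonzero(fold_ids == fid)
        train_idx = np.flatnonzero(fold_ids != fid)
        ytr = data.labels[train_idx]
        if np.unique(ytr).size < 2:
            raise ValueError(f"training fold for held-out unit {fid!r} contains a single class")
        Xtr = data.features[train_idx]
        Xte = data.features[test_idx]
        if pca_components is not None:
            from .pca import PCAModel, project

            basis = PCAModel.from_feature_matrix(Xtr, n_retained=pca_components)
            Xtr = project(Xtr, basis).rows
            Xte = project(Xte, basis).rows
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        p, s = fn(LabeledDataset(Xtr, ytr), Xte, pos_label=pos_label, **clf_kwargs)
        preds[test_idx] = p
        scores[test_idx] = s
    return preds.astype(data.labels.dtype), scores


def compute_metrics(predictions, labels, pos_label: str = POS_LABEL) -> dict:
    """Accuracy / false-alarm / missed-detection percentages over one denominator."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty input")
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must align")
    total = labels.size
    is_pos = labels == pos_label
    correct = predictions == labels
    missed = int(np.sum(is_pos & ~correct))
    false_alarm = int(np.sum(~is_pos & ~correct))
    return {
        "n": int(total),
        "tumor_correct": int(np.sum(is_pos & correct)),
        "tumor_missed": missed,
        "normal_correct": int(np.sum(~is_pos & correct)),
        "normal_false_alarm": false_alarm,
        "accuracy": 100.0 * correct.sum() / total,
        "false_alarm": 100.0 * false_alarm / total,
        "missed_detection": 100.0 * missed / total,
    }


def roc_auc(scores, labels, pos_label: str = POS_LABEL):
    """ROC points (FPR, TPR) and AUC in percent; AUC = Mann-Whitney statistic."""
    from sklearn.metrics import roc_auc_score, roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = (labels == pos_label).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = roc_curve(y, scores)
    auc = 100.0 * roc_auc_score(y, scores)
    return fpr, tpr, float(auc)


@dataclass
class EvalReport:
    """Per-classifier LOOCV outcome: confusion counts, metrics, ROC, AUC."""

    results: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def add(self, name: str, metrics: dict, fpr, tpr, auc: float) -> None:
        self.results[name] = {
            **metrics,
            "auc": auc,
            "roc_fpr": np.asarray(fpr).tolist(),
            "roc_tpr": np.asarray(tpr).tolist(),
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, r in self.results.items():
            rows.append(
                {
                    "classifier": name,
                    "n": r["n"],
                    "accuracy": r["accuracy"],
                    "false_alarm": r["false_alarm"],
                    "missed_detection": r["missed_detection"],
                    "auc": r["auc"],
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {"meta": self.meta, "results": self.results}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate(
    data: LabeledDataset,
    classifiers: Sequence[str] = ("nb", "svm", "pnn"),
    standardize: bool = True,
    group_by_patient: bool = False,
    pca_components: Optional[int] = None,
    pos_label: str = POS_LABEL,
    classifier_options: Optional[dict] = None,
) -> EvalReport:
    """LOOCV-evaluate each classifier and collect metrics + ROC/AUC."""
    report = EvalReport(
        meta={
            "n_samples": data.n,
            "standardize": standardize,
            "group_by_patient": group_by_patient,
            "pca_components": pca_components,
        }
    )
    options = classifier_options or {}
    for name in classifiers:
        preds, scores = loocv(
            data,
            classifier=name,
            standardize=standardize,
            group_by_patient=group_by_patient,
            pca_components=pca_components,
            pos_label=pos_label,
            **options.get(name, {}),
        )
        metrics = compute_metrics(preds, data.labels, pos_label=pos_label)
        fpr, tpr, auc = roc_auc(scores, data.labels, pos_label=pos_label)
        report.add(name, metrics, fpr, tpr, auc)
    return report
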