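"""Expert fitness-level classification from physiological records.

Each subject is encoded as an ordered eight-feature vector

    [gender, age, weight, bmi, flexibility, reaction_time, grip_strength, balance]

(gender coded male=1 / female=0; reaction time is a latency score, so
larger means slower).  For each of the four physical tests —
flexibility, balance, grip strength, reaction time — an expert assigns
one of three fitness levels: ``strong``, ``moderate`` or ``weak``.  The
pipeline trains one classifier per test and evaluates it with stratified
k-fold cross-validation, reporting per-class precision, recall and F1
and their unweighted (macro) means.

Three classifier families are provided:

* Gaussian naive Bayes — class-conditional independent Gaussians per
  feature, class priors from frequencies, per-class variances floored at
  1e-9; prediction by maximum posterior.
* k-nearest neighbours — Euclidean distance on z-scored features
  (training-set statistics), majority vote, ties broken by the class of
  the nearest neighbour among the tied classes.
* Linear discriminant analysis — pooled within-class covariance (ridge
  1e-6 added if singular) and class priors; prediction by maximum
  discriminant score.

Degenerate metric ratios (0/0) are defined as 0 by convention, never an
exception.
"""

from __future__ import annotations

import json
import math
import os
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import (
    DegenerateModelError,
    DomainError,
    StratificationError,
    ValidationError,
)

FEATURE_NAMES = (
    "gender",
    "age",
    "weight",
    "bmi",
    "flexibility",
    "reaction_time",
    "grip_strength",
    "balance",
)
TESTS = ("flexibility", "balance", "grip_strength", "reaction_time")
LABELS = ("strong", "moderate", "weak")

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# instances and datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawRecord:
    """One subject's physiological record, prior to instance encoding."""

    gender: int
    age: float
    weight: float
    bmi: float
    flexibility: float
    reaction_time: float
    grip_strength: float
    balance: float


def preprocess(raw: RawRecord) -> np.ndarray:
    """Encode a raw record as the ordered eight-feature instance vector."""
    if raw.gender not in (0, 1):
        raise ValidationError(f"gender must be 0 (female) or 1 (male), got {raw.gender!r}")
    values = [getattr(raw, name) for name in FEATURE_NAMES]
    for name, value in zip(FEATURE_NAMES, values):
        if value is None or not math.isfinite(float(value)):
            raise ValidationError(f"feature {name!r} must be a finite number")
        if float(value) < 0:
            raise ValidationError(f"feature {name!r} must be non-negative")
    return np.asarray(values, dtype=float)


@dataclass
class LabeledDataset:
    """Instances plus one label sequence per fitness test."""

    X: np.ndarray                      # (n, 8)
    labels: dict                       # test -> array of label strings, length n
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(FEATURE_NAMES):
            raise ValidationError("X must be an (n, 8) feature matrix")
        for test in TESTS:
            if test not in self.labels:
                raise ValidationError(f"missing label sequence for test {test!r}")
            y = np.asarray(self.labels[test])
            if len(y) != len(self.X):
                raise ValidationError(f"label list for {test!r} does not match instance count")
            bad = set(y) - set(LABELS)
            if bad:
                raise ValidationError(f"labels outside {LABELS}: {sorted(bad)}")
            self.labels[test] = y

    def __len__(self) -> int:
        return len(self.X)


def _validate_labels(y) -> np.ndarray:
    y = np.asarray(y)
    bad = set(y) - set(LABELS)
    if bad:
        raise ValidationError(f"labels outside {LABELS}: {sorted(bad)}")
    return y


def _present_classes(y: np.ndarray) -> list:
    present = set(y)
    return [c for c in LABELS if c in present]


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

class GaussianNBClassifier:
    """Gaussian class-conditional naive Bayes."""

    kind = "naive_bayes"
    VAR_FLOOR = 1e-9

    def __init__(self):
        self.classes_ = None
        self.priors_ = None
        self.means_ = None
        self.vars_ = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = _validate_labels(y)
        classes = _present_classes(y)
        if len(classes) < 2:
            raise DegenerateModelError("naive Bayes needs at least two classes present")
        self.classes_ = classes
        self.priors_ = np.array([np.mean(y == c) for c in classes])
        self.means_ = np.array([X[y == c].mean(axis=0) for c in classes])
        self.vars_ = np.array(
            [np.maximum(X[y == c].var(axis=0), self.VAR_FLOOR) for c in classes]
        )
        return self

    def log_posterior(self, X) -> np.ndarray:
        """Unnormalised log posterior, shape (n, n_classes)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((len(X), len(self.classes_)))
        for j in range(len(self.classes_)):
            ll = -0.5 * np.sum(
                np.log(2.0 * np.pi * self.vars_[j])
                + (X - self.means_[j]) ** 2 / self.vars_[j],
                axis=1,
            )
            out[:, j] = np.log(self.priors_[j]) + ll
        return out

    def predict_proba(self, X) -> np.ndarray:
        lp = self.log_posterior(X)
        lp = lp - lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        idx = np.argmax(self.log_posterior(X), axis=1)
        return np.asarray(self.classes_)[idx]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "classes": list(self.classes_),
            "priors": self.priors_.tolist(),
            "means": self.means_.tolist(),
            "vars": self.vars_.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GaussianNBClassifier":
        model = cls()
        model.classes_ = list(payload["classes"])
        model.priors_ = np.asarray(payload["priors"], dtype=float)
        model.means_ = np.asarray(payload["means"], dtype=float)
        model.vars_ = np.asarray(payload["vars"], dtype=float)
        return model


class KNNClassifier:
    """k-nearest-neighbour majority vote on z-scored features."""

    kind = "knn"

    def __init__(self, k: int = 3):
        if k < 1:
            raise DomainError("k must be >= 1")
        self.k = k
        self.mu_ = None
        self.sigma_ = None
        self.Xz_ = None
        self.y_ = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = _validate_labels(y)
        if self.k > len(X):
            raise DomainError(f"k={self.k} exceeds the {len(X)} training instances")
        self.mu_ = X.mean(axis=0)
        sigma = X.std(axis=0)
        self.sigma_ = np.where(sigma > 0, sigma, 1.0)  # constant features contribute 0
        self.Xz_ = (X - self.mu_) / self.sigma_
        self.y_ = y
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xz = (X - self.mu_) / self.sigma_
        out = []
        for x in Xz:
            dist = np.linalg.norm(self.Xz_ - x, axis=1)
            order = np.argsort(dist, kind="stable")
            top = order[: self.k]
            votes = Counter(self.y_[top])
            best = max(votes.values())
            tied = [c for c, v in votes.items() if v == best]
            if len(tied) == 1:
                out.append(tied[0])
            else:
                # tie: the class (among those tied) of the single nearest neighbour
                for idx in top:
                    if self.y_[idx] in tied:
                        out.append(self.y_[idx])
                        break
        return np.asarray(out)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "k": self.k,
            "mu": self.mu_.tolist(),
            "sigma": self.sigma_.tolist(),
            "Xz": self.Xz_.tolist(),
            "y": self.y_.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "KNNClassifier":
        model = cls(k=int(payload["k"]))
        model.mu_ = np.asarray(payload["mu"], dtype=float)
        model.sigma_ = np.asarray(payload["sigma"], dtype=float)
        model.Xz_ = np.asarray(payload["Xz"], dtype=float)
        model.y_ = np.asarray(payload["y"])
        return model


class LDAClassifier:
    """Linear discriminant analysis with pooled within-class covariance."""

    kind = "lda"
    RIDGE = 1e-6

    def __init__(self):
        self.classes_ = None
        self.coef_ = None
        self.intercept_ = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = _validate_labels(y)
        classes = _present_classes(y)
        if len(classes) < 2:
            raise DegenerateModelError("LDA needs at least two classes present")
        n, p = X.shape
        if n - len(classes) < 1:
            raise DegenerateModelError("too few samples to estimate the pooled covariance")
        means = np.array([X[y == c].mean(axis=0) for c in classes])
        priors = np.array([np.mean(y == c) for c in classes])
        scatter = np.zeros((p, p))
        for c, mu in zip(classes, means):
            diff = X[y == c] - mu
            scatter += diff.T @ diff
        cov = scatter / (n - len(classes))
        try:
            inv = np.linalg.inv(cov)
            if not np.all(np.isfinite(inv)) or np.linalg.cond(cov) > 1e12:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            inv = np.linalg.inv(cov + self.RIDGE * np.eye(p))
        self.classes_ = classes
        self.coef_ = means @ inv                       # one row per class
        self.intercept_ = (
            -0.5 * np.einsum("ij,ij->i", means @ inv, means) + np.log(priors)
        )
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef_.T + self.intercept_

    def predict(self, X) -> np.ndarray:
        idx = np.argmax(self.decision_function(X), axis=1)
        return np.asarray(self.classes_)[idx]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "classes": list(self.classes_),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LDAClassifier":
        model = cls()
        model.classes_ = list(payload["classes"])
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        model.intercept_ = np.asarray(payload["intercept"], dtype=float)
        return model


_LEARNERS = {
    "naive_bayes": GaussianNBClassifier,
    "knn": KNNClassifier,
    "lda": LDAClassifier,
}


def make_learner(name: str, **kwargs):
    """Instantiate a classifier by name (``naive_bayes``, ``knn``, ``lda``)."""
    try:
        cls = _LEARNERS[name]
    except KeyError:
        raise DomainError(f"unknown learner {name!r}; expected one of {sorted(_LEARNERS)}")
    return cls(**kwargs)


def train_naive_bayes(data: LabeledDataset, test: str) -> GaussianNBClassifier:
    return GaussianNBClassifier().fit(data.X, data.labels[test])


def train_knn(data: LabeledDataset, test: str, k: int = 3) -> KNNClassifier:
    return KNNClassifier(k=k).fit(data.X, data.labels[test])


def train_lda(data: LabeledDataset, test: str) -> LDAClassifier:
    return LDAClassifier().fit(data.X, data.labels[test])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class true-positive / false-positive / false-negative counts."""

    tp: dict
    fp: dict
    fn: dict


@dataclass(frozen=True)
class MetricsReport:
    precision: dict
    recall: dict
    f1: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def to_dict(self) -> dict:
        return {
            "precision": dict(self.precision),
            "recall": dict(self.recall),
            "f1": dict(self.f1),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = _validate_labels(y_true)
    y_pred = _validate_labels(y_pred)
    if len(y_true) != len(y_pred):
        raise DomainError("y_true and y_pred must have equal lengths")
    tp, fp, fn = {}, {}, {}
    for c in LABELS:
        tp[c] = int(np.sum((y_true == c) & (y_pred == c)))
        fp[c] = int(np.sum((y_true != c) & (y_pred == c)))
        fn[c] = int(np.sum((y_true == c) & (y_pred != c)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def precision_recall_f1(counts: ConfusionCounts) -> MetricsReport:
    """Per-class precision, recall and F1 plus unweighted macro averages.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 the harmonic mean of
    the two; every 0/0 ratio is defined as 0.
    """
    precision, recall, f1 = {}, {}, {}
    for c in LABELS:
        p = _safe_div(counts.tp[c], counts.tp[c] + counts.fp[c])
        r = _safe_div(counts.tp[c], counts.tp[c] + counts.fn[c])
        precision[c] = p
        recall[c] = r
        f1[c] = _safe_div(2.0 * p * r, p + r)
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=macro_average(list(precision.values())),
        macro_recall=macro_average(list(recall.values())),
        macro_f1=macro_average(list(f1.values())),
    )


def macro_average(values) -> float:
    """Unweighted arithmetic mean — the aggregation used for all macro scores."""
    return float(np.mean(np.asarray(values, dtype=float)))


# ---------------------------------------------------------------------------
# cross-validation and the full evaluation grid
# ---------------------------------------------------------------------------

def kfold_cv(data: LabeledDataset, test: str, learner, k_folds: int = 4, seed: int = 0) -> MetricsReport:
    """Stratified k-fold cross-validation of one learner on one test's labels.

    ``learner`` is a learner name (see :func:`make_learner`) or a
    zero-argument factory returning an unfitted classifier.  Fold metrics
    are averaged with equal weight (per-class and macro alike).
    Deterministic for equal ``(data, seed)``.
    """
    y = data.labels[test]
    counts = Counter(y)
    small = [c for c, n in counts.items() if n < k_folds]
    if small:
        raise StratificationError(
            f"classes {sorted(small)} have fewer than {k_folds} members; cannot stratify"
        )
    factory = (lambda: make_learner(learner)) if isinstance(learner, str) else learner
    splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    reports = []
    for train_idx, test_idx in splitter.split(data.X, y):
        model = factory().fit(data.X[train_idx], y[train_idx])
        pred = model.predict(data.X[test_idx])
        reports.append(precision_recall_f1(confusion(y[test_idx], pred)))
    return MetricsReport(
        precision={c: macro_average([r.precision[c] for r in reports]) for c in LABELS},
        recall={c: macro_average([r.recall[c] for r in reports]) for c in LABELS},
        f1={c: macro_average([r.f1[c] for r in reports]) for c in LABELS},
        macro_precision=macro_average([r.macro_precision for r in reports]),
        macro_recall=macro_average([r.macro_recall for r in reports]),
        macro_f1=macro_average([r.macro_f1 for r in reports]),
    )


@dataclass(frozen=True)
class EvaluationReport:
    """Cross-validated macro-F1 for every learner x test cell."""

    f1_table: dict          # learner -> {test -> macro F1}
    learner_macro: dict     # learner -> mean macro F1 over the four tests
    best_learner: str

    def to_dict(self) -> dict:
        return {
            "f1_table": {k: dict(v) for k, v in self.f1_table.items()},
            "learner_macro": dict(self.learner_macro),
            "learner_macro_percent": {
                k: round(100.0 * v, 1) for k, v in self.learner_macro.items()
            },
            "best_learner": self.best_learner,
        }


def evaluate_all(data: LabeledDataset, k_folds: int = 4, seed: int = 0) -> EvaluationReport:
    """Run every learner on every test under k-fold CV.

    Returns the 3x4 macro-F1 table, each learner's macro average over the
    four tests, and the best learner by that average.
    """
    f1_table = {}
    for learner in _LEARNERS:
        f1_table[learner] = {
            test: kfold_cv(data, test, learner, k_folds=k_folds, seed=seed).macro_f1
            for test in TESTS
        }
    learner_macro = {
        learner: macro_average([row[test] for test in TESTS])
        for learner, row in f1_table.items()
    }
    best = max(learner_macro, key=learner_macro.get)
    return EvaluationReport(f1_table=f1_table, learner_macro=learner_macro, best_learner=best)


# ---------------------------------------------------------------------------
# model persistence and the JSON prediction surface
# ---------------------------------------------------------------------------

def train_models(data: LabeledDataset, learner: str = "naive_bayes", **kwargs) -> dict:
    """Train one classifier per fitness test; returns ``{test: model}``."""
    return {
        test: make_learner(learner, **kwargs).fit(data.X, data.labels[test])
        for test in TESTS
    }


def save_models(models: dict, directory) -> None:
    """Persist trained models as versioned JSON under ``directory``."""
    os.makedirs(directory, exist_ok=True)
    payload = {
        "version": MODEL_FORMAT_VERSION,
        "feature_order": list(FEATURE_NAMES),
        "models": {test: models[test].to_dict() for test in TESTS},
    }
    with open(os.path.join(directory, "models.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_models(directory) -> dict:
    path = os.path.join(directory, "models.json")
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValidationError(f"unsupported model format version {payload.get('version')!r}")
    out = {}
    for test, entry in payload["models"].items():
        cls = _LEARNERS[entry["kind"]]
        out[test] = cls.from_dict(entry)
    return out


def predict_json(models: dict, request) -> dict:
    """Serve one JSON classification request against stored per-test models.

    ``request`` is a dict or a JSON string with exactly the eight feature
    fields.  Returns ``{test: label}`` on success or a structured
    ``{"error": {...}}`` object naming the offending field.
    """
    if isinstance(request, str):
        try:
            request = json.loads(request)
        except json.JSONDecodeError as exc:
            return {"error": {"message": f"invalid JSON: {exc}"}}
    if not isinstance(request, dict):
        return {"error": {"message": "request must be a JSON object"}}

    missing = [f for f in FEATURE_NAMES if f not in request]
    if missing:
        return {"error": {"message": "missing required field", "field": missing[0]}}
    extra = [f for f in request if f not in FEATURE_NAMES]
    if extra:
        return {"error": {"message": "unknown field", "field": extra[0]}}
    for name in FEATURE_NAMES:
        value = request[name]
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            return {"error": {"message": "field must be numeric", "field": name}}
    try:
        vector = preprocess(RawRecord(**{f: request[f] for f in FEATURE_NAMES}))
    except ValidationError as exc:
        return {"error": {"message": str(exc)}}
    return {test: str(models[test].predict(vector[None, :])[0]) for test in TESTS}
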