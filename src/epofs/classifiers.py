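"""Uniform adapter over the five classification learners used in the study.

The wrapper loop and the error estimators are classifier-agnostic: they see a
:class:`ClassifierSpec` and two functions, :func:`make_classifier` (spec ->
fresh scikit-learn estimator) and :func:`fit_predict`.  Distance- and
margin-based learners (k-NN, SVM, MLP) are wrapped in a train-fitted
standardization pipeline; tree learners consume raw expression values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["ClassifierSpec", "KINDS", "make_classifier", "fit_predict"]

KINDS = ("decision_tree", "random_forest", "knn", "svm", "mlp")

# learners whose decision rule depends on feature scale
_SCALED = {"knn", "svm", "mlp"}

_DEFAULTS = {
    "decision_tree": {},
    "random_forest": {"n_estimators": 100},
    "knn": {"n_neighbors": 5},
    "svm": {"kernel": "rbf", "C": 1.0, "probability": True},
    # small-sample microarray regime: a generous patience and validation split
    # keep early stopping from halting before the loss moves at all
    "mlp": {"hidden_layer_sizes": (32,), "early_stopping": True, "max_iter": 500,
            "n_iter_no_change": 25, "validation_fraction": 0.2},
}


@dataclass
class ClassifierSpec:
    """Declarative description of one of the five supported learners.

    ``kind`` is one of ``decision_tree``, ``random_forest``, ``knn``, ``svm``
    or ``mlp`` (a backpropagation-trained feed-forward network).
    ``hyperparameters`` override the defaults and must be valid constructor
    parameters of the underlying scikit-learn estimator; unknown keys are
    rejected at construction time.
    """

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected one of {KINDS}")
        make_classifier(self)  # validates hyperparameter keys eagerly

    def to_dict(self) -> dict:
        d = asdict(self)
        hp = dict(d["hyperparameters"])
        for k, v in hp.items():
            if isinstance(v, tuple):
                hp[k] = list(v)
        d["hyperparameters"] = hp
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        hp = dict(d.get("hyperparameters", {}))
        if "hidden_layer_sizes" in hp and isinstance(hp["hidden_layer_sizes"], list):
            hp["hidden_layer_sizes"] = tuple(hp["hidden_layer_sizes"])
        return cls(kind=d["kind"], hyperparameters=hp, seed=int(d.get("seed", 0)))


def _estimator(spec: ClassifierSpec):
    params = dict(_DEFAULTS[spec.kind])
    params.update(spec.hyperparameters)
    if spec.kind == "decision_tree":
        cls = DecisionTreeClassifier
    elif spec.kind == "random_forest":
        cls = RandomForestClassifier
    elif spec.kind == "knn":
        cls = KNeighborsClassifier
    elif spec.kind == "svm":
        cls = SVC
    else:
        cls = MLPClassifier
    if spec.kind != "knn":
        params.setdefault("random_state", spec.seed)
    valid = cls().get_params()
    unknown = set(params) - set(valid)
    if unknown:
        raise ValueError(f"unknown hyperparameters for {spec.kind}: {sorted(unknown)}")
    return cls(**params)


def make_classifier(spec: ClassifierSpec):
    """Build a fresh, unfitted estimator for ``spec``.

    Returns a scikit-learn ``Pipeline`` with a ``StandardScaler`` front end
    for the scale-sensitive kinds, a bare estimator otherwise.
    """
    est = _estimator(spec)
    if spec.kind in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def fit_predict(
    spec: ClassifierSpec,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Fit a fresh ``spec`` learner and predict labels for ``test_features``.

    Returns ``(labels, scores)`` where ``scores`` is the per-class
    probability matrix when the learner exposes one, else ``None``.
    Deterministic under ``spec.seed`` for the stochastic learners.
    """
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training data contains a single class")
    if train_features.shape[1] != test_features.shape[1]:
        raise ValueError(
            f"feature-count mismatch: train has {train_features.shape[1]}, "
            f"test has {test_features.shape[1]}"
        )
    model = make_classifier(spec)
    model.fit(train_features, train_labels)
    labels = model.predict(test_features)
    scores = None
    if hasattr(model, "predict_proba"):
        try:
            scores = model.predict_proba(test_features)
        except AttributeError:  # e.g. SVC(probability=False)
            scores = None
    return labels, scores
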