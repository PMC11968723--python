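"""Final-model evaluation: confusion-matrix metrics, k-fold CV error, the
0.632+ bootstrap error estimator, and paired significance tests.

The 0.632+ estimator blends the optimistic resubstitution error ``err`` with
the pessimistic leave-one-out bootstrap error ``err_B``:

    err_632+ = (1 - w) * err + w * err_B,      w = 0.632 / (1 - 0.368 * R)

where the relative overfitting rate ``R = (err_B - err) / (Gamma - err)`` is
clipped to [0, 1] and ``Gamma`` is the no-information error rate obtained by
scoring the fitted model over all (target_i, predictor_j) pairs.  The 0.632
constant is the expected fraction of distinct instances in a bootstrap
resample (1 - 1/e); ``w`` runs from 0.632 (no overfitting) to 1 (maximal
overfitting).  Loss is 0-1 throughout, matching the label-based metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec, make_classifier
from .data import Dataset

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ErrorEstimate",
    "metric_set",
    "kfold_error",
    "bootstrap_632plus",
    "blend_weight",
    "mean_distinct_fraction",
    "paired_tests",
]


@dataclass
class ConfusionCounts:
    """A k x k contingency matrix (rows = true class, columns = predicted)."""

    matrix: np.ndarray
    classes: Optional[list] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contingency matrix must be square")
        if np.any(self.matrix < 0):
            raise ValueError("counts must be non-negative")
        if self.matrix.sum() == 0:
            raise ValueError("at least one instance required")
        if self.classes is None:
            self.classes = list(range(self.matrix.shape[0]))

    @classmethod
    def binary(cls, tp: int, tn: int, fp: int, fn: int) -> "ConfusionCounts":
        """Binary counts with class order (negative, positive)."""
        return cls(np.array([[tn, fp], [fn, tp]]), classes=[0, 1])

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if classes is None:
            classes = np.unique(np.concatenate([y_true, y_pred])).tolist()
        index = {c: i for i, c in enumerate(classes)}
        mat = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            mat[index[t], index[p]] += 1
        return cls(mat, classes=list(classes))

    @property
    def n(self) -> int:
        return int(self.matrix.sum())


@dataclass
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    auc_roc: float = float("nan")
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "specificity": self.specificity,
            "auc_roc": self.auc_roc,
            "flags": list(self.flags),
        }


def _safe_ratio(num: float, den: float, name: str, flags: list) -> float:
    if den == 0:
        flags.append(f"{name}_undefined")
        return 0.0
    return num / den


def metric_set(
    counts: ConfusionCounts,
    scores: Optional[np.ndarray] = None,
    y_true: Optional[np.ndarray] = None,
) -> MetricSet:
    """Accuracy, precision, recall, F1, specificity (and AUC when scores are
    given) from a contingency matrix.

    Binary matrices use the positive class (index 1) as reference; multiclass
    matrices macro-average the one-vs-rest values.  A ratio with a zero
    denominator is reported as 0 and flagged, never silently dropped.  AUC
    needs per-instance class scores: ``scores`` has one column per class (in
    ``counts.classes`` order) and ``y_true`` the matching true labels;
    multiclass AUC is macro one-vs-rest.
    """
    mat = counts.matrix
    k = mat.shape[0]
    n = counts.n
    flags: list = []
    accuracy = float(np.trace(mat)) / n

    precisions, recalls, specificities, f1s = [], [], [], []
    cls_range = range(k) if k > 2 else [1]
    for c in cls_range:
        tp = mat[c, c]
        fp = mat[:, c].sum() - tp
        fn = mat[c, :].sum() - tp
        tn = n - tp - fp - fn
        prec = _safe_ratio(tp, tp + fp, "precision", flags)
        rec = _safe_ratio(tp, tp + fn, "recall", flags)
        spec = _safe_ratio(tn, tn + fp, "specificity", flags)
        f1 = _safe_ratio(2.0 * prec * rec, prec + rec, "f1", flags)
        precisions.append(prec)
        recalls.append(rec)
        specificities.append(spec)
        f1s.append(f1)

    auc = float("nan")
    if scores is not None and y_true is not None:
        scores = np.asarray(scores, dtype=float)
        y_idx = np.array([counts.classes.index(y) for y in np.asarray(y_true)])
        try:
            if k == 2:
                auc = float(roc_auc_score(y_idx, scores[:, 1]))
            else:
                auc = float(roc_auc_score(y_idx, scores, multi_class="ovr",
                                          average="macro", labels=list(range(k))))
        except ValueError:
            flags.append("auc_undefined")

    return MetricSet(
        accuracy=accuracy,
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
        specificity=float(np.mean(specificities)),
        auc_roc=auc,
        flags=flags,
    )


def kfold_error(
    dataset: Dataset,
    mask: Optional[np.ndarray],
    spec: ClassifierSpec,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Mean held-out 0-1 loss over ``k`` seeded stratified folds."""
    X = dataset.expression if mask is None else dataset.subset_genes(mask)
    y = dataset.labels
    _, counts = np.unique(y, return_counts=True)
    k_eff = min(k, int(counts.min()))
    if k_eff < k:
        warnings.warn(f"smallest class has {counts.min()} members; using k={k_eff}",
                      stacklevel=2)
    if k_eff < 2:
        raise ValueError("each class needs at least 2 members")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    losses = np.empty(len(y))
    for train_idx, test_idx in skf.split(X, y):
        model = make_classifier(spec)
        model.fit(X[train_idx], y[train_idx])
        losses[test_idx] = model.predict(X[test_idx]) != y[test_idx]
    return float(losses.mean())


@dataclass
class ErrorEstimate:
    """Resubstitution, leave-one-out bootstrap, and 0.632+ blended error."""

    err_resub: float
    err_loo_boot: float
    err_632plus: float
    w_blend: float
    R_overfit: float
    gamma_noinfo: float
    B: int
    n_never_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "err_resub": self.err_resub,
            "err_loo_boot": self.err_loo_boot,
            "err_632plus": self.err_632plus,
            "w_blend": self.w_blend,
            "R_overfit": self.R_overfit,
            "gamma_noinfo": self.gamma_noinfo,
            "B": self.B,
            "n_never_excluded": self.n_never_excluded,
        }


def blend_weight(R: float) -> float:
    """The 0.632+ blending weight ``w = 0.632 / (1 - 0.368 * R)``, R in [0, 1]."""
    R = min(max(R, 0.0), 1.0)
    return 0.632 / (1.0 - 0.368 * R)


def bootstrap_632plus(
    dataset: Dataset,
    mask: Optional[np.ndarray],
    spec: ClassifierSpec,
    B: int = 50,
    seed: int = 0,
) -> ErrorEstimate:
    """The 0.632+ bootstrap estimate of the prediction error under 0-1 loss.

    Draws ``B`` bootstrap resamples with replacement; the leave-one-out
    bootstrap error averages, per instance, the losses of the models whose
    resample excluded it.  An instance contained in every resample is left
    out of that average (counted in ``n_never_excluded``).  The
    no-information rate Gamma scores the full-data model over all
    (target, prediction) pairs.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if dataset.n_instances < 10:
        raise ValueError("need at least 10 instances")
    rng = np.random.default_rng(seed)
    X = dataset.expression if mask is None else dataset.subset_genes(mask)
    y = dataset.labels
    n = len(y)

    # resubstitution error and no-information rate from the full-data fit
    full = make_classifier(spec)
    full.fit(X, y)
    pred_full = full.predict(X)
    err_resub = float(np.mean(pred_full != y))
    gamma = float(np.mean(y[:, None] != pred_full[None, :]))

    loss_sum = np.zeros(n)
    loss_cnt = np.zeros(n, dtype=int)
    for _ in range(B):
        idx = rng.integers(n, size=n)
        out = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if out.size == 0:
            continue
        if len(np.unique(y[idx])) < 2:
            continue  # degenerate resample; cannot fit a classifier
        model = make_classifier(spec)
        model.fit(X[idx], y[idx])
        pred = model.predict(X[out])
        miss = (pred != y[out]).astype(float)
        loss_sum[out] += miss
        loss_cnt[out] += 1

    covered = loss_cnt > 0
    n_never = int(n - covered.sum())
    if n_never:
        warnings.warn(f"{n_never} instances appeared in every bootstrap resample; "
                      "excluded from the leave-one-out average", stacklevel=2)
    if not covered.any():
        raise RuntimeError("no instance was ever out-of-bag; increase B")
    err_boot = float(np.mean(loss_sum[covered] / loss_cnt[covered]))

    if gamma == err_resub:
        R = 0.0
    else:
        R = (err_boot - err_resub) / (gamma - err_resub)
    R = min(max(R, 0.0), 1.0)
    w = blend_weight(R)
    err_632plus = (1.0 - w) * err_resub + w * err_boot
    return ErrorEstimate(
        err_resub=err_resub,
        err_loo_boot=err_boot,
        err_632plus=err_632plus,
        w_blend=w,
        R_overfit=R,
        gamma_noinfo=gamma,
        B=B,
        n_never_excluded=n_never,
    )


def mean_distinct_fraction(n: int, n_resamples: int, rng: np.random.Generator) -> float:
    """Monte-Carlo estimate of the mean fraction of distinct instances in a
    bootstrap resample of size ``n`` (converges to 1 - 1/e ~ 0.632)."""
    fracs = np.empty(n_resamples)
    for b in range(n_resamples):
        fracs[b] = len(np.unique(rng.integers(n, size=n))) / n
    return float(fracs.mean())


def paired_tests(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Paired t-test, Wilcoxon signed-rank, Cohen's d and 95% CI for two
    paired run vectors.

    Cohen's d is computed on the paired differences (mean / SD with ddof=1).
    Degenerate cases are flagged: all differences zero (Wilcoxon reported as
    p=1), or zero-variance nonzero differences (d and t undefined).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    n = d.size
    flags: list = []
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))

    if sd_d == 0.0:
        if mean_d == 0.0:
            flags.append("all_differences_zero")
            t_p, wil_p, cohens = 1.0, 1.0, 0.0
            ci = (0.0, 0.0)
        else:
            flags.append("zero_variance_differences")
            t_p = 0.0
            cohens = float("nan")
            wil_p = float(stats.wilcoxon(d, method="exact").pvalue) if n <= 25 else \
                float(stats.wilcoxon(d, method="approx").pvalue)
            ci = (mean_d, mean_d)
    else:
        t_res = stats.ttest_rel(a, b)
        t_p = float(t_res.pvalue)
        cohens = mean_d / sd_d
        if np.all(d == 0.0):  # pragma: no cover - handled above
            wil_p = 1.0
        else:
            method = "exact" if n <= 25 else "approx"
            try:
                wil_p = float(stats.wilcoxon(d, method=method).pvalue)
            except ValueError:
                flags.append("wilcoxon_undefined")
                wil_p = 1.0
        half = stats.t.ppf(0.975, n - 1) * sd_d / np.sqrt(n)
        ci = (mean_d - half, mean_d + half)

    return {
        "t_p": t_p,
        "wilcoxon_p": wil_p,
        "cohens_d": cohens,
        "ci95": (float(ci[0]), float(ci[1])),
        "mean_difference": mean_d,
        "n": n,
        "flags": flags,
    }
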