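"""Wrapper gene selection: continuous EPO positions mapped to gene subsets.

The optimizer works in a continuous box; a sigmoid transfer function turns
each position into a boolean gene mask, and the mask is scored by the
composite fitness

    f(s) = alpha * A  +  (1 - alpha) * (1 - Ns/Nt)  -  W * P(s)

where ``A`` is the stratified k-fold cross-validation accuracy of the wrapped
classifier on the selected genes, ``Ns/Nt`` the selected fraction, and
``P(s)`` a redundancy penalty (mean absolute pairwise correlation among the
selected genes).  ``alpha`` close to 1 makes accuracy dominate; the sparsity
reward and redundancy penalty break ties toward compact, non-duplicated
subsets.

An adaptive bit-flip mutation (rate decaying linearly over the run, the same
schedule shape as the optimizer's exploration factor) perturbs every
candidate's mask once per iteration, giving the wrapper a hill-climbing
local-search component in mask space.

For small problems :func:`exhaustive_oracle` enumerates every non-empty
subset and returns the global fitness maximizer; it exists so the stochastic
search can be validated against a known optimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec, make_classifier
from .data import Dataset
from .epo import EpoConfig, run_epo

__all__ = [
    "FitnessConfig",
    "SelectionResult",
    "binarize",
    "redundancy_penalty",
    "composite_fitness",
    "fitness",
    "mutate",
    "select_genes",
    "exhaustive_oracle",
    "POSITION_BOUND",
]

# half-width of the continuous search box; sigmoid(+/-4) ~ 0.982 / 0.018, so
# the box covers confidently-selected through confidently-dropped genes
POSITION_BOUND = 4.0


@dataclass
class FitnessConfig:
    """Weights and estimation settings of the composite fitness."""

    alpha_weight: float = 0.9
    redundancy_weight: float = 0.1
    transfer_threshold: float = 0.5
    inner_cv_folds: int = 5
    cv_seed: int = 0
    correlation: str = "pearson"  # or "spearman"
    mutation_rate_max: float = 0.1
    mutation_rate_min: float = 0.01
    mutation_mode: str = "balanced"  # or "symmetric"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_weight <= 1.0:
            raise ValueError("alpha_weight must lie in [0, 1]")
        if self.redundancy_weight < 0.0:
            raise ValueError("redundancy_weight must be non-negative")
        if not 0.0 < self.transfer_threshold < 1.0:
            raise ValueError("transfer_threshold must lie in (0, 1)")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError("correlation must be 'pearson' or 'spearman'")
        if not 0.0 <= self.mutation_rate_min <= self.mutation_rate_max <= 1.0:
            raise ValueError("require 0 <= mutation_rate_min <= mutation_rate_max <= 1")
        if self.mutation_mode not in ("balanced", "symmetric"):
            raise ValueError("mutation_mode must be 'balanced' or 'symmetric'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FitnessConfig":
        return cls(**d)


@dataclass
class SelectionResult:
    """Best mask found by a selection run, with provenance to replay it."""

    mask: np.ndarray
    fitness: float
    accuracy_inner: float
    n_selected: int
    history: list
    epo_config: Optional[dict] = None
    fitness_config: Optional[dict] = None
    seed: Optional[int] = None
    n_evaluations: int = 0

    def selected_genes(self, dataset: Dataset) -> list:
        return [g for g, keep in zip(dataset.gene_ids, self.mask) if keep]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mask"] = [bool(b) for b in self.mask]
        return d


def binarize(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Sigmoid transfer from a continuous position to a gene mask.

    Gene j is selected iff ``sigmoid(position_j) > threshold`` (strict, so a
    position of exactly 0 at the default threshold is NOT selected).  An
    all-false mask is repaired by selecting the single gene with the largest
    position value.
    """
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position must be finite")
    mask = expit(position) > threshold
    if not mask.any():
        mask = mask.copy()
        mask[int(np.argmax(position))] = True
    return mask


def redundancy_penalty(dataset: Dataset, mask: np.ndarray, method: str = "pearson") -> float:
    """Mean absolute pairwise correlation among the selected genes, in [0, 1].

    Returns 0 for a single selected gene.  A zero-variance gene contributes 0
    to every pair it appears in.
    """
    mask = np.asarray(mask, dtype=bool)
    ns = int(mask.sum())
    if ns == 0:
        raise ValueError("mask selects no genes")
    if ns == 1:
        return 0.0
    sub = dataset.subset_genes(mask)
    if method == "spearman":
        sub = np.apply_along_axis(rankdata, 0, sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance genes
    off = np.abs(corr[np.triu_indices(ns, k=1)])
    return float(off.mean())


def composite_fitness(
    accuracy: float,
    n_selected: int,
    n_total: int,
    cfg: FitnessConfig,
    penalty: float = 0.0,
) -> float:
    """The composite objective ``alpha*A + (1-alpha)*(1 - Ns/Nt) - W*P(s)``."""
    a, w = cfg.alpha_weight, cfg.redundancy_weight
    return a * accuracy + (1.0 - a) * (1.0 - n_selected / n_total) - w * penalty


def _cv_folds(dataset: Dataset, cfg: FitnessConfig) -> list:
    """Stratified fold indices, fixed once per (dataset, config) so every
    mask is scored on identical splits."""
    _, counts = np.unique(dataset.labels, return_counts=True)
    k = min(cfg.inner_cv_folds, int(counts.min()))
    if k < cfg.inner_cv_folds:
        import warnings

        warnings.warn(
            f"smallest class has {counts.min()} members; "
            f"reducing inner CV folds from {cfg.inner_cv_folds} to {k}",
            stacklevel=2,
        )
    if k < 2:
        raise ValueError("each class needs at least 2 members for inner CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.cv_seed)
    return list(skf.split(dataset.expression, dataset.labels))


def _cv_accuracy(dataset: Dataset, mask: np.ndarray, spec: ClassifierSpec,
                 folds: list) -> float:
    sub = dataset.subset_genes(mask)
    y = dataset.labels
    accs = []
    for train_idx, test_idx in folds:
        model = make_classifier(spec)
        model.fit(sub[train_idx], y[train_idx])
        accs.append(float(np.mean(model.predict(sub[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def fitness(
    dataset: Dataset,
    mask: np.ndarray,
    classifier: ClassifierSpec,
    cfg: FitnessConfig,
    folds: Optional[list] = None,
) -> float:
    """Score one gene mask: inner-CV accuracy combined with sparsity and
    redundancy terms.  ``folds`` may be precomputed (and shared across masks)
    for speed and strict comparability; otherwise they are built
    deterministically from ``cfg.cv_seed``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no genes")
    if folds is None:
        folds = _cv_folds(dataset, cfg)
    acc = _cv_accuracy(dataset, mask, classifier, folds)
    pen = 0.0
    if cfg.redundancy_weight > 0.0:
        pen = redundancy_penalty(dataset, mask, cfg.correlation)
    return composite_fitness(acc, int(mask.sum()), dataset.n_genes, cfg, pen)


def mutate(
    mask: np.ndarray,
    t: int,
    n_iter: int,
    cfg: FitnessConfig,
    rng: np.random.Generator,
    rate: Optional[float] = None,
) -> np.ndarray:
    """Adaptive bit-flip mutation with a linearly decaying rate
    ``rate_max - (rate_max - rate_min) * t / n_iter``.

    In ``symmetric`` mode every bit flips independently with that rate.  A
    symmetric flip drifts the expected subset size toward half the genes
    (expected net change ``rate * (Nt - 2*Ns)``), which on sparse problems
    overwhelms the fitness's sparsity term.  The default ``balanced`` mode
    mixes two size-aware kernels, chosen with a fair coin per call:

    * a size-unbiased exchange flip — selected genes drop with probability
      ``rate``, unselected genes are added with probability
      ``rate * Ns / (Nt - Ns)`` (capped at 1), so expected additions equal
      expected removals and subset size moves by selection pressure alone;
    * a pure-drop move — selected genes drop with probability ``rate`` and
      nothing is added, a backward-elimination step that a greedy acceptor
      keeps whenever the dropped genes were uninformative.

    An emptied mask is repaired by re-selecting one gene uniformly at random.
    """
    mask = np.asarray(mask, dtype=bool)
    if rate is None:
        hi, lo = cfg.mutation_rate_max, cfg.mutation_rate_min
        rate = hi - (hi - lo) * t / max(n_iter, 1)
    if cfg.mutation_mode == "symmetric":
        flips = rng.uniform(size=mask.shape) < rate
    elif rng.uniform() < 0.5:
        # pure-drop kernel
        flips = mask & (rng.uniform(size=mask.shape) < rate)
    else:
        # size-unbiased exchange kernel
        ns = int(mask.sum())
        nt = mask.size
        p_add = min(1.0, rate * ns / (nt - ns)) if nt > ns else 0.0
        draws = rng.uniform(size=mask.shape)
        flips = np.where(mask, draws < rate, draws < p_add)
    out = mask ^ flips
    if not out.any():
        out[int(rng.integers(out.size))] = True
    return out


def _mask_to_position(mask: np.ndarray, position: np.ndarray) -> np.ndarray:
    """Rewrite ``position`` so it binarizes to ``mask`` (threshold 0.5),
    preserving each coordinate's magnitude as its confidence."""
    mag = np.abs(position)
    mag[mag == 0.0] = 1e-6
    return np.where(mask, mag, -mag)


def select_genes(
    dataset: Dataset,
    classifier: ClassifierSpec,
    epo_cfg: EpoConfig,
    fit_cfg: Optional[FitnessConfig] = None,
) -> SelectionResult:
    """Run the full EPO wrapper selection on ``dataset``.

    The continuous optimizer maximizes ``fitness(binarize(position))``;
    every candidate additionally undergoes mask-space mutation each
    iteration (kept only on improvement).  Fitness values are cached by mask, so the
    reported evaluation count is the number of distinct masks scored.
    Deterministic under ``epo_cfg.seed``.
    """
    if fit_cfg is None:
        fit_cfg = FitnessConfig()
    folds = _cv_folds(dataset, fit_cfg)
    cache: dict = {}
    n_calls = 0

    def objective(position: np.ndarray) -> float:
        nonlocal n_calls
        mask = binarize(position, fit_cfg.transfer_threshold)
        key = np.packbits(mask).tobytes()
        if key not in cache:
            n_calls += 1
            cache[key] = fitness(dataset, mask, classifier, fit_cfg, folds)
        return cache[key]

    def mutator(position: np.ndarray, t: int, rng: np.random.Generator) -> np.ndarray:
        mask = binarize(position, fit_cfg.transfer_threshold)
        mutated = mutate(mask, t, epo_cfg.n_iter, fit_cfg, rng)
        return _mask_to_position(mutated, position)

    bounds = (-POSITION_BOUND, POSITION_BOUND)
    state = run_epo(objective, epo_cfg, bounds, dataset.n_genes, mutator=mutator)

    best_mask = binarize(state.best_position, fit_cfg.transfer_threshold)
    acc = _cv_accuracy(dataset, best_mask, classifier, folds)
    return SelectionResult(
        mask=best_mask,
        fitness=state.best_fitness,
        accuracy_inner=acc,
        n_selected=int(best_mask.sum()),
        history=list(state.history),
        epo_config=epo_cfg.to_dict(),
        fitness_config=fit_cfg.to_dict(),
        seed=epo_cfg.seed,
        n_evaluations=n_calls,
    )


def exhaustive_oracle(
    dataset: Dataset,
    classifier: ClassifierSpec,
    fit_cfg: Optional[FitnessConfig] = None,
) -> SelectionResult:
    """Evaluate the fitness of every non-empty gene subset (n_genes <= 20).

    Returns the global maximizer; ties resolve to the lexicographically
    smallest mask (masks compared as tuples of booleans).
    """
    if fit_cfg is None:
        fit_cfg = FitnessConfig()
    g = dataset.n_genes
    if g > 20:
        raise ValueError(f"exhaustive enumeration refused for {g} > 20 genes")
    folds = _cv_folds(dataset, fit_cfg)
    best_mask = None
    best_fit = -np.inf
    n_eval = 0
    for bits in itertools.product((False, True), repeat=g):
        mask = np.array(bits, dtype=bool)
        if not mask.any():
            continue
        f = fitness(dataset, mask, classifier, fit_cfg, folds)
        n_eval += 1
        if f > best_fit:
            best_fit = f
            best_mask = mask
    acc = _cv_accuracy(dataset, best_mask, classifier, folds)
    return SelectionResult(
        mask=best_mask,
        fitness=float(best_fit),
        accuracy_inner=acc,
        n_selected=int(best_mask.sum()),
        history=[float(best_fit)],
        fitness_config=fit_cfg.to_dict(),
        n_evaluations=n_eval,
    )


def random_search(
    dataset: Dataset,
    classifier: ClassifierSpec,
    n_evaluations: int,
    fit_cfg: Optional[FitnessConfig] = None,
    seed: int = 0,
) -> SelectionResult:
    """Budget-matched baseline: score uniformly random gene subsets.

    Each candidate mask selects every gene independently with probability
    1/2 (repaired if empty); the best of ``n_evaluations`` masks is
    returned.  Used as the fair comparison partner for :func:`select_genes`
    under an equal fitness-call budget.
    """
    if fit_cfg is None:
        fit_cfg = FitnessConfig()
    rng = np.random.default_rng(seed)
    folds = _cv_folds(dataset, fit_cfg)
    best_mask = None
    best_fit = -np.inf
    history = []
    for _ in range(n_evaluations):
        mask = rng.uniform(size=dataset.n_genes) < 0.5
        if not mask.any():
            mask[int(rng.integers(mask.size))] = True
        f = fitness(dataset, mask, classifier, fit_cfg, folds)
        if f > best_fit:
            best_fit = f
            best_mask = mask
        history.append(best_fit)
    acc = _cv_accuracy(dataset, best_mask, classifier, folds)
    return SelectionResult(
        mask=best_mask,
        fitness=float(best_fit),
        accuracy_inner=acc,
        n_selected=int(best_mask.sum()),
        history=history,
        fitness_config=fit_cfg.to_dict(),
        seed=seed,
        n_evaluations=n_evaluations,
    )
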