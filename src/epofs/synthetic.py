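"""Synthetic microarray-like datasets with planted structure.

Real microarray studies give no ground truth about which genes matter, so
every recovery experiment in this package runs on generated data whose
informative genes are known.  The generator plants three kinds of genes on a
standard-normal log-intensity scale:

* informative genes — class-conditionally normal with class means spaced
  ``effect_size`` standard deviations apart,
* redundant genes — noisy copies of randomly chosen informative genes with a
  prescribed overall Pearson correlation ``redundancy_rho``,
* noise genes — standard normal, independent of the class label.

Shape presets mirror the eight public cancer microarray benchmarks commonly
used for gene-selection studies (2,000-24,481 genes; 60-253 instances; 2-4
classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .data import Dataset

__all__ = ["SyntheticSpec", "generate", "table1_presets", "PRESET_SHAPES", "Dataset"]

# (n_genes, n_instances, n_classes) of the eight benchmark datasets
PRESET_SHAPES = {
    "colon": (2000, 60, 2),
    "cns": (7129, 60, 2),
    "breast": (24481, 97, 2),
    "lung": (12533, 181, 2),
    "ovarian": (15154, 253, 2),
    "lymphoma": (4026, 62, 3),
    "mll": (12582, 72, 3),
    "srbct": (2308, 83, 4),
}


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    ``effect_size`` is the spacing of adjacent class means in units of
    ``noise_sd``; 2.0 gives well-separated but overlapping classes, the
    regime where feature selection visibly pays off.  ``redundancy_rho`` is
    the target overall correlation between a redundant gene and its parent.
    """

    n_instances: int = 100
    n_genes: int = 500
    n_classes: int = 2
    n_informative: int = 10
    n_redundant: int = 20
    effect_size: float = 2.0
    redundancy_rho: float = 0.9
    noise_sd: float = 1.0
    class_proportions: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_classes <= 4:
            raise ValueError("n_classes must be between 2 and 4")
        if self.n_informative < 0 or self.n_redundant < 0:
            raise ValueError("planted gene counts must be non-negative")
        if self.n_informative + self.n_redundant > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant genes require at least one informative parent")
        if not 0.0 <= self.redundancy_rho < 1.0:
            raise ValueError("redundancy_rho must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.class_proportions is None:
            self.class_proportions = [1.0 / self.n_classes] * self.n_classes
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (self.n_classes,) or np.any(props <= 0):
            raise ValueError("class_proportions must be positive, one per class")
        if abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("class_proportions must sum to 1")
        self.class_proportions = props.tolist()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**d)


def _class_mean_matrix(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-(class, informative gene) means, spaced ``effect_size*noise_sd`` apart.

    Each gene gets a random permutation of the centred ladder of class means
    so different genes discriminate different class orderings.
    """
    k = spec.n_classes
    ladder = (np.arange(k) - (k - 1) / 2.0) * spec.effect_size * spec.noise_sd
    means = np.empty((k, spec.n_informative))
    for g in range(spec.n_informative):
        means[:, g] = rng.permutation(ladder)
    return means


def generate(spec: SyntheticSpec) -> Dataset:
    """Draw one dataset from the planted-structure model, deterministically."""
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_instances, spec.n_genes
    k = spec.n_classes
    props = np.asarray(spec.class_proportions)

    # fixed label counts (largest-remainder rounding), then shuffled
    counts = np.floor(props * n).astype(int)
    remainder = props * n - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    y = np.repeat(np.arange(k), counts)
    rng.shuffle(y)

    expr = np.empty((n, g))
    n_inf, n_red = spec.n_informative, spec.n_redundant

    if n_inf:
        means = _class_mean_matrix(spec, rng)  # (k, n_inf)
        expr[:, :n_inf] = means[y] + spec.noise_sd * rng.standard_normal((n, n_inf))

    if n_red:
        parents = rng.integers(n_inf, size=n_red)
        rho = spec.redundancy_rho
        # total (between + within class) variance of an informative gene
        means_used = means[:, parents]  # (k, n_red)
        mu_bar = props @ means_used
        var_between = props @ (means_used - mu_bar) ** 2
        sigma_x = np.sqrt(var_between + spec.noise_sd**2)
        noise = rng.standard_normal((n, n_red))
        # scale the independent noise so the overall correlation with the
        # parent equals rho regardless of the class structure
        expr[:, n_inf:n_inf + n_red] = (
            rho * expr[:, parents] + sigma_x * np.sqrt(1.0 - rho**2) * noise
        )

    n_noise = g - n_inf - n_red
    if n_noise:
        expr[:, n_inf + n_red:] = rng.standard_normal((n, n_noise))

    # plant positions are shuffled so selection cannot exploit column order
    perm = rng.permutation(g)
    expr = expr[:, perm]
    truth = perm < n_inf + n_red

    width = max(4, len(str(g)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(g)]
    labels = np.array([f"class_{c}" for c in y])
    return Dataset(expression=expr, labels=labels, gene_ids=gene_ids, truth_mask=truth)


def table1_presets(**overrides) -> dict:
    """Specs matching the shapes of the eight benchmark microarray datasets.

    Returns a name -> :class:`SyntheticSpec` mapping; planted-signal
    parameters keep the generator defaults unless overridden.
    """
    presets = {}
    for name, (n_genes, n_instances, n_classes) in PRESET_SHAPES.items():
        kwargs = dict(
            n_instances=n_instances,
            n_genes=n_genes,
            n_classes=n_classes,
        )
        kwargs.update(overrides)
        presets[name] = SyntheticSpec(**kwargs)
    return presets
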