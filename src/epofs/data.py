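"""The in-memory expression-matrix container shared across the package."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Dataset"]


@dataclass
class Dataset:
    """An instances x genes expression matrix with class labels.

    Attributes
    ----------
    expression : ndarray, shape (n_instances, n_genes)
        Real-valued expression levels; no missing values allowed.
    labels : ndarray, shape (n_instances,)
        Class label per instance (strings).
    gene_ids : list of str
        One identifier per gene column.
    truth_mask : ndarray of bool, optional
        For synthetic data: which genes carry planted class signal.
    """

    expression: np.ndarray
    labels: np.ndarray
    gene_ids: list
    truth_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.expression.ndim != 2:
            raise ValueError("expression must be a 2-D matrix")
        n, g = self.expression.shape
        if self.labels.shape != (n,):
            raise ValueError("labels length must match the number of instances")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length must match the number of genes")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression contains missing or non-finite values")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("dataset must contain at least two classes")
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask, dtype=bool)
            if self.truth_mask.shape != (g,):
                raise ValueError("truth_mask length must match the number of genes")

    @property
    def n_instances(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset_genes(self, mask: np.ndarray) -> np.ndarray:
        """Expression restricted to the genes where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return self.expression[:, mask]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.expression, columns=self.gene_ids)
        df["class"] = self.labels
        return df
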