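"""Reading and writing expression datasets and run configurations.

ARFF support is dense-only: attributes are real-valued gene columns plus one
nominal class attribute (by default the last nominal attribute in the file).
Reading goes through :func:`scipy.io.arff.loadarff`; writing is a small
serializer that emits the same dialect.  CSV/TSV files carry one row per
instance with a header of gene identifiers and a designated label column.
Missing values are rejected outright, with their locations named.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.io import arff as scipy_arff

from .classifiers import ClassifierSpec
from .data import Dataset
from .epo import EpoConfig
from .selection import FitnessConfig
from .synthetic import SyntheticSpec

__all__ = [
    "read_dataset",
    "read_arff",
    "read_csv",
    "write_arff",
    "write_csv",
    "RunConfig",
]


def _float_repr(x: float) -> str:
    return repr(float(x))


def write_arff(dataset: Dataset, path, relation: str = "expression") -> None:
    """Write a dense ARFF file: real gene attributes, nominal class last."""
    classes = [str(c) for c in dataset.classes]
    lines = [f"@relation {relation}", ""]
    for g in dataset.gene_ids:
        lines.append(f"@attribute {g} real")
    lines.append("@attribute class {" + ",".join(classes) + "}")
    lines.append("")
    lines.append("@data")
    for row, label in zip(dataset.expression, dataset.labels):
        lines.append(",".join(_float_repr(v) for v in row) + "," + str(label))
    Path(path).write_text("\n".join(lines) + "\n")


def write_csv(dataset: Dataset, path, label_column: str = "class") -> None:
    df = pd.DataFrame(dataset.expression, columns=dataset.gene_ids)
    df[label_column] = dataset.labels
    df.to_csv(path, index=False)


def _reject_missing(values: np.ndarray, gene_ids, kind: str) -> None:
    bad = ~np.isfinite(values)
    if bad.any():
        rows, cols = np.nonzero(bad)
        locs = ", ".join(
            f"(row {r + 1}, {gene_ids[c]})" for r, c in list(zip(rows, cols))[:10]
        )
        raise ValueError(
            f"{kind} file contains {bad.sum()} missing/non-numeric values: {locs}"
        )


def read_arff(path, class_attribute: Optional[str] = None) -> Dataset:
    """Load a dense ARFF expression file.

    The class is the attribute named ``class_attribute`` when given,
    otherwise the last nominal attribute.  All remaining attributes must be
    numeric gene columns.  Sparse ARFF is not supported.
    """
    text = Path(path).read_text()
    if any(line.lstrip().startswith("{") for line in text.splitlines()
           if not line.lstrip().startswith(("%", "@")) and line.strip()):
        raise ValueError("sparse ARFF files are not supported; provide dense ARFF")
    data, meta = scipy_arff.loadarff(_io.StringIO(text))
    names = list(meta.names())
    types = dict(zip(names, meta.types()))
    if class_attribute is None:
        nominal = [n for n in names if types[n] == "nominal"]
        if not nominal:
            raise ValueError("no nominal class attribute found")
        class_attribute = nominal[-1]
    elif class_attribute not in names:
        raise ValueError(f"class attribute {class_attribute!r} not in file")
    gene_ids = [n for n in names if n != class_attribute]
    non_numeric = [g for g in gene_ids if types[g] not in ("numeric", "real", "integer")]
    if non_numeric:
        raise ValueError(f"non-numeric gene columns: {non_numeric[:10]}")
    expr = np.column_stack([np.asarray(data[g], dtype=float) for g in gene_ids]) \
        if gene_ids else np.empty((len(data), 0))
    _reject_missing(expr, gene_ids, "ARFF")
    labels = np.array([v.decode() if isinstance(v, bytes) else str(v)
                       for v in data[class_attribute]])
    if "?" in labels:
        raise ValueError("ARFF file contains missing class labels")
    return Dataset(expression=expr, labels=labels, gene_ids=gene_ids)


def read_csv(path, label_column: Optional[str] = None, sep: str = ",") -> Dataset:
    """Load a delimited expression table (header row, one row per instance)."""
    df = pd.read_csv(path, sep=sep)
    if label_column is None:
        label_column = "class" if "class" in df.columns else df.columns[-1]
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not in file")
    labels = df[label_column].astype(str).to_numpy()
    feats = df.drop(columns=[label_column])
    gene_ids = [str(c) for c in feats.columns]
    try:
        expr = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric gene columns in CSV: {exc}") from exc
    _reject_missing(expr, gene_ids, "CSV")
    return Dataset(expression=expr, labels=labels, gene_ids=gene_ids)


def read_dataset(path, format: Optional[str] = None,
                 class_attribute: Optional[str] = None) -> Dataset:
    """Dispatch on ``format`` ('arff', 'csv', 'tsv') or the file suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "arff":
        return read_arff(path, class_attribute)
    if format in ("csv", "txt"):
        return read_csv(path, class_attribute)
    if format == "tsv":
        return read_csv(path, class_attribute, sep="\t")
    raise ValueError(f"unsupported dataset format {format!r}")


@dataclass
class RunConfig:
    """Everything needed to reproduce a selection/evaluation run."""

    dataset: Optional[str] = None  # path, or "synthetic:<preset>"
    classifiers: list = field(default_factory=lambda: [ClassifierSpec("knn")])
    epo: EpoConfig = field(default_factory=EpoConfig)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    synthetic: Optional[SyntheticSpec] = None
    bootstrap_B: int = 50
    cv_folds: int = 5
    estimator: str = "632plus"  # or "kfold"
    n_repeats: int = 20
    output_dir: str = "results"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "classifiers": [c.to_dict() for c in self.classifiers],
            "epo": self.epo.to_dict(),
            "fitness": self.fitness.to_dict(),
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "bootstrap_B": self.bootstrap_B,
            "cv_folds": self.cv_folds,
            "estimator": self.estimator,
            "n_repeats": self.n_repeats,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            dataset=d.get("dataset"),
            classifiers=[ClassifierSpec.from_dict(c) for c in d.get("classifiers", [])]
            or [ClassifierSpec("knn")],
            epo=EpoConfig.from_dict(d.get("epo", {})),
            fitness=FitnessConfig.from_dict(d.get("fitness", {})),
            synthetic=SyntheticSpec.from_dict(d["synthetic"]) if d.get("synthetic") else None,
            bootstrap_B=int(d.get("bootstrap_B", 50)),
            cv_folds=int(d.get("cv_folds", 5)),
            estimator=d.get("estimator", "632plus"),
            n_repeats=int(d.get("n_repeats", 20)),
            output_dir=d.get("output_dir", "results"),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
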