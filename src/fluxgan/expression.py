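"""Expression matrix container (genes x samples, FPKM-like) with labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEALTHY = "healthy"
CANCER = "cancer"
REAL = "real"
SYNTHETIC = "synthetic"


class ExpressionValidationError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Non-negative genes x samples matrix with per-sample label and origin.

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns; ``labels`` maps sample -> {healthy, cancer}; ``origin`` maps
    sample -> {real, synthetic}.
    """

    values: pd.DataFrame
    labels: dict[str, str]
    origin: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.origin:
            self.origin = {s: REAL for s in self.values.columns}
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample(self, sample_id: str) -> dict[str, float]:
        """Gene -> level mapping for one sample."""
        return self.values[sample_id].to_dict()

    def restrict_to_label(self, label: str) -> "ExpressionMatrix":
        keep = [s for s in self.sample_ids if self.labels[s] == label]
        return ExpressionMatrix(
            values=self.values[keep].copy(),
            labels={s: self.labels[s] for s in keep},
            origin={s: self.origin[s] for s in keep},
        )

    def concat(self, other: "ExpressionMatrix") -> "ExpressionMatrix":
        if list(other.values.index) != self.gene_ids:
            raise ExpressionValidationError("gene order mismatch in concat")
        overlap = set(self.sample_ids) & set(other.sample_ids)
        if overlap:
            raise ExpressionValidationError(f"duplicate sample ids in concat: {sorted(overlap)}")
        return ExpressionMatrix(
            values=pd.concat([self.values, other.values], axis=1),
            labels={**self.labels, **other.labels},
            origin={**self.origin, **other.origin},
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        idx = list(self.values.index)
        if len(set(idx)) != len(idx):
            dup = sorted({g for g in idx if idx.count(g) > 1})
            raise ExpressionValidationError(f"duplicate gene ids: {dup}")
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            dup = sorted({s for s in cols if cols.count(s) > 1})
            raise ExpressionValidationError(f"duplicate sample ids: {dup}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            gi, si = np.argwhere(np.isnan(arr))[0]
            raise ExpressionValidationError(
                f"NaN expression value at gene {idx[gi]!r}, sample {cols[si]!r}"
            )
        if (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ExpressionValidationError(
                f"negative expression value {arr[gi, si]} at gene {idx[gi]!r}, "
                f"sample {cols[si]!r}"
            )
        for s in cols:
            if s not in self.labels:
                raise ExpressionValidationError(f"sample {s!r} has no label")
            if self.labels[s] not in (HEALTHY, CANCER):
                raise ExpressionValidationError(
                    f"sample {s!r} has unknown label {self.labels[s]!r}"
                )
            if self.origin.get(s) not in (REAL, SYNTHETIC):
                raise ExpressionValidationError(
                    f"sample {s!r} has unknown origin {self.origin.get(s)!r}"
                )


def read_expression_matrix(path, labels_path, sep: str | None = None) -> ExpressionMatrix:
    """Read expression TSV/CSV (gene ids in first column, sample header) plus
    a two-column labels TSV (sample_id, label)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    values = pd.read_csv(path, sep=sep, index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns = values.columns.astype(str)
    lab = pd.read_csv(labels_path, sep="\t", header=None, names=["sample_id", "label"])
    labels = dict(zip(lab["sample_id"].astype(str), lab["label"].astype(str)))
    missing = [s for s in values.columns if s not in labels]
    if missing:
        raise ExpressionValidationError(f"samples missing from label file: {missing}")
    return ExpressionMatrix(values=values.astype(float), labels={s: labels[s] for s in values.columns})


def write_expression_matrix(m: ExpressionMatrix, path, labels_path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")
    with open(labels_path, "w") as fh:
        for s in m.sample_ids:
            fh.write(f"{s}\t{m.labels[s]}\n")


def filter_zero_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes whose value is exactly zero in every sample (idempotent)."""
    keep = m.values.index[(m.values != 0).any(axis=1)]
    return ExpressionMatrix(
        values=m.values.loc[keep].copy(),
        labels=dict(m.labels),
        origin=dict(m.origin),
    )
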