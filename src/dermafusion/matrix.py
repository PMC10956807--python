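"""Feature-matrix container and tab-delimited serialization.

A :class:`FeatureMatrix` is the currency passed between feature
extraction, dimensionality reduction, fusion and classification: an
``n x p`` float array whose rows stay aligned with a list of image
identifiers.  Misaligned rows silently corrupt labels downstream, so
alignment is part of the type, not a convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "read_matrix", "write_matrix"]


@dataclass
class FeatureMatrix:
    """``n x p`` feature table with row <-> image alignment.

    Parameters
    ----------
    values
        Array of shape ``(n, p)``; coerced to float64.
    row_ids
        ``n`` image identifiers, one per row, in row order.
    """

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if not self.row_ids:
            self.row_ids = [str(i) for i in range(self.values.shape[0])]
        self.row_ids = [str(r) for r in self.row_ids]
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.row_ids)} row_ids for {self.values.shape[0]} rows"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def subset(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(list(indices), dtype=int)
        return FeatureMatrix(self.values[idx], [self.row_ids[i] for i in idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return self.row_ids == other.row_ids and np.array_equal(
            self.values, other.values
        )


def write_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as tab-delimited text with a header line.

    Layout: first column ``row_id``, then ``f0 .. f{p-1}``.
    """
    df = pd.DataFrame(fm.values, columns=[f"f{j}" for j in range(fm.p)])
    df.insert(0, "row_id", fm.row_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_matrix(path: str | Path) -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", dtype={"row_id": str}, float_precision="round_trip")
    if "row_id" not in df.columns:
        raise ValueError(f"{path}: missing 'row_id' column")
    ids = df["row_id"].tolist()
    values = df.drop(columns="row_id").to_numpy(dtype=np.float64)
    return FeatureMatrix(values, ids)
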