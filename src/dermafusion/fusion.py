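"""Pairwise fusion of reduced backbone feature matrices.

Fusion is plain column-wise concatenation of two row-aligned feature
matrices: 724 + 694 = 1418, 694 + 921 = 1615 and 724 + 921 = 1645
columns for the three backbone pairs.  Row identifiers must match
exactly and in order — silently fusing misaligned matrices would
attach the wrong label to every row downstream, so a mismatch is an
error, never a reindex.
"""

from __future__ import annotations

import numpy as np

from .matrix import FeatureMatrix

__all__ = ["fuse_features"]


def fuse_features(
    F1: FeatureMatrix, F2: FeatureMatrix, standardize: bool = False
) -> FeatureMatrix:
    """Concatenate two aligned feature matrices column-wise.

    With ``standardize=True`` each column of each input is centered
    and scaled to unit variance first (off by default; the published
    procedure concatenates raw reduced features).
    """
    if F1.n != F2.n:
        raise ValueError(f"row-count mismatch: {F1.n} vs {F2.n}")
    if F1.row_ids != F2.row_ids:
        raise ValueError(
            "row_ids differ between the two matrices; refusing to fuse "
            "misaligned features"
        )

    def prep(v: np.ndarray) -> np.ndarray:
        if not standardize or v.size == 0:
            return v
        sd = v.std(axis=0)
        return (v - v.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    values = np.hstack([prep(F1.values), prep(F2.values)])
    return FeatureMatrix(values, list(F1.row_ids))
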