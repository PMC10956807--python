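"""Dataset splitting and class-balancing augmentation.

Splitting follows the published arithmetic for the ISIC 2019 lesion
archive: per class, 40% of the images are held out for testing and
10% of the remaining 60% (i.e. 6% overall) for validation, with both
counts rounded half away from zero and the training share absorbing
the remainder.  That exact rule reproduces every published per-class
count, including the two cells a naive rounding misses (the 772.5
validation half-case resolving to 773 and a training count of 1795
where direct rounding of the training fraction gives 1794).

Balancing augments only the *training* split (after splitting, so no
test image ever leaks into training): a class with factor k keeps its
originals and adds k augmented copies per original, growing an
n-image class to n*(k+1).  The default factors are the published
ones: Scc 25, Akiec 17, Bcc 4, Bkl 5, Df 60, Mel 3, Nv 0, Vasc 60.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from skimage.transform import resize, rotate

__all__ = [
    "SplitRatios",
    "AugmentPlan",
    "SplitResult",
    "DEFAULT_AUGMENT_FACTORS",
    "split_counts",
    "split_dataset",
    "augment_image",
    "balance_dataset",
]

#: Published per-class augmentation factors (additional copies per original).
DEFAULT_AUGMENT_FACTORS: dict[str, int] = {
    "scc": 25,
    "akiec": 17,
    "bcc": 4,
    "bkl": 5,
    "df": 60,
    "mel": 3,
    "nv": 0,
    "vasc": 60,
}


@dataclass(frozen=True)
class SplitRatios:
    """Test and overall-validation fractions; training is the remainder."""

    test_frac: float = 0.40
    val_frac_overall: float = 0.06

    def __post_init__(self) -> None:
        if not 0.0 < self.test_frac < 1.0 or not 0.0 < self.val_frac_overall < 1.0:
            raise ValueError("fractions must lie in (0, 1)")
        if self.test_frac + self.val_frac_overall >= 1.0:
            raise ValueError("test + validation fractions leave no training share")


@dataclass(frozen=True)
class AugmentPlan:
    """Class name -> number of additional augmented copies per original."""

    factors: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_AUGMENT_FACTORS)
    )

    def __post_init__(self) -> None:
        for cls, k in self.factors.items():
            if int(k) != k or k < 0:
                raise ValueError(f"factor for {cls!r} must be a non-negative integer")

    def factor(self, cls: str) -> int:
        key = str(cls).lower()
        if key not in {c.lower() for c in self.factors}:
            raise KeyError(f"augmentation plan has no factor for class {cls!r}")
        for c, k in self.factors.items():
            if c.lower() == key:
                return int(k)
        raise KeyError(cls)  # pragma: no cover


@dataclass
class SplitResult:
    """Per-class train/val/test membership."""

    train: dict[str, list]
    val: dict[str, list]
    test: dict[str, list]

    def counts(self) -> dict[str, tuple[int, int, int]]:
        return {
            cls: (len(self.train[cls]), len(self.val[cls]), len(self.test[cls]))
            for cls in self.train
        }


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_counts(n: int, ratios: SplitRatios | None = None) -> tuple[int, int, int]:
    """(train, val, test) counts for a class of size n.

    test and val are rounded half away from zero independently; train
    absorbs the remainder.
    """
    ratios = ratios or SplitRatios()
    if n < 0:
        raise ValueError("class size must be non-negative")
    n_test = _round_half_away(ratios.test_frac * n)
    n_val = _round_half_away(ratios.val_frac_overall * n)
    n_train = n - n_test - n_val
    if n_train < 0:
        raise ValueError(
            f"class of size {n} is too small: rounding leaves a negative "
            "training share"
        )
    return n_train, n_val, n_test


def split_dataset(
    items_by_class: Mapping[str, Sequence[Hashable]],
    ratios: SplitRatios | None = None,
    seed: int = 0,
) -> SplitResult:
    """Partition each class into train/val/test, sampled without replacement."""
    ratios = ratios or SplitRatios()
    train: dict[str, list] = {}
    val: dict[str, list] = {}
    test: dict[str, list] = {}
    for cls in items_by_class:
        items = list(items_by_class[cls])
        n_train, n_val, n_test = split_counts(len(items), ratios)
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, *str(cls).encode("utf-8")])
        )
        order = rng.permutation(len(items))
        shuffled = [items[i] for i in order]
        test[cls] = shuffled[:n_test]
        val[cls] = shuffled[n_test : n_test + n_val]
        train[cls] = shuffled[n_test + n_val :]
    return SplitResult(train=train, val=val, test=test)


def augment_image(image: np.ndarray, seed: int = 0) -> np.ndarray:
    """One seeded random rotate/flip/crop/resize composition.

    Rotation up to +-25 degrees (edge-replicated), independent
    horizontal and vertical flips, a random central-area crop keeping
    at least 85% of the area, then resize back to the input size.
    Deterministic in (image shape-independent) seed.
    """
    img = np.asarray(image)
    if img.size == 0 or img.ndim not in (2, 3):
        raise ValueError("expected a non-empty 2-D or 3-D image")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA06]))
    h, w = img.shape[:2]
    out = img.astype(np.float64)
    angle = rng.uniform(-25.0, 25.0)
    out = rotate(out, angle, mode="edge", preserve_range=True)
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    # random crop covering >= 85% of the area, then resize back
    scale = np.sqrt(rng.uniform(0.85, 1.0))
    ch, cw = max(int(round(h * scale)), 1), max(int(round(w * scale)), 1)
    r0 = rng.integers(0, h - ch + 1)
    c0 = rng.integers(0, w - cw + 1)
    out = out[r0 : r0 + ch, c0 : c0 + cw]
    out = resize(out, (h, w), order=1, preserve_range=True, anti_aliasing=False)
    if np.issubdtype(img.dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(img.dtype)
    return out


def balance_dataset(
    train_by_class: Mapping[str, Sequence],
    plan: AugmentPlan | None = None,
    seed: int = 0,
    augment_fn=None,
) -> dict[str, list]:
    """Grow each training class from n to n*(k+1) items.

    Originals are kept; each original contributes k augmented copies.
    When items are images, copies are produced by :func:`augment_image`
    with a seed derived deterministically from (seed, class, original
    index, copy index); ``augment_fn(item, seed)`` may override the
    transformation.  For count-level work, items may be arbitrary
    identifiers and ``augment_fn`` can simply tag them.
    """
    plan = plan or AugmentPlan()
    fn = augment_fn
    out: dict[str, list] = {}
    for cls, items in train_by_class.items():
        k = plan.factor(cls)  # raises if the class is missing from the plan
        grown = list(items)
        for i, item in enumerate(items):
            for copy in range(k):
                item_seed = int(
                    np.random.SeedSequence(
                        [seed, *str(cls).encode("utf-8"), i, copy]
                    ).generate_state(1)[0]
                    % (2**31 - 1)
                )
                if fn is not None:
                    grown.append(fn(item, item_seed))
                elif isinstance(item, np.ndarray):
                    grown.append(augment_image(item, item_seed))
                else:
                    grown.append((item, f"aug{copy}"))
        out[cls] = grown
    return out
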