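"""CNN-style feature extraction primitives and backbone registry.

Deep-feature extraction in the pipeline means: push each (enhanced,
segmented) image through a convolutional backbone and keep the global
average pooled activation vector.  This module provides

* the numeric primitives — strided/padded cross-correlation
  (:func:`convolve2d`), max/average pooling (:func:`pool`) and global
  average pooling (:func:`global_average_pool`);
* a registry of backbone geometries (DenseNet121 / MobileNet / VGG19
  as declared by their users: GAP vector lengths 1024 / 1024 / 4096);
* a self-contained "toy" adapter per backbone — a fixed, seeded stack
  of conv/pool/GAP stages with He-scaled random weights that produces
  vectors of exactly the declared length with no downloaded weights.
  An ``external`` adapter hook lets callers plug in real pretrained
  models; nothing in the package requires one.

"Convolution" follows the deep-learning convention: valid
cross-correlation (no kernel flip) with explicit stride and zero
padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .matrix import FeatureMatrix

__all__ = [
    "Kernel",
    "BackboneSpec",
    "BACKBONES",
    "convolve2d",
    "pool",
    "global_average_pool",
    "extract_features",
    "toy_backbone_vector",
]

INPUT_SIZE = (224, 224)  # backbone input convention


@dataclass(frozen=True)
class Kernel:
    """Convolution filter: weights (f, f, z) or (f, f, z, m), stride, zero-padding."""

    weights: np.ndarray
    stride: int = 1
    padding: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        if w.ndim not in (3, 4) or w.shape[0] != w.shape[1] or w.shape[0] < 1:
            raise ValueError(
                f"weights must be (f, f, z[, m]) with f >= 1, got {w.shape}"
            )
        if self.stride < 1 or self.padding < 0:
            raise ValueError("stride must be >= 1 and padding >= 0")


def _as_3d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[..., None]
    if x.ndim != 3:
        raise ValueError(f"expected (H, W[, C]) input, got shape {x.shape}")
    return x


def convolve2d(image: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Strided, zero-padded cross-correlation.

    Output spatial side is ``(H - f + 2*pad)/stride + 1`` and must be
    an integer; a 3-D kernel yields an ``(H', W')`` map, a 4-D kernel
    an ``(H', W', m)`` stack.
    """
    x = _as_3d(image)
    w = kernel.weights
    f, z = w.shape[0], w.shape[2]
    if x.shape[2] != z:
        raise ValueError(
            f"kernel expects {z} channels but input has {x.shape[2]}"
        )
    h, wd = x.shape[:2]
    for side in (h, wd):
        num = side - f + 2 * kernel.padding
        if num < 0 or num % kernel.stride != 0:
            raise ValueError(
                f"non-integer output size for side {side} with f={f}, "
                f"pad={kernel.padding}, stride={kernel.stride}"
            )
    if kernel.padding:
        p = kernel.padding
        x = np.pad(x, ((p, p), (p, p), (0, 0)))
    windows = sliding_window_view(x, (f, f), axis=(0, 1))
    windows = windows[:: kernel.stride, :: kernel.stride]  # (H', W', z, f, f)
    if w.ndim == 3:
        return np.einsum("ijzab,abz->ij", windows, w)
    return np.einsum("ijzab,abzm->ijm", windows, w)


def pool(fmap: np.ndarray, k: int, stride: int, mode: str = "max") -> np.ndarray:
    """Per-channel k x k window pooling stepped by ``stride``.

    ``mode='max'`` keeps the window maximum, ``mode='avg'`` the window
    mean.  Windows are the fully contained ones (no padding).
    """
    if k < 1 or stride < 1:
        raise ValueError("k and stride must be >= 1")
    if mode not in ("max", "avg"):
        raise ValueError(f"mode must be 'max' or 'avg', got {mode!r}")
    x = _as_3d(fmap)
    if k > min(x.shape[:2]):
        raise ValueError(f"pool size {k} exceeds spatial dims {x.shape[:2]}")
    windows = sliding_window_view(x, (k, k), axis=(0, 1))[::stride, ::stride]
    out = windows.max(axis=(-2, -1)) if mode == "max" else windows.mean(axis=(-2, -1))
    return out if np.asarray(fmap).ndim == 3 else out[..., 0]


def global_average_pool(fmap: np.ndarray) -> np.ndarray:
    """Spatial mean per channel; (H, W, C) -> vector of length C."""
    x = _as_3d(fmap)
    if x.shape[0] == 0 or x.shape[1] == 0:
        raise ValueError("cannot pool an empty feature map")
    return x.mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# Backbone registry
# ---------------------------------------------------------------------------

#: Adapters registered by callers who have real pretrained models:
#: name -> callable(list of HxWx3 uint8 images) -> (n, declared_vector_len).
EXTERNAL_ADAPTERS: dict[str, Callable[[Sequence[np.ndarray]], np.ndarray]] = {}


@dataclass(frozen=True)
class BackboneSpec:
    """Declared geometry of a feature-extraction backbone.

    ``declared_map_dims`` is the final feature-map shape as reported
    for each architecture and ``declared_vector_len`` the GAP vector
    length; the toy adapter reproduces the vector length (the map
    geometries, recorded verbatim, are not all mutually consistent
    with the canonical architectures and are carried as metadata).
    """

    name: str
    declared_map_dims: tuple[int, int, int]
    declared_vector_len: int
    adapter: str = "toy"

    def __post_init__(self) -> None:
        if self.declared_vector_len <= 0:
            raise ValueError("declared_vector_len must be positive")
        if self.adapter not in ("toy", "external"):
            raise ValueError("adapter must be 'toy' or 'external'")


BACKBONES: dict[str, BackboneSpec] = {
    "densenet121": BackboneSpec("densenet121", (16, 32, 512), 1024),
    "mobilenet": BackboneSpec("mobilenet", (7, 7, 512), 1024),
    "vgg19": BackboneSpec("vgg19", (7, 7, 1024), 4096),
    "toy": BackboneSpec("toy", (7, 7, 64), 64),
}


def get_backbone(name: str) -> BackboneSpec:
    try:
        return BACKBONES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown backbone {name!r}; known: {sorted(BACKBONES)}"
        ) from None


def _stable_seed(name: str, seed: int) -> list[int]:
    return [seed, *name.encode("utf-8")]


def _toy_weights(name: str, out_dim: int, seed: int) -> dict[str, Kernel]:
    """Fixed seeded conv stack for a backbone; He-scaled normal weights.

    Two conv/pool stages plus 1x1 projection heads at both scales; the
    two GAP vectors concatenate to ``out_dim`` (one quarter from the
    early, fine-scale stage, the rest from the deep stage), which makes
    the features sensitive to both local texture and global color.
    """
    rng = np.random.default_rng(np.random.SeedSequence(_stable_seed(name, seed)))

    def he(shape: tuple[int, ...]) -> np.ndarray:
        fan_in = shape[0] * shape[1] * shape[2]
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    d_mid = max(out_dim // 4, 1)
    d_top = out_dim - d_mid
    return {
        "stem": Kernel(he((4, 4, 3, 24)), stride=4, padding=0),  # 224 -> 56
        "conv2": Kernel(he((3, 3, 24, 96)), stride=1, padding=1),  # 28 -> 28
        "head_mid": Kernel(he((1, 1, 24, d_mid))),
        "head_top": Kernel(he((1, 1, 96, d_top))),
    }


def toy_backbone_vector(image: np.ndarray, spec: BackboneSpec, seed: int = 0) -> np.ndarray:
    """Run one image through the seeded toy conv/pool/GAP stack."""
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 2:
        x = np.repeat(x[..., None], 3, axis=2)
    if x.shape[:2] != INPUT_SIZE:
        x = resize(x, INPUT_SIZE, order=1, anti_aliasing=True, preserve_range=True)
    x = x / 255.0 - 0.5
    k = _toy_weights(spec.name, spec.declared_vector_len, seed)
    s1 = np.maximum(convolve2d(x, k["stem"]), 0.0)  # 56x56x24
    s2 = np.maximum(convolve2d(pool(s1, 2, 2, "max"), k["conv2"]), 0.0)  # 28x28x96
    mid = global_average_pool(convolve2d(pool(s1, 4, 4, "avg"), k["head_mid"]))
    top = global_average_pool(convolve2d(pool(s2, 4, 4, "avg"), k["head_top"]))
    return np.concatenate([mid, top])


def _load_images_from_dir(root: str | Path) -> tuple[list[np.ndarray], list[str]]:
    import imageio.v3 as iio

    root = Path(root)
    images, ids = [], []
    for path in sorted(root.rglob("*.png")) + sorted(root.rglob("*.jpg")):
        if path.name.endswith(".mask.png"):
            continue
        images.append(np.asarray(iio.imread(path)))
        ids.append(path.stem)
    return images, ids


def extract_features(
    dataset: "Iterable[np.ndarray] | str | Path",
    backbone: BackboneSpec | str = "toy",
    seed: int = 0,
    row_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Extract one feature vector per image into an aligned matrix.

    ``dataset`` may be a directory of PNG/JPEG images, a
    :class:`~dermafusion.synthetic.SyntheticDataset`, or any iterable
    of images.  Row order equals dataset order.  The toy adapter is
    deterministic in (backbone, seed); the external adapter delegates
    to a callable registered in :data:`EXTERNAL_ADAPTERS`.
    """
    spec = get_backbone(backbone) if isinstance(backbone, str) else backbone
    if isinstance(dataset, (str, Path)):
        images, ids = _load_images_from_dir(dataset)
    elif hasattr(dataset, "images"):
        images = list(dataset.images)
        ids = list(getattr(dataset, "ids", []) or [])
    else:
        images = list(dataset)
        ids = []
    if row_ids is not None:
        ids = list(row_ids)
    if not ids:
        ids = [str(i) for i in range(len(images))]
    if len(ids) != len(images):
        raise ValueError("row_ids length must match the number of images")

    if spec.adapter == "external":
        fn = EXTERNAL_ADAPTERS.get(spec.name)
        if fn is None:
            raise KeyError(
                f"no external adapter registered for backbone {spec.name!r}"
            )
        values = np.asarray(fn(images), dtype=np.float64)
    else:
        values = np.empty((len(images), spec.declared_vector_len))
        for i, img in enumerate(images):
            values[i] = toy_backbone_vector(img, spec, seed)
    if values.shape != (len(images), spec.declared_vector_len):
        raise ValueError(
            f"adapter returned shape {values.shape}, expected "
            f"({len(images)}, {spec.declared_vector_len})"
        )
    return FeatureMatrix(values.reshape(len(images), spec.declared_vector_len), ids)
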