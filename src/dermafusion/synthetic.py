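"""Synthetic dermoscopy-like image and feature generation.

Real dermoscopy archives (e.g. ISIC 2019) are multi-gigabyte downloads,
so every downstream stage of the pipeline is exercised instead on
images generated here: a skin-toned background carrying a single
elliptical lesion with an optionally irregular border, class-specific
color, mild texture, additive Gaussian noise and (optionally) dark
hair strokes.  Ground-truth masks come for free, which makes the
segmentation stage checkable with a Dice score instead of by eye.

All generators are pure functions of their parameters and a seed.
At ``border_irregularity=0`` and ``noise_sigma=0`` the lesion is an
exact rotated ellipse, so geometric ground truth stays analytically
checkable.

For testing the reduction/classification stages without images,
:func:`generate_feature_matrix` produces Gaussian class blobs whose
mean separation is controlled in units of the within-class standard
deviation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .matrix import FeatureMatrix

__all__ = [
    "LesionSpec",
    "SyntheticDataset",
    "generate_lesion_image",
    "generate_class_dataset",
    "generate_feature_matrix",
    "default_class_specs",
    "write_dataset",
]


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and appearance of one synthetic lesion.

    ``border_irregularity`` is the amplitude (fraction of the local
    elliptical radius) of a seeded sinusoid-plus-noise radial
    perturbation; 0 gives an exact ellipse.  ``noise_sigma`` is the
    standard deviation of additive Gaussian pixel noise in 8-bit
    intensity units.
    """

    center: tuple[float, float] = (112.0, 112.0)  # (row, col) px
    axes: tuple[float, float] = (55.0, 42.0)  # semi-axes (a, b) px
    rotation: float = 0.0  # degrees
    lesion_color: tuple[int, int, int] = (101, 67, 51)
    skin_color: tuple[int, int, int] = (224, 172, 143)
    border_irregularity: float = 0.0
    noise_sigma: float = 0.0
    hair_count: int = 0

    def __post_init__(self) -> None:
        a, b = self.axes
        if a <= 0 or b <= 0:
            raise ValueError(f"semi-axes must be positive, got {self.axes}")
        for name in ("lesion_color", "skin_color"):
            col = getattr(self, name)
            if len(col) != 3 or any(not (0 <= c <= 255) for c in col):
                raise ValueError(f"{name} must be an RGB triple in [0, 255]")
        if not 0.0 <= self.border_irregularity <= 1.0:
            raise ValueError("border_irregularity must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.hair_count < 0:
            raise ValueError("hair_count must be non-negative")


@dataclass
class SyntheticDataset:
    """Images with integer class labels and ground-truth masks."""

    images: list[np.ndarray]
    labels: list[int]
    masks: list[np.ndarray]
    ids: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.images)
        if not (len(self.labels) == len(self.masks) == n):
            raise ValueError("images, labels and masks must have equal length")
        if not self.ids:
            self.ids = [f"img{i:05d}" for i in range(n)]
        if len(self.ids) != n:
            raise ValueError("ids length mismatch")
        for img, mask in zip(self.images, self.masks):
            if img.shape[:2] != mask.shape[:2]:
                raise ValueError("mask shape does not match its image")
        if self.labels:
            k = len(self.class_names) if self.class_names else max(self.labels) + 1
            if any(not (0 <= y < k) for y in self.labels):
                raise ValueError("labels outside declared classes")

    def __len__(self) -> int:
        return len(self.images)


def _radial_perturbation(theta: np.ndarray, amplitude: float, seed: int) -> np.ndarray:
    """Smooth 2*pi-periodic radial wobble with peak amplitude <= `amplitude`.

    A low-order Fourier series with seeded coefficients; normalized so
    the worst case equals the requested amplitude exactly.
    """
    if amplitude == 0.0:
        return np.zeros_like(theta)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EA5]))
    orders = np.arange(2, 7)
    amps = rng.normal(size=orders.size)
    phases = rng.uniform(0, 2 * np.pi, size=orders.size)
    wave = np.zeros_like(theta, dtype=float)
    for o, a, ph in zip(orders, amps, phases):
        wave += a * np.sin(o * theta + ph)
    peak = np.max(np.abs(wave))
    if peak == 0:  # pragma: no cover - measure-zero draw
        return np.zeros_like(theta)
    return amplitude * wave / peak


def _draw_hairs(image: np.ndarray, count: int, seed: int) -> None:
    """Overlay thin dark quadratic-Bezier strokes in place."""
    if count == 0:
        return
    from skimage.draw import line

    h, w = image.shape[:2]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA1B]))
    for _ in range(count):
        p0 = rng.uniform([0, 0], [h - 1, w - 1])
        p2 = rng.uniform([0, 0], [h - 1, w - 1])
        p1 = (p0 + p2) / 2 + rng.normal(0, 0.25 * min(h, w), size=2)
        t = np.linspace(0, 1, 64)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        pts = np.clip(np.round(pts).astype(int), 0, [h - 1, w - 1])
        shade = rng.integers(20, 60)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = line(r0, c0, r1, c1)
            image[rr, cc] = shade


def generate_lesion_image(
    spec: LesionSpec, size: tuple[int, int] = (224, 224), seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Render one lesion image and its binary ground-truth mask.

    Returns
    -------
    image : uint8 array of shape ``(H, W, 3)``
    mask : uint8 array of shape ``(H, W)``, 1 on lesion pixels

    The lesion interior is ``lesion_color`` modulated by a gentle
    deterministic texture (zero-mean, amplitude 5), the outside is
    ``skin_color`` with a soft illumination gradient, and Gaussian
    noise of ``noise_sigma`` is added last.  With ``noise_sigma=0``
    image and mask are co-registered exactly.
    """
    h, w = size
    cr, cc = spec.center
    a, b = spec.axes
    reach = max(a, b) * (1.0 + spec.border_irregularity)
    if cr - reach < 0 or cr + reach > h - 1 or cc - reach < 0 or cc + reach > w - 1:
        raise ValueError(
            f"lesion (center {spec.center}, reach {reach:.1f} px) does not fit "
            f"inside a {h}x{w} frame"
        )

    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = rows - cr, cols - cc
    phi = np.deg2rad(spec.rotation)
    xr = np.cos(phi) * dx + np.sin(phi) * dy  # along semi-axis a
    yr = -np.sin(phi) * dx + np.cos(phi) * dy  # along semi-axis b
    rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)  # elliptical radius
    theta = np.arctan2(yr / b, xr / a)
    boundary = 1.0 + _radial_perturbation(theta, spec.border_irregularity, seed)
    mask = (rho <= boundary).astype(np.uint8)

    img = np.empty((h, w, 3), dtype=float)
    skin = np.asarray(spec.skin_color, dtype=float)
    lesion = np.asarray(spec.lesion_color, dtype=float)
    # soft illumination gradient over skin; zero-mean texture inside lesion
    illum = 1.0 + 0.03 * ((rows - h / 2) / h + (cols - w / 2) / w)
    img[:] = skin[None, None, :] * illum[..., None]
    texture = 5.0 * np.sin(rows / 6.0) * np.cos(cols / 7.0)
    inside = mask.astype(bool)
    img[inside] = lesion[None, :] + texture[inside, None]

    _draw_hairs(img, spec.hair_count, seed)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9015E]))
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    return np.clip(np.round(img), 0, 255).astype(np.uint8), mask


#: Eight lesion archetypes loosely echoing the ISIC 2019 classes; they
#: differ in color, eccentricity and border irregularity, which is what
#: the desk-scale pipeline can actually discriminate.
#: Palette chosen so every pair of class colors is separated by well
#: over the per-image jitter (+-12 per channel) — the classes are meant
#: to be discriminable by design, not photorealistic.
_CLASS_TEMPLATES: list[tuple[str, tuple[int, int, int], tuple[float, float], float]] = [
    ("scc", (170, 110, 90), (50.0, 40.0), 0.10),
    ("akiec", (210, 150, 130), (45.0, 38.0), 0.15),
    ("bcc", (140, 140, 50), (55.0, 42.0), 0.08),
    ("bkl", (100, 80, 50), (48.0, 44.0), 0.12),
    ("df", (130, 75, 110), (40.0, 36.0), 0.05),
    ("mel", (50, 35, 30), (58.0, 44.0), 0.20),
    ("nv", (105, 140, 90), (44.0, 42.0), 0.04),
    ("vasc", (180, 60, 70), (42.0, 38.0), 0.06),
]


def default_class_specs(
    size: tuple[int, int] = (224, 224),
    noise_sigma: float = 4.0,
    n_classes: int = 8,
) -> tuple[list[LesionSpec], list[str]]:
    """Template specs (and names) for up to eight lesion classes.

    Geometry is expressed for a 224x224 frame and scaled to ``size``.
    """
    if not 1 <= n_classes <= len(_CLASS_TEMPLATES):
        raise ValueError(f"n_classes must be in 1..{len(_CLASS_TEMPLATES)}")
    h, w = size
    s = min(h, w) / 224.0
    specs, names = [], []
    for name, color, (a, b), irr in _CLASS_TEMPLATES[:n_classes]:
        specs.append(
            LesionSpec(
                center=(h / 2.0, w / 2.0),
                axes=(a * s, b * s),
                lesion_color=color,
                border_irregularity=irr,
                noise_sigma=noise_sigma,
            )
        )
        names.append(name)
    return specs, names


def _jitter_spec(
    spec: LesionSpec, size: tuple[int, int], rng: np.random.Generator
) -> LesionSpec:
    """Perturb a template so images within a class vary realistically."""
    h, w = size
    a, b = spec.axes
    scale = rng.uniform(0.85, 1.15)
    a2, b2 = a * scale, b * scale * rng.uniform(0.9, 1.1)
    reach = max(a2, b2) * (1 + spec.border_irregularity) + 2
    lo_r, hi_r = reach, h - 1 - reach
    lo_c, hi_c = reach, w - 1 - reach
    if lo_r >= hi_r or lo_c >= hi_c:
        raise ValueError("template lesion too large for the frame")
    shift = 0.08 * min(h, w)
    center = (
        float(np.clip(spec.center[0] + rng.uniform(-shift, shift), lo_r, hi_r)),
        float(np.clip(spec.center[1] + rng.uniform(-shift, shift), lo_c, hi_c)),
    )
    color = tuple(
        int(np.clip(c + rng.integers(-12, 13), 0, 255)) for c in spec.lesion_color
    )
    return replace(
        spec,
        center=center,
        axes=(a2, b2),
        rotation=float(rng.uniform(0, 180)),
        lesion_color=color,  # type: ignore[arg-type]
    )


def generate_class_dataset(
    class_specs: Sequence[LesionSpec],
    n_per_class: int,
    size: tuple[int, int] = (224, 224),
    seed: int = 0,
    class_names: Sequence[str] | None = None,
) -> SyntheticDataset:
    """Generate ``n_per_class`` jittered images for each class template."""
    if len(class_specs) < 1:
        raise ValueError("at least one class spec is required")
    if n_per_class < 0:
        raise ValueError("n_per_class must be non-negative")
    names = (
        list(class_names)
        if class_names is not None
        else [f"class{k}" for k in range(len(class_specs))]
    )
    if len(names) != len(class_specs):
        raise ValueError("class_names length must match class_specs")
    images, labels, masks, ids = [], [], [], []
    for k, template in enumerate(class_specs):
        for i in range(n_per_class):
            rng = np.random.default_rng(np.random.SeedSequence([seed, k, i]))
            spec = _jitter_spec(template, size, rng)
            img_seed = int(rng.integers(0, 2**31 - 1))
            img, mask = generate_lesion_image(spec, size, img_seed)
            images.append(img)
            labels.append(k)
            masks.append(mask)
            ids.append(f"{names[k]}_{i:04d}")
    return SyntheticDataset(images, labels, masks, ids, names)


def generate_feature_matrix(
    n_per_class: int,
    p: int,
    class_sep: float,
    K: int,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Gaussian class blobs with unit within-class standard deviation.

    ``class_sep`` follows the scikit-learn convention: class means sit
    at ``class_sep`` times distinct coordinate-axis vertices (pairwise
    Euclidean distance ``class_sep * sqrt(2)``) when ``p >= K``; for
    ``p < K`` random directions are rescaled so the minimum pairwise
    distance is ``class_sep * sqrt(2)``.
    """
    if p < 1 or K < 1:
        raise ValueError("p and K must be >= 1")
    if n_per_class < 0:
        raise ValueError("n_per_class must be non-negative")
    rng = np.random.default_rng(seed)
    if p >= K:
        means = np.zeros((K, p))
        means[np.arange(K), np.arange(K)] = class_sep
    else:
        means = rng.normal(size=(K, p))
        if K > 1 and class_sep > 0:
            d = np.sqrt(((means[:, None] - means[None, :]) ** 2).sum(-1))
            dmin = d[np.triu_indices(K, 1)].min()
            means *= class_sep * np.sqrt(2.0) / max(dmin, 1e-12)
        elif class_sep == 0:
            means[:] = 0.0
    X = np.empty((K * n_per_class, p))
    y = np.repeat(np.arange(K), n_per_class)
    for k in range(K):
        block = slice(k * n_per_class, (k + 1) * n_per_class)
        X[block] = means[k] + rng.normal(size=(n_per_class, p))
    return FeatureMatrix(X), y


def write_dataset(
    dataset: SyntheticDataset,
    root: str | Path,
    splits: dict[str, str] | None = None,
) -> Path:
    """Write images/masks in a class-per-folder layout plus a manifest CSV.

    Layout: ``<root>/<class_name>/<id>.png`` with ``<id>.mask.png``
    alongside; the manifest has columns ``id, class, split``.
    Returns the manifest path.
    """
    root = Path(root)
    names = dataset.class_names or [
        f"class{k}" for k in range(max(dataset.labels, default=-1) + 1)
    ]
    for img, mask, label, img_id in zip(
        dataset.images, dataset.masks, dataset.labels, dataset.ids
    ):
        cls_dir = root / names[label]
        cls_dir.mkdir(parents=True, exist_ok=True)
        iio.imwrite(cls_dir / f"{img_id}.png", img)
        iio.imwrite(cls_dir / f"{img_id}.mask.png", (mask * 255).astype(np.uint8))
    manifest = root / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "class", "split"])
        for label, img_id in zip(dataset.labels, dataset.ids):
            split = splits.get(img_id, "") if splits else ""
            writer.writerow([img_id, names[label], split])
    return manifest
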