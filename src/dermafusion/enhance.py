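"""Fused image enhancement: average filtering followed by CLAHE.

Dermoscopy images carry sensor noise and often low contrast between a
lesion and the surrounding skin.  The enhancement stage runs two
standard operations in sequence: a k x k average (box) filter to
suppress high-frequency noise, then contrast-limited adaptive
histogram equalization (CLAHE) to lift local contrast at lesion
borders without over-amplifying noise.

Conventions
-----------
* Images are ``(H, W)`` grayscale or ``(H, W, 3)`` RGB, uint8 or float
  on the 0-255 scale.
* :func:`average_filter` returns float64 (no premature quantization);
  :func:`enhance` returns the dtype it was given.
* Borders are replicate-padded: zero padding would darken image
  borders, which CLAHE would then amplify.
* On RGB input CLAHE equalizes the luminance channel only (YCbCr),
  since per-channel equalization shifts hue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage import exposure
from skimage.color import rgb2ycbcr, ycbcr2rgb

__all__ = ["EnhanceConfig", "average_filter", "clahe", "enhance"]


@dataclass(frozen=True)
class EnhanceConfig:
    """Parameters of the fused enhancement stage.

    kernel_size : odd box-filter side, px (default 5 -> a 25-pixel
    neighborhood).  clahe_tile : number of CLAHE tiles per image side.
    clahe_clip : clip limit as a multiple of the uniform histogram bin
    height (OpenCV convention; mapped internally to skimage's [0, 1]
    fraction as ``clip / 256``).
    """

    kernel_size: int = 5
    clahe_tile: int = 8
    clahe_clip: float = 2.0

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.clahe_tile < 1:
            raise ValueError("clahe_tile must be >= 1")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be positive")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim not in (2, 3) or image.size == 0:
        raise ValueError(f"expected a non-empty 2-D or 3-D image, got shape {image.shape}")
    if image.ndim == 3 and image.shape[2] not in (1, 3):
        raise ValueError(f"channel count must be 1 or 3, got {image.shape[2]}")
    return image


def average_filter(image: np.ndarray, kernel_size: int = 5) -> np.ndarray:
    """Mean of each pixel's k x k neighborhood, per channel.

    Replicate padding at the borders keeps the output the same shape
    as the input.  Returns float64 on the input's intensity scale.
    """
    image = _check_image(image)
    if kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd, got {kernel_size}")
    if kernel_size < 1 or kernel_size > min(image.shape[:2]):
        raise ValueError(
            f"kernel_size must be in [1, min(H, W)={min(image.shape[:2])}]"
        )
    squeeze = image.ndim == 2
    img = image[..., None].astype(np.float64) if squeeze else image.astype(np.float64)
    pad = kernel_size // 2
    padded = np.pad(img, ((pad, pad), (pad, pad), (0, 0)), mode="edge")
    windows = sliding_window_view(padded, (kernel_size, kernel_size), axis=(0, 1))
    out = windows.mean(axis=(-2, -1))
    return out[..., 0] if squeeze else out


def clahe(image: np.ndarray, tile: int = 8, clip: float = 2.0) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into ``tile x tile`` regions; each region's
    histogram is equalized with the excess above the clip limit
    redistributed, and region mappings are blended bilinearly.  RGB
    images are equalized on luminance only.  Output is float64 in
    [0, 255].
    """
    image = _check_image(image)
    h, w = image.shape[:2]
    if tile < 1:
        raise ValueError("tile must be >= 1")
    if tile > min(h, w):
        raise ValueError(f"tile={tile} exceeds the smallest image side {min(h, w)}")
    if clip <= 0:
        raise ValueError("clip must be positive")
    kernel = (max(h // tile, 1), max(w // tile, 1))
    clip_frac = min(clip / 256.0, 1.0)

    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 255.0)
    if arr.ndim == 3 and arr.shape[2] == 3:
        ycc = rgb2ycbcr(arr / 255.0)
        y = (ycc[..., 0] - 16.0) / 219.0  # luminance to [0, 1]
        y_eq = exposure.equalize_adapthist(
            np.clip(y, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_frac
        )
        ycc[..., 0] = y_eq * 219.0 + 16.0
        out = np.clip(ycbcr2rgb(ycc), 0.0, 1.0) * 255.0
        return out
    chan = arr[..., 0] if arr.ndim == 3 else arr
    eq = exposure.equalize_adapthist(
        chan / 255.0, kernel_size=kernel, clip_limit=clip_frac
    )
    out = eq * 255.0
    return out[..., None] if arr.ndim == 3 else out


def enhance(image: np.ndarray, config: EnhanceConfig | None = None) -> np.ndarray:
    """Average filter then CLAHE — the fused enhancement stage.

    Exactly ``clahe(average_filter(image, k), tile, clip)``, with the
    result cast back to the input dtype (rounded for integer inputs).
    """
    config = config or EnhanceConfig()
    image = _check_image(image)
    out = clahe(
        average_filter(image, config.kernel_size),
        tile=config.clahe_tile,
        clip=config.clahe_clip,
    )
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(np.asarray(image).dtype)
    return out
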