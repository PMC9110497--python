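"""Image representation, file I/O and geometric preprocessing.

Images are plain numpy arrays of shape (H, W, 3), dtype float64 or float32,
channel order R, G, B, values in the unit range [0, 1].  All loss formulas
in this package are defined on that range.  8-bit files are mapped by
division with 255 on load and rounded back on save, so a save/load
round trip is exact to within one quantisation step (1/255 per channel).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

__all__ = ["load_image", "save_image", "validate_image",
           "resize_keep_aspect", "random_crop"]


def validate_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Check the (H, W, 3) unit-range contract; returns the array."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"{name} must have shape (H, W, 3), got {img.shape}")
    if img.size == 0:
        raise ValueError(f"{name} is empty")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError(f"{name} values must lie in [0, 1]; "
                         f"got range [{img.min():.4g}, {img.max():.4g}]")
    return img


def load_image(path) -> np.ndarray:
    """Load a PNG/JPEG file as a unit-range RGB array.

    Grayscale or alpha-bearing inputs are converted to RGB with a warning.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode != "RGB":
                logger.warning("converting %s from mode %s to RGB", path, im.mode)
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float64)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    return arr / 255.0


def save_image(img: np.ndarray, path) -> None:
    """Write a unit-range RGB array as an 8-bit PNG/JPEG (by extension)."""
    img = validate_image(img)
    data = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="RGB").save(Path(path))


def resize_keep_aspect(img: np.ndarray, target_w: int, target_h: int) -> np.ndarray:
    """Aspect-preserving bilinear rescale followed by a symmetric center crop.

    The image is scaled by the larger of the two axis ratios so it covers the
    target box, then cropped to exactly (target_h, target_w).  Upsampling is
    permitted but logged.
    """
    img = validate_image(img)
    if target_w <= 0 or target_h <= 0:
        raise ValueError("target dimensions must be positive")
    h, w = img.shape[:2]
    scale = max(target_w / w, target_h / h)
    if scale > 1:
        logger.warning("upsampling %dx%d to cover %dx%d", w, h, target_w, target_h)
    new_h = max(target_h, int(round(h * scale)))
    new_w = max(target_w, int(round(w * scale)))
    scaled = _sk_resize(img, (new_h, new_w), order=1, mode="edge",
                        anti_aliasing=scale < 1, preserve_range=True)
    top = (new_h - target_h) // 2
    left = (new_w - target_w) // 2
    out = scaled[top:top + target_h, left:left + target_w]
    return np.clip(out, 0.0, 1.0)


def random_crop(img: np.ndarray, size: int, seed) -> np.ndarray:
    """Square crop at a uniformly random position; pure in (img, size, seed).

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    img = validate_image(img)
    h, w = img.shape[:2]
    if size > min(h, w):
        raise ValueError(
            f"crop size {size} exceeds image {h}x{w}; resize the image first")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    top = int(rng.integers(0, h - size + 1))
    left = int(rng.integers(0, w - size + 1))
    return img[top:top + size, left:left + size]
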