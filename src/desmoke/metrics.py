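"""Referenceless image-quality metrics for desmoking evaluation.

* **REA** (restored-edge assessment): the rate of newly visible edges in a
  restored frame relative to its original, (n_restored - n_original) /
  n_original.  Visible edges are luminance-gradient pixels whose magnitude
  exceeds 5% of the local mean luminance.  An unchanged image scores 0;
  higher is better restoration.
* **JNBM** (just-noticeable-blur metric): perceptual sharpness from
  probability-summation over edge widths measured against contrast-dependent
  just-noticeable blur widths, pooled with exponent 3.6 over 64x64 blocks.
  Higher is sharper.
* **fog density proxy**: trimmed mean of the (soft-matting refined) dark
  channel — higher means more smoke.  This is a transparent stand-in score,
  NOT the published corpus-trained fog-density evaluator; it is labelled
  ``fog_proxy`` in every output.

Luminance uses Rec. 601 weights (0.299 R + 0.587 G + 0.114 B).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import priors
from .image_core import load_image, validate_image

logger = logging.getLogger(__name__)

__all__ = ["rea", "jnbm", "fog_density_proxy", "evaluate_batch",
           "MetricReport", "luminance", "count_visible_edges"]

REC601 = np.array([0.299, 0.587, 0.114])

# REA parameters: 3x3 gradient operator, visibility at 5% local contrast
_REA_CONTRAST = 0.05
_REA_LOCAL = 11

# JNBM parameters: 64x64 blocks, a block is an "edge block" if more than
# 0.2% of its pixels are edge pixels; probability-summation exponent 3.6;
# just-noticeable width 5 for block contrast <= 50 (8-bit), else 3
_JNB_BLOCK = 64
_JNB_EDGE_BLOCK_FRAC = 0.002
_JNB_BETA = 3.6
_SOBEL_THRESHOLD = 25.5  # on 0..255 luminance gradient (10%)


def luminance(img: np.ndarray) -> np.ndarray:
    img = validate_image(img)
    return img @ REC601


def count_visible_edges(img: np.ndarray) -> int:
    """Number of pixels whose 3x3 gradient exceeds 5% local mean luminance."""
    lum = luminance(img)
    gx = ndimage.sobel(lum, axis=1, mode="nearest") / 8.0
    gy = ndimage.sobel(lum, axis=0, mode="nearest") / 8.0
    grad = np.hypot(gx, gy)
    local = ndimage.uniform_filter(lum, size=_REA_LOCAL, mode="nearest")
    visible = grad > _REA_CONTRAST * np.maximum(local, 1e-3)
    return int(visible.sum())


def rea(original: np.ndarray, restored: np.ndarray) -> float:
    """Rate of new visible edges: (n_restored - n_original) / n_original."""
    original = validate_image(original, "original")
    restored = validate_image(restored, "restored")
    if original.shape != restored.shape:
        raise ValueError("original and restored images must share a shape")
    n_orig = count_visible_edges(original)
    if n_orig == 0:
        raise ValueError("REA undefined: the original image has no visible "
                         "edges (division by zero)")
    n_rest = count_visible_edges(restored)
    return (n_rest - n_orig) / n_orig


def _edge_widths_in_rows(lum255: np.ndarray, edge_cols: np.ndarray,
                         edge_rows: np.ndarray) -> np.ndarray:
    """Width of each (row, col) edge pixel: span between the nearest local
    luminance extrema along its row."""
    h, w = lum255.shape
    widths = np.empty(edge_rows.size)
    for n, (r, c) in enumerate(zip(edge_rows, edge_cols)):
        row = lum255[r]
        rising = row[min(c + 1, w - 1)] >= row[c]
        # walk left while monotone in the edge direction
        left = c
        while left > 0 and ((row[left - 1] <= row[left]) == rising
                            and row[left - 1] != row[left]):
            left -= 1
        right = c
        while right < w - 1 and ((row[right + 1] >= row[right]) == rising
                                 and row[right + 1] != row[right]):
            right += 1
        widths[n] = right - left
    return widths


def jnbm(img: np.ndarray) -> float:
    """Probability-summation sharpness score; higher = sharper.

    Blocks with no measurable edges contribute nothing; an image with no
    edge blocks at all returns 0 with a warning instead of failing, so batch
    evaluation never aborts on blank frames.
    """
    lum255 = luminance(img) * 255.0
    h, w = lum255.shape
    gx = ndimage.sobel(lum255, axis=1, mode="nearest") / 8.0
    edge_map = np.abs(gx) > _SOBEL_THRESHOLD

    n_blocks = 0
    pooled = 0.0
    for top in range(0, h - h % _JNB_BLOCK or h, _JNB_BLOCK):
        for left in range(0, w - w % _JNB_BLOCK or w, _JNB_BLOCK):
            blk = np.s_[top:top + _JNB_BLOCK, left:left + _JNB_BLOCK]
            edges = edge_map[blk]
            if edges.mean() <= _JNB_EDGE_BLOCK_FRAC:
                continue
            block_lum = lum255[blk]
            contrast = block_lum.max() - block_lum.min()
            w_jnb = 5.0 if contrast <= 50 else 3.0
            er, ec = np.nonzero(edges)
            widths = _edge_widths_in_rows(block_lum, ec, er)
            widths = widths[widths > 0]
            if widths.size == 0:
                continue
            n_blocks += 1
            d_block = float(np.sum((widths / w_jnb) ** _JNB_BETA) ** (1 / _JNB_BETA))
            pooled += d_block ** _JNB_BETA
    if n_blocks == 0 or pooled == 0:
        warnings.warn("no edge blocks found; returning sharpness 0",
                      stacklevel=2)
        return 0.0
    distortion = pooled ** (1 / _JNB_BETA)
    return n_blocks / distortion


def fog_density_proxy(img: np.ndarray, patch: int = 15,
                      trim_frac: float = 0.01, refine: bool = True) -> float:
    """Trimmed mean of the (refined) dark channel; higher = more smoke.

    A transparent stand-in for a corpus-trained fog-density score: it tracks
    the physical brightening that scattered light adds to every channel, but
    its absolute scale is its own.
    """
    img = validate_image(img)
    dark = priors.dark_channel(img, patch)
    if refine:
        dark = priors.refine_dark_channel(dark, img)
    return priors.trimmed_mean(dark, trim_frac)


@dataclass
class MetricReport:
    per_image: pd.DataFrame   # columns: path, jnbm, rea, fog_proxy
    aggregate: pd.DataFrame   # rows mean/sd per metric

    def to_csv(self, path) -> None:
        frame = self.per_image.copy()
        agg = self.aggregate.copy()
        agg.insert(0, "path", [f"__{ix}__" for ix in agg.index])
        pd.concat([frame, agg], ignore_index=True).to_csv(path, index=False)


def _list_images(d: Path) -> dict[str, Path]:
    return {p.name: p for p in sorted(d.iterdir())
            if p.suffix.lower() in {".png", ".jpg", ".jpeg"}}


def evaluate_batch(images_dir, reference_dir=None, patch: int = 15,
                   trim_frac: float = 0.01, refine: bool = True) -> MetricReport:
    """Per-image JNBM / REA / fog-proxy plus mean and sd.

    REA compares each image against the same-named file in ``reference_dir``
    (the pre-restoration originals); without a reference the REA column is
    NaN.  Mismatched filenames raise, listing the orphans.
    """
    images_dir = Path(images_dir)
    files = _list_images(images_dir)
    if not files:
        raise ValueError(f"no images found in {images_dir}")
    refs: dict[str, Path] = {}
    if reference_dir is not None:
        refs = _list_images(Path(reference_dir))
        only_img = sorted(set(files) - set(refs))
        only_ref = sorted(set(refs) - set(files))
        if only_img or only_ref:
            raise ValueError(
                "filename mismatch between images and reference: "
                f"unmatched images {only_img}, unmatched references {only_ref}")
    rows = []
    for name, path in files.items():
        img = load_image(path)
        row = {"path": name,
               "jnbm": jnbm(img),
               "rea": np.nan,
               "fog_proxy": fog_density_proxy(img, patch, trim_frac, refine)}
        if refs:
            row["rea"] = rea(load_image(refs[name]), img)
        rows.append(row)
    per_image = pd.DataFrame(rows)
    metric_cols = ["jnbm", "rea", "fog_proxy"]
    aggregate = pd.DataFrame({c: {"mean": per_image[c].mean(),
                                  "sd": per_image[c].std(ddof=1)}
                              for c in metric_cols})
    return MetricReport(per_image=per_image, aggregate=aggregate)
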