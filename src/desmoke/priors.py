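"""Smoke-sensitive image priors.

Two statistics underpin the desmoking objectives:

* the **inter-channel discrepancy** of a pixel, the sum of absolute pairwise
  differences between its R, G, B values — near zero under dense gray smoke,
  larger on vividly coloured tissue;
* the **dark channel**, the patchwise minimum over space and channels —
  near zero for haze-free tissue images, elevated wherever bright scattered
  light (smoke) lifts every channel.

Also provided: edge-aware refinement of a dark channel by solving a matting
Laplacian–regularised linear system against the colour image, and the
trimmed mean used to aggregate dark channels robustly against specular
highlights and dead-dark pixels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg
from scipy.stats import trim_mean

from .image_core import validate_image

__all__ = ["interchannel_pixel", "interchannel_image", "dark_channel",
           "matting_laplacian", "refine_dark_channel", "trimmed_mean"]


def interchannel_pixel(p) -> float:
    """|R-G| + |G-B| + |B-R| for one unit-range pixel; value in [0, 2]."""
    r, g, b = (float(v) for v in p)
    return abs(r - g) + abs(g - b) + abs(b - r)


def interchannel_image(img: np.ndarray) -> float:
    """Mean inter-channel discrepancy over all pixels; value in [0, 2]."""
    img = validate_image(img)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    psi = np.abs(r - g) + np.abs(g - b) + np.abs(b - r)
    return float(psi.mean())


def dark_channel(img: np.ndarray, patch: int = 15) -> np.ndarray:
    """Patchwise minimum over space and channels.

    The window is clamped at the image border (no artificial dark frame from
    zero padding).  Returns an (H, W) map in [0, 1].
    """
    img = validate_image(img)
    if patch < 1 or patch % 2 == 0:
        raise ValueError(f"patch must be a positive odd integer, got {patch}")
    per_pixel_min = img.min(axis=2)
    return ndimage.minimum_filter(per_pixel_min, size=patch, mode="nearest")


def matting_laplacian(guide: np.ndarray, window_eps: float = 1e-4) -> sparse.csr_matrix:
    """Matting Laplacian of a colour guide image (3x3 local windows).

    For each window w_k with mean mu_k and covariance Sigma_k the entry is
    L_ij = sum_k delta_ij - (1/9) * (1 + (I_i-mu_k)^T (Sigma_k + eps/9 I)^-1 (I_j-mu_k)).
    Row sums are zero, so constant maps lie in the null space.
    """
    guide = validate_image(guide)
    h, w = guide.shape[:2]
    n = h * w
    win = np.lib.stride_tricks.sliding_window_view(guide, (3, 3), axis=(0, 1))
    # (h-2, w-2, 3ch, 3, 3) -> (nw, 9, 3)
    V = win.transpose(0, 1, 3, 4, 2).reshape(-1, 9, 3)
    nw = V.shape[0]
    mu = V.mean(axis=1)                                        # (nw,3)
    diff = V - mu[:, None, :]                                  # (nw,9,3)
    cov = np.einsum("nij,nik->njk", diff, diff) / 9.0
    cov += (window_eps / 9.0) * np.eye(3)[None]
    inv = np.linalg.inv(cov)
    G = np.einsum("nij,njk,nlk->nil", diff, inv, diff)         # (nw,9,9)
    vals = np.eye(9)[None] - (1.0 + G) / 9.0
    idx = np.arange(n).reshape(h, w)
    widx = np.lib.stride_tricks.sliding_window_view(idx, (3, 3)).reshape(nw, 9)
    rows = np.repeat(widx, 9, axis=1).ravel()
    cols = np.tile(widx, (1, 9)).ravel()
    L = sparse.coo_matrix((vals.ravel(), (rows, cols)), shape=(n, n))
    return L.tocsr()


def refine_dark_channel(raw: np.ndarray, guide: np.ndarray, eps: float = 1e-4,
                        window_eps: float = 1e-4, tol: float = 1e-6,
                        maxiter: int = 5000) -> np.ndarray:
    """Edge-aware refinement of a coarse dark channel by soft matting.

    Solves (L + eps*E) t = eps * raw with L the matting Laplacian of the
    guide image, via conjugate gradients.  ``eps`` weighs the data term:
    large eps returns the raw map, small eps smooths aggressively along
    guide-image structure.  Output is clamped to [0, 1].
    """
    raw = np.asarray(raw, dtype=np.float64)
    guide = validate_image(guide)
    if raw.shape != guide.shape[:2]:
        raise ValueError(f"raw map {raw.shape} does not match guide "
                         f"{guide.shape[:2]}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    n = raw.size
    L = matting_laplacian(guide, window_eps)
    A = L + eps * sparse.identity(n, format="csr")
    b = eps * raw.ravel()
    x, info = cg(A, b, x0=raw.ravel().copy(), rtol=tol, maxiter=maxiter)
    if info != 0:
        residual = float(np.linalg.norm(A @ x - b))
        raise RuntimeError(
            f"soft-matting CG failed to converge (info={info}, "
            f"residual={residual:.3e})")
    return np.clip(x.reshape(raw.shape), 0.0, 1.0)


def trimmed_mean(values, trim_frac: float = 0.01) -> float:
    """Mean after discarding the lowest and highest ``trim_frac`` fraction.

    Rank-based and permutation-invariant; ``trim_frac`` is per tail and must
    lie in [0, 0.5).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("cannot take the trimmed mean of an empty collection")
    if not 0.0 <= trim_frac < 0.5:
        raise ValueError(f"trim_frac must lie in [0, 0.5), got {trim_frac}")
    if int(values.size * trim_frac) * 2 >= values.size:
        raise ValueError("trim_frac would discard every value")
    return float(trim_mean(values, trim_frac))
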