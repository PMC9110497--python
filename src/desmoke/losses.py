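"""Training objectives for unpaired desmoking.

The combined objective is

    L = L_GAN(G, F, D_X, D_Y) + lambda_cyc * L_cyc(G, F)
        + alpha * L_IC + beta * L_DC

where G maps clear -> hazy, F maps hazy -> clear, the adversarial terms use
the least-squares form, L_cyc is the two-way L1 reconstruction penalty, and
the two smoke-specific terms score the generator outputs only:

* L_IC drives the inter-channel discrepancy of the fake clear image towards
  the boundary value 1 (vivid tissue colour) and that of the fake hazy image
  away from it (grayness under smoke);
* L_DC is the trimmed mean of the dark channel of both generated images —
  low when the generated scenes are smoke-free.

These functions are the plain-numpy reference route; the differentiable
route used inside training lives in ``desmoke.nn.functional`` and is tested
for parity against this one.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from . import priors

__all__ = ["LossWeights", "TranslationDirection", "LossBreakdown",
           "adversarial_loss", "gan_log_objective", "cycle_loss",
           "ic_direction_map", "ic_loss", "dc_loss", "total_objective"]


class TranslationDirection(enum.Enum):
    CLEAR_TO_HAZY = "clear_to_hazy"
    HAZY_TO_CLEAR = "hazy_to_clear"


@dataclass(frozen=True)
class LossWeights:
    """Objective weights: alpha (inter-channel), beta (dark channel), cycle."""

    alpha: float = 3.0
    beta: float = 0.05
    lambda_cyc: float = 10.0

    def __post_init__(self):
        for name in ("alpha", "beta", "lambda_cyc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class LossBreakdown:
    adversarial_g: float
    adversarial_f: float
    cycle: float
    ic: float
    dc: float
    total: float


def adversarial_loss(scores: np.ndarray, target_is_real: bool) -> float:
    """Least-squares adversarial loss on a patch-score grid.

    Mean squared deviation of the scores from 1 (real target) or 0 (fake).
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("discriminator scores must be finite")
    target = 1.0 if target_is_real else 0.0
    return float(np.mean((scores - target) ** 2))


def gan_log_objective(scores_real: np.ndarray, scores_fake: np.ndarray) -> float:
    """Log-form adversarial objective E[log D(real)] + E[log(1 - D(fake))].

    The discriminator maximises this; the generator minimises it.  Provided
    for analysis — training uses the least-squares form above.
    """
    sr = np.asarray(scores_real, dtype=np.float64)
    sf = np.asarray(scores_fake, dtype=np.float64)
    if np.any(sr <= 0) or np.any(sf >= 1):
        raise ValueError("log objective needs scores in (0,1) with "
                         "D(real) > 0 and D(fake) < 1")
    return float(np.mean(np.log(sr)) + np.mean(np.log(1.0 - sf)))


def cycle_loss(x: np.ndarray, x_rec: np.ndarray,
               y: np.ndarray, y_rec: np.ndarray) -> float:
    """Two-way cycle-consistency: mean |x - F(G(x))| + mean |y - G(F(y))|."""
    x, x_rec = np.asarray(x), np.asarray(x_rec)
    y, y_rec = np.asarray(y), np.asarray(y_rec)
    if x.shape != x_rec.shape or y.shape != y_rec.shape:
        raise ValueError("cycle_loss shape mismatch between an image and its "
                         "reconstruction")
    return float(np.mean(np.abs(x - x_rec)) + np.mean(np.abs(y - y_rec)))


def ic_direction_map(v: float, direction: TranslationDirection) -> float:
    """Boundary map with pivot 1 applied to a (normalised) discrepancy value.

    hazy -> clear penalises distance from the boundary (push chroma up);
    clear -> hazy penalises proximity to it (push towards grayness).
    """
    v = float(v)
    if v < 0:
        raise ValueError("discrepancy value must be non-negative")
    dist = abs(v - 1.0)
    if direction is TranslationDirection.HAZY_TO_CLEAR:
        return dist
    return 1.0 - dist


def ic_loss(fake_hazy: np.ndarray, fake_clear: np.ndarray,
            normalize: bool = True) -> float:
    """Inter-channel loss over the two generated images.

    The raw per-image discrepancy lies in [0, 2]; it is divided by 2 before
    the boundary map so the term shares the cycle loss's scale.
    """
    scale = 0.5 if normalize else 1.0
    v_hazy = priors.interchannel_image(fake_hazy) * scale
    v_clear = priors.interchannel_image(fake_clear) * scale
    return (ic_direction_map(v_hazy, TranslationDirection.CLEAR_TO_HAZY)
            + ic_direction_map(v_clear, TranslationDirection.HAZY_TO_CLEAR))


def dc_loss(fake_hazy: np.ndarray, fake_clear: np.ndarray, patch: int = 7,
            trim_frac: float = 0.01, refine: bool = False,
            include_hazy_term: bool = True) -> float:
    """Dark-channel loss: trimmed dark-channel means of the generated images.

    ``refine`` applies the soft-matting refinement before aggregation (off by
    default inside gradient steps for cost; on for reported evaluations).
    ``include_hazy_term`` allows ablating the penalty on the generated hazy
    image, which the full objective includes.
    """
    def one(img):
        dark = priors.dark_channel(img, patch)
        if refine:
            dark = priors.refine_dark_channel(dark, img)
        return priors.trimmed_mean(dark, trim_frac)

    total = one(fake_clear)
    if include_hazy_term:
        total += one(fake_hazy)
    return float(total)


def total_objective(adversarial_g: float, adversarial_f: float, cycle: float,
                    ic: float, dc: float,
                    weights: LossWeights = LossWeights()) -> LossBreakdown:
    """Weighted combination with a recorded breakdown.

    With alpha = beta = 0 this reduces exactly to the baseline
    cycle-consistent adversarial objective.
    """
    parts = {"adversarial_g": adversarial_g, "adversarial_f": adversarial_f,
             "cycle": cycle, "ic": ic, "dc": dc}
    for name, value in parts.items():
        if not math.isfinite(value):
            raise ValueError(f"loss component '{name}' is not finite: {value}")
    total = (adversarial_g + adversarial_f + weights.lambda_cyc * cycle
             + weights.alpha * ic + weights.beta * dc)
    return LossBreakdown(adversarial_g=float(adversarial_g),
                         adversarial_f=float(adversarial_f),
                         cycle=float(cycle), ic=float(ic), dc=float(dc),
                         total=float(total))
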