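"""Differentiable forms of the training objectives.

These operate on autograd ``Tensor``s in NCHW layout.  Image-valued tensors
are expected in the unit range [0,1]; the discrepancy and dark-channel terms
are defined on that range (the inter-channel boundary map uses 1 as its
pivot).  The plain-numpy reference implementations live in
``desmoke.losses`` / ``desmoke.priors``; parity between the two routes is
covered by the test suite.
"""

from __future__ import annotations

from . import autograd as ag
from .autograd import Tensor


def lsgan_loss(scores: Tensor, target: float) -> Tensor:
    """Least-squares adversarial loss: mean squared deviation from target."""
    return ag.mean(ag.square(ag.affine(scores, 1.0, -float(target))))


def l1_loss(a: Tensor, b: Tensor) -> Tensor:
    return ag.mean(ag.abs_(ag.sub(a, b)))


def interchannel_mean(img01: Tensor) -> Tensor:
    """Per-sample mean inter-channel discrepancy, (N,3,H,W) -> (N,).

    For each pixel, |R-G| + |G-B| + |B-R|; averaged over pixels.
    """
    r = ag.channel_slice(img01, 0)
    g = ag.channel_slice(img01, 1)
    b = ag.channel_slice(img01, 2)
    psi = ag.add(ag.add(ag.abs_(ag.sub(r, g)), ag.abs_(ag.sub(g, b))),
                 ag.abs_(ag.sub(b, r)))
    return ag.mean(psi, axis=(1, 2, 3))


def ic_boundary(v: Tensor, direction_is_hazy_to_clear: bool) -> Tensor:
    """Direction-dependent boundary map with pivot 1, elementwise on (N,)."""
    dist = ag.abs_(ag.affine(v, 1.0, -1.0))
    if direction_is_hazy_to_clear:
        return dist
    return ag.affine(dist, -1.0, 1.0)


def ic_loss(fake_hazy01: Tensor, fake_clear01: Tensor) -> Tensor:
    """Inter-channel loss over a batch; normalised discrepancy (/2)."""
    v_hazy = ag.affine(interchannel_mean(fake_hazy01), 0.5, 0.0)
    v_clear = ag.affine(interchannel_mean(fake_clear01), 0.5, 0.0)
    term_hazy = ag.mean(ic_boundary(v_hazy, direction_is_hazy_to_clear=False))
    term_clear = ag.mean(ic_boundary(v_clear, direction_is_hazy_to_clear=True))
    return ag.add(term_hazy, term_clear)


def dark_channel_mean(img01: Tensor, patch: int, trim_frac: float) -> Tensor:
    """Per-batch trimmed mean of the dark channel, scalar Tensor."""
    dark = ag.min_pool2d(ag.channel_min(img01), patch)
    return ag.mean(ag.trimmed_mean_per_sample(dark, trim_frac))


def dc_loss(fake_hazy01: Tensor, fake_clear01: Tensor, patch: int = 7,
            trim_frac: float = 0.01, include_hazy_term: bool = True) -> Tensor:
    """Dark-channel loss: trimmed dark-channel mean of both generated domains."""
    term = dark_channel_mean(fake_clear01, patch, trim_frac)
    if include_hazy_term:
        term = ag.add(term, dark_channel_mean(fake_hazy01, patch, trim_frac))
    return term
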