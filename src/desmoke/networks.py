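"""Generator and discriminator architectures.

The generator is a residual translation network: a 7x7 stem, two stride-2
downsamplings, ``n_res_blocks`` residual blocks at the bottleneck, two
nearest-upsample + 3x3 conv upsamplings, and a 7x7 tanh head.  Internally it
maps [-1, 1] images to [-1, 1]; the public callable accepts and returns
unit-range (H, W, 3) / (N, H, W, 3) arrays, reflect-padding inputs whose
sides are not divisible by 4 and cropping back afterwards.

The discriminator is a patch classifier: ``n_layers`` stride-2 4x4
convolutions followed by two stride-1 4x4 convolutions, emitting one
real/fake score per receptive-field patch (70x70 pixels for the default
3-layer spec).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn.autograd import Tensor
from .nn.layers import (Conv2d, InstanceNorm, LeakyReLU, Module, ReLU,
                        ResidualBlock, Sequential, Tanh, UpsampleNearest2)

logger = logging.getLogger(__name__)

__all__ = ["GeneratorSpec", "DiscriminatorSpec", "ResNetGenerator",
           "PatchDiscriminator", "build_generator", "build_discriminator",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class GeneratorSpec:
    n_res_blocks: int = 9
    base_width: int = 64
    norm: str = "instance"

    def __post_init__(self):
        if self.n_res_blocks < 1:
            raise ValueError("n_res_blocks must be >= 1")
        if self.norm != "instance":
            raise ValueError("only instance normalisation is supported")


@dataclass(frozen=True)
class DiscriminatorSpec:
    n_layers: int = 3
    base_width: int = 64

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


def _to_nchw(images: np.ndarray) -> tuple[np.ndarray, bool]:
    images = np.asarray(images, dtype=np.float32)
    single = images.ndim == 3
    if single:
        images = images[None]
    if images.ndim != 4 or images.shape[3] != 3:
        raise ValueError(f"expected (H,W,3) or (N,H,W,3), got {images.shape}")
    return images.transpose(0, 3, 1, 2), single


class ResNetGenerator(Module):
    DOWN_FACTOR = 4  # two stride-2 stages

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        w = spec.base_width
        self.net = Sequential(
            Conv2d(3, w, 7, pad=3, pad_mode="reflect", rng=rng),
            InstanceNorm(), ReLU(),
            Conv2d(w, 2 * w, 3, stride=2, pad=1, rng=rng),
            InstanceNorm(), ReLU(),
            Conv2d(2 * w, 4 * w, 3, stride=2, pad=1, rng=rng),
            InstanceNorm(), ReLU(),
            *[ResidualBlock(4 * w, rng) for _ in range(spec.n_res_blocks)],
            UpsampleNearest2(),
            Conv2d(4 * w, 2 * w, 3, pad=1, rng=rng),
            InstanceNorm(), ReLU(),
            UpsampleNearest2(),
            Conv2d(2 * w, w, 3, pad=1, rng=rng),
            InstanceNorm(), ReLU(),
            Conv2d(w, 3, 7, pad=3, pad_mode="reflect", rng=rng),
            Tanh(),
        )

    def forward(self, x: Tensor) -> Tensor:
        """[-1,1] NCHW tensor in, [-1,1] NCHW tensor out, same shape."""
        return self.net(x)

    def translate(self, images: np.ndarray) -> np.ndarray:
        """Unit-range ndarray in, unit-range ndarray out (inference)."""
        nchw, single = _to_nchw(images)
        n, c, h, w = nchw.shape
        f = self.DOWN_FACTOR
        pad_h = (-h) % f
        pad_w = (-w) % f
        x = nchw * 2.0 - 1.0
        if pad_h or pad_w:
            logger.info("reflect-padding %dx%d input to a multiple of %d", h, w, f)
            x = np.pad(x, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)),
                       mode="reflect")
        out = self.forward(Tensor(x)).data
        out = out[:, :, :h, :w]
        out01 = (out + 1.0) / 2.0
        out01 = out01.transpose(0, 2, 3, 1)
        return out01[0] if single else out01

    def __call__(self, images: np.ndarray) -> np.ndarray:
        return self.translate(images)


class PatchDiscriminator(Module):
    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        w = spec.base_width
        modules: list[Module] = [Conv2d(3, w, 4, stride=2, pad=1, rng=rng),
                                 LeakyReLU(0.2)]
        ch = w
        for _ in range(spec.n_layers - 1):
            modules += [Conv2d(ch, 2 * ch, 4, stride=2, pad=1, rng=rng),
                        InstanceNorm(), LeakyReLU(0.2)]
            ch *= 2
        modules += [Conv2d(ch, 2 * ch, 4, stride=1, pad=1, rng=rng),
                    InstanceNorm(), LeakyReLU(0.2),
                    Conv2d(2 * ch, 1, 4, stride=1, pad=1, rng=rng)]
        self.net = Sequential(*modules)

    @property
    def receptive_field(self) -> int:
        rf, jump = 1, 1
        for stride in [2] * self.spec.n_layers + [1, 1]:
            rf += 3 * jump  # kernel 4 -> (k-1)*jump
            jump *= stride
        return rf

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)

    def score(self, images: np.ndarray) -> np.ndarray:
        """Unit-range ndarray in, patch-score grid out."""
        nchw, single = _to_nchw(images)
        h, w = nchw.shape[2], nchw.shape[3]
        rf = self.receptive_field
        if min(h, w) < rf:
            raise ValueError(
                f"input {h}x{w} is smaller than one receptive field ({rf}); "
                f"use a shallower discriminator or larger images")
        out = self.forward(Tensor(nchw * 2.0 - 1.0)).data[:, 0]
        return out[0] if single else out

    def __call__(self, images: np.ndarray) -> np.ndarray:
        return self.score(images)


def build_generator(spec: GeneratorSpec = GeneratorSpec(),
                    seed: int | None = None) -> ResNetGenerator:
    """Construct a generator with reproducible N(0, 0.02) initialisation."""
    return ResNetGenerator(spec, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec = DiscriminatorSpec(),
                        seed: int | None = None) -> PatchDiscriminator:
    return PatchDiscriminator(spec, np.random.default_rng(seed))


# ---------------------------------------------------------------------
# checkpoints: npz weights + JSON sidecar with specs and a content hash
# ---------------------------------------------------------------------

def _weights_dict(nets: dict[str, Module]) -> dict[str, np.ndarray]:
    out = {}
    for name, net in nets.items():
        for i, p in enumerate(net.parameters()):
            out[f"{name}.{i}"] = p.data
    return out


def _hash_weights(weights: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(weights):
        h.update(key.encode())
        h.update(np.ascontiguousarray(weights[key]).tobytes())
    return h.hexdigest()


def save_checkpoint(path, nets: dict[str, Module],
                    specs: dict[str, object], extra: dict | None = None) -> Path:
    """Write weights (npz) plus a JSON sidecar with specs and weight hash."""
    path = Path(path)
    weights = _weights_dict(nets)
    np.savez(path, **weights)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "specs": {k: asdict(v) for k, v in specs.items()},
        "weights_sha256": _hash_weights(weights),
        "extra": extra or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path) -> tuple[dict[str, Module], dict]:
    """Rebuild networks from a checkpoint; verifies the weight hash."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"checkpoint sidecar missing: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    with np.load(path) as npz:
        weights = {k: npz[k] for k in npz.files}
    got = _hash_weights(weights)
    want = sidecar["weights_sha256"]
    if got != want:
        raise ValueError(f"checkpoint {path} is corrupt: weight hash "
                         f"{got[:12]} != recorded {want[:12]}")
    nets: dict[str, Module] = {}
    for name, spec_dict in sidecar["specs"].items():
        if name.startswith("G") or name.startswith("F"):
            net: Module = build_generator(GeneratorSpec(**spec_dict), seed=0)
        else:
            net = build_discriminator(DiscriminatorSpec(**spec_dict), seed=0)
        for i, p in enumerate(net.parameters()):
            p.data = weights[f"{name}.{i}"].astype(np.float32)
        nets[name] = net
    return nets, sidecar
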