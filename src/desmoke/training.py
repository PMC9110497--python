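"""Two-domain unpaired training loop.

One training step performs a generator update — least-squares adversarial
terms for both mappings, the two-way cycle penalty, and the inter-channel
and dark-channel terms on the generated images — followed by one
least-squares update of each discriminator against real samples and a
history pool of previously generated fakes.

The learning-rate schedule holds ``lr0`` constant for ``epochs_const``
epochs, then decays linearly to exactly 0 over ``epochs_decay`` epochs.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import image_core
from .losses import LossBreakdown, LossWeights, TranslationDirection, total_objective
from .networks import (DiscriminatorSpec, GeneratorSpec, build_discriminator,
                       build_generator, load_checkpoint, save_checkpoint)
from .nn import autograd as ag
from .nn import functional as F
from .nn.autograd import Tensor
from .nn.optim import Adam

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainState", "lr_at_epoch", "train_step", "fit",
           "translate", "ImagePool"]


@dataclass
class TrainConfig:
    lr0: float = 0.002
    epochs_const: int = 50
    epochs_decay: int = 50
    batch_size: int = 4
    crop: int = 256
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    pool_size: int = 50
    dc_patch: int = 7
    dc_trim: float = 0.01
    dc_include_hazy_term: bool = True
    gen_spec: GeneratorSpec = field(default_factory=GeneratorSpec)
    disc_spec: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    checkpoint_every: int = 1

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.epochs_const < 0 or self.epochs_decay < 1:
            raise ValueError("epoch counts invalid")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Scheduled learning rate: constant, then linear decay to exactly 0.

    Continuous at the boundary; returns 0 at epoch == total (the step after
    the final training epoch).
    """
    total = cfg.epochs_const + cfg.epochs_decay
    if epoch < 0 or epoch > total:
        raise ValueError(f"epoch {epoch} outside schedule [0, {total}]")
    if epoch < cfg.epochs_const:
        return cfg.lr0
    return cfg.lr0 * (total - epoch) / cfg.epochs_decay


class ImagePool:
    """History buffer of generated images for discriminator updates.

    With probability 1/2 a query swaps the incoming fake for a stored one,
    decoupling the discriminator from the generator's most recent output.
    """

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self._store: list[np.ndarray] = []

    def query(self, batch: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return batch
        out = []
        for img in batch:
            if len(self._store) < self.size:
                self._store.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                j = int(self.rng.integers(len(self._store)))
                out.append(self._store[j].copy())
                self._store[j] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


class TrainState:
    """Networks, optimisers, fake-image pools and RNG for one run."""

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        seed = cfg.seed
        self.G = build_generator(cfg.gen_spec, seed=seed)          # clear -> hazy
        self.F = build_generator(cfg.gen_spec, seed=seed + 1)      # hazy -> clear
        self.D_X = build_discriminator(cfg.disc_spec, seed=seed + 2)  # judges clear
        self.D_Y = build_discriminator(cfg.disc_spec, seed=seed + 3)  # judges hazy
        lr = cfg.lr0
        self.opt_g = Adam(self.G.parameters() + self.F.parameters(), lr)
        self.opt_dx = Adam(self.D_X.parameters(), lr)
        self.opt_dy = Adam(self.D_Y.parameters(), lr)
        self.rng = np.random.default_rng(seed + 4)
        self.pool_x = ImagePool(cfg.pool_size, self.rng)
        self.pool_y = ImagePool(cfg.pool_size, self.rng)

    def set_lr(self, lr: float) -> None:
        for opt in (self.opt_g, self.opt_dx, self.opt_dy):
            opt.lr = lr


def _nchw(batch: np.ndarray) -> np.ndarray:
    batch = np.asarray(batch, dtype=np.float32)
    if batch.ndim != 4 or batch.shape[3] != 3:
        raise ValueError(f"batch must be (N,H,W,3), got {batch.shape}")
    return batch.transpose(0, 3, 1, 2)


def train_step(state: TrainState, batch_clear: np.ndarray,
               batch_hazy: np.ndarray) -> LossBreakdown:
    """One generator update and one update per discriminator.

    Returns the generator-side loss breakdown evaluated at the pre-update
    parameters.  Raises on a non-finite loss.
    """
    cfg = state.cfg
    w = cfg.weights
    x01 = Tensor(_nchw(batch_clear))          # clear domain, [0,1]
    y01 = Tensor(_nchw(batch_hazy))           # hazy domain, [0,1]
    x = ag.affine(x01, 2.0, -1.0)
    y = ag.affine(y01, 2.0, -1.0)

    # ---- generator update --------------------------------------------
    fake_y = state.G.forward(x)               # G(x): fake hazy, [-1,1]
    fake_x = state.F.forward(y)               # F(y): fake clear
    rec_x = state.F.forward(fake_y)
    rec_y = state.G.forward(fake_x)
    fake_y01 = ag.affine(fake_y, 0.5, 0.5)
    fake_x01 = ag.affine(fake_x, 0.5, 0.5)

    adv_g = F.lsgan_loss(state.D_Y.forward(fake_y), 1.0)
    adv_f = F.lsgan_loss(state.D_X.forward(fake_x), 1.0)
    cyc = ag.add(F.l1_loss(ag.affine(rec_x, 0.5, 0.5), x01),
                 F.l1_loss(ag.affine(rec_y, 0.5, 0.5), y01))
    ic = F.ic_loss(fake_y01, fake_x01)
    dc = F.dc_loss(fake_y01, fake_x01, patch=cfg.dc_patch,
                   trim_frac=cfg.dc_trim,
                   include_hazy_term=cfg.dc_include_hazy_term)

    total = ag.add(ag.add(adv_g, adv_f), ag.mul(cyc, w.lambda_cyc))
    if w.alpha:
        total = ag.add(total, ag.mul(ic, w.alpha))
    if w.beta:
        total = ag.add(total, ag.mul(dc, w.beta))

    breakdown = total_objective(adv_g.item(), adv_f.item(), cyc.item(),
                                ic.item(), dc.item(), w)
    if not np.isfinite(breakdown.total):
        raise FloatingPointError("non-finite generator loss; see last "
                                 "checkpoint for a recoverable state")

    state.opt_g.zero_grad()
    total.backward()
    state.opt_g.step()

    # ---- discriminator updates (history pool, detached fakes) --------
    for disc, opt, real01, fake, pool in (
            (state.D_Y, state.opt_dy, y01, fake_y, state.pool_y),
            (state.D_X, state.opt_dx, x01, fake_x, state.pool_x)):
        pooled = pool.query((fake.data + 1.0) / 2.0)
        real_t = ag.affine(Tensor(real01.data), 2.0, -1.0)
        fake_t = Tensor(pooled.astype(np.float32) * 2.0 - 1.0)
        loss_d = ag.mul(ag.add(F.lsgan_loss(disc.forward(real_t), 1.0),
                               F.lsgan_loss(disc.forward(fake_t), 0.0)), 0.5)
        opt.zero_grad()
        loss_d.backward()
        opt.step()

    return breakdown


def _load_domain(root: Path, sub: str) -> list[np.ndarray]:
    d = root / sub
    if not d.is_dir():
        raise FileNotFoundError(f"dataset directory missing: {d}")
    files = sorted(p for p in d.iterdir()
                   if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
    if not files:
        raise ValueError(f"no images found in {d}")
    return [image_core.load_image(p) for p in files]


def fit(cfg: TrainConfig, data_root, out_dir) -> dict:
    """Train on ``data_root/trainA`` (clear) and ``trainB`` (hazy).

    Writes per-epoch checkpoints, a CSV log of per-epoch mean losses and a
    JSON run manifest.  Returns a dict with the final checkpoint path, the
    log path and the manifest path.
    """
    data_root, out_dir = Path(data_root), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clear = _load_domain(data_root, "trainA")
    hazy = _load_domain(data_root, "trainB")

    state = TrainState(cfg)
    rng = np.random.default_rng(cfg.seed + 5)
    total_epochs = cfg.epochs_const + cfg.epochs_decay
    log_path = out_dir / "train_log.csv"
    ckpt_path = None
    with open(log_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "lr", "adv_g", "adv_f", "cycle", "ic",
                         "dc", "total"])
        for epoch in range(total_epochs):
            lr = lr_at_epoch(cfg, epoch)
            state.set_lr(lr)
            order_c = rng.permutation(len(clear))
            order_h = rng.permutation(len(hazy))
            n_batches = min(len(clear), len(hazy)) // cfg.batch_size
            if n_batches == 0:
                raise ValueError("fewer images than one batch per domain")
            sums = np.zeros(6)
            for b in range(n_batches):
                ic_idx = order_c[b * cfg.batch_size:(b + 1) * cfg.batch_size]
                ih_idx = order_h[b * cfg.batch_size:(b + 1) * cfg.batch_size]
                bc = np.stack([_maybe_crop(clear[i], cfg.crop, rng) for i in ic_idx])
                bh = np.stack([_maybe_crop(hazy[i], cfg.crop, rng) for i in ih_idx])
                br = train_step(state, bc, bh)
                sums += [br.adversarial_g, br.adversarial_f, br.cycle,
                         br.ic, br.dc, br.total]
            means = sums / n_batches
            writer.writerow([epoch, f"{lr:.6g}"] + [f"{v:.6g}" for v in means])
            fh.flush()
            if (epoch + 1) % cfg.checkpoint_every == 0 or epoch == total_epochs - 1:
                ckpt_path = save_checkpoint(
                    out_dir / f"ckpt_epoch_{epoch:03d}.npz",
                    {"G": state.G, "F": state.F,
                     "D_X": state.D_X, "D_Y": state.D_Y},
                    {"G": cfg.gen_spec, "F": cfg.gen_spec,
                     "D_X": cfg.disc_spec, "D_Y": cfg.disc_spec},
                    extra={"epoch": epoch, "lr": lr})
            logger.info("epoch %d lr %.5f total %.4f", epoch, lr, means[5])

    manifest_path = out_dir / "run_manifest.json"
    cfg_dict = asdict(cfg)
    manifest_path.write_text(json.dumps(
        {"config": cfg_dict, "seed": cfg.seed, "epochs": total_epochs,
         "final_checkpoint": str(ckpt_path)}, indent=2, default=str))
    return {"checkpoint": ckpt_path, "log": log_path, "manifest": manifest_path}


def _maybe_crop(img: np.ndarray, crop: int, rng: np.random.Generator) -> np.ndarray:
    if crop and crop < min(img.shape[0], img.shape[1]):
        return image_core.random_crop(img, crop, rng)
    return img


def translate(checkpoint, img: np.ndarray,
              direction: TranslationDirection) -> np.ndarray:
    """Apply a trained mapping to one image at full resolution.

    ``hazy_to_clear`` applies F (desmoking); ``clear_to_hazy`` applies G.
    Deterministic: the same checkpoint and input give the same output.
    """
    nets, _ = load_checkpoint(checkpoint)
    net = nets["F"] if direction is TranslationDirection.HAZY_TO_CLEAR else nets["G"]
    return net.translate(img)
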