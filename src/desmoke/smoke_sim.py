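"""Synthetic fixtures: tissue-like frames and scattering-model smoke.

Smoke is rendered with the atmospheric scattering model

    I(x) = J(x) * t(x) + A * (1 - t(x)),

where J is the clear scene, A the (near-white) atmospheric light and t the
per-pixel transmission.  Transmission fields are t = exp(-density * n(x))
with n a positive, spatially smooth noise field of unit mean, so the mean
optical thickness -mean(log t) equals the requested density.  Partial smoke
restricts the field to a random mask covering a requested area fraction.

Clear frames are procedural phantoms: multi-octave value noise mapped into a
reddish tissue gamut, with specular highlights and a dark vignette — giving
the low dark channel and high inter-channel discrepancy that real
smoke-free laparoscopic frames exhibit.  Hazy and clear domains are built
from disjoint phantoms, preserving the unpaired-training assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .image_core import save_image, validate_image

__all__ = ["SmokeParams", "GRADE_DENSITIES", "make_tissue_phantom",
           "make_transmission_field", "apply_scattering", "make_dataset"]

# densities per smoke grade, chosen so trimmed-mean dark channels of the
# three grades are well separated; recorded in every dataset manifest
GRADE_DENSITIES = {"light": 0.3, "medium": 0.8, "heavy": 1.8}


@dataclass(frozen=True)
class SmokeParams:
    atmos_light: tuple[float, float, float] = (0.96, 0.96, 0.98)
    density: float = 0.8
    heterogeneity: float = 0.6
    partial_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if not 0.0 <= self.partial_fraction <= 1.0:
            raise ValueError("partial_fraction must lie in [0, 1]")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be non-negative")


def _value_noise(size: int, rng: np.random.Generator, octaves: int = 4,
                 base_cells: int = 4) -> np.ndarray:
    """Multi-octave value noise, roughly zero-mean, unit-std."""
    out = np.zeros((size, size))
    amp = 1.0
    for o in range(octaves):
        cells = base_cells * 2 ** o + 1
        grid = rng.standard_normal((cells, cells))
        out += amp * _sk_resize(grid, (size, size), order=3, mode="edge",
                                anti_aliasing=False)
        amp *= 0.5
    out -= out.mean()
    sd = out.std()
    return out / sd if sd > 0 else out


def make_tissue_phantom(size: int, seed: int) -> np.ndarray:
    """Procedural smoke-free frame in a tissue-like colour gamut.

    Reddish textured base, correlated channel structure, specular spots and
    a dark vignette; deterministic in ``seed``.
    """
    if size < 32:
        raise ValueError("phantom size must be >= 32")
    rng = np.random.default_rng(seed)
    structure = _value_noise(size, rng)
    detail = _value_noise(size, rng, octaves=5, base_cells=8)

    def squash(a):
        return 1.0 / (1.0 + np.exp(-a))

    r = 0.45 + 0.30 * squash(1.2 * structure + 0.3 * detail)
    g = 0.10 + 0.22 * squash(1.0 * structure + 0.5 * detail - 0.4)
    b = 0.08 + 0.18 * squash(0.9 * structure + 0.6 * detail - 0.6)
    img = np.stack([r, g, b], axis=2)

    # dark vignette towards the corners (endoscope illumination falloff)
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    radius2 = (yy - 0.5) ** 2 + (xx - 0.5) ** 2
    img *= (1.0 - 0.75 * np.clip(radius2 / 0.5, 0, 1))[..., None]

    # a few small specular highlights (wet tissue reflections)
    n_spots = int(rng.integers(2, 6))
    spots = np.zeros((size, size))
    for _ in range(n_spots):
        cy, cx = rng.integers(0, size, 2)
        sigma = float(rng.uniform(size / 80, size / 40))
        d2 = (np.arange(size)[:, None] - cy) ** 2 + (np.arange(size)[None, :] - cx) ** 2
        spots += np.exp(-d2 / (2 * sigma ** 2))
    img = img + np.clip(spots, 0, 1)[..., None] * (1.0 - img)

    return np.clip(img, 0.0, 1.0)


def make_transmission_field(size: int, params: SmokeParams) -> np.ndarray:
    """Spatially varying transmission t = exp(-density * n(x)) in (0, 1].

    n(x) = exp(h*z - h^2/2) with z smooth unit-variance noise, so n has unit
    mean and -mean(log t) ~= density.  For partial smoke, t = 1 outside a
    random smooth mask covering ``partial_fraction`` of the frame.
    """
    rng = np.random.default_rng(params.seed)
    if params.density == 0:
        return np.ones((size, size))
    z = _value_noise(size, rng)
    h = params.heterogeneity
    n = np.exp(h * z - 0.5 * h * h)
    t = np.exp(-params.density * n)
    if params.partial_fraction < 1.0:
        # quantile threshold on a smooth field: covered area is exactly the
        # requested fraction, and the boundary follows the noise contours
        mask_field = _value_noise(size, rng, octaves=3)
        thresh = np.quantile(mask_field, 1.0 - params.partial_fraction)
        mask = (mask_field >= thresh).astype(float)
        t = 1.0 - mask * (1.0 - t)
    return np.clip(t, np.finfo(float).tiny, 1.0)


def apply_scattering(clear: np.ndarray, t: np.ndarray,
                     atmos_light) -> np.ndarray:
    """Blend a clear frame with atmospheric light: I = J*t + A*(1-t)."""
    clear = validate_image(clear)
    t = np.asarray(t, dtype=np.float64)
    if t.shape != clear.shape[:2]:
        raise ValueError(f"transmission {t.shape} does not match image "
                         f"{clear.shape[:2]}")
    a = np.asarray(atmos_light, dtype=np.float64).reshape(1, 1, 3)
    out = clear * t[..., None] + a * (1.0 - t[..., None])
    return np.clip(out, 0.0, 1.0)


def _grade_params(grade: str, seed: int) -> SmokeParams:
    if grade == "partial":
        return SmokeParams(density=GRADE_DENSITIES["medium"],
                           partial_fraction=0.5, seed=seed)
    return SmokeParams(density=GRADE_DENSITIES[grade], seed=seed)


def _allocate(n: int, grading: dict[str, float]) -> list[str]:
    """Largest-remainder allocation of n images to grades."""
    total = sum(grading.values())
    if total <= 0:
        raise ValueError("grading mixture must have positive mass")
    quotas = {g: n * frac / total for g, frac in grading.items()}
    counts = {g: int(q) for g, q in quotas.items()}
    left = n - sum(counts.values())
    for g in sorted(quotas, key=lambda g: quotas[g] - counts[g], reverse=True):
        if left == 0:
            break
        counts[g] += 1
        left -= 1
    out = []
    for g, c in counts.items():
        out.extend([g] * c)
    return out


def make_dataset(n_per_domain: int, size: int, grading: dict[str, float],
                 seed: int, out_dir) -> dict:
    """Write an unpaired two-domain dataset and its JSON manifest.

    Layout: trainA/testA clear phantoms, trainB/testB hazy frames built from
    *different* phantoms.  The manifest records per-image smoke parameters
    and ground-truth mean transmission.
    """
    if n_per_domain < 1:
        raise ValueError("n_per_domain must be >= 1")
    unknown = set(grading) - (set(GRADE_DENSITIES) | {"partial"})
    if unknown:
        raise ValueError(f"unknown smoke grades: {sorted(unknown)}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "size": size, "n_per_domain": n_per_domain,
                      "grading": grading, "grade_densities": GRADE_DENSITIES,
                      "images": []}
    for split in ("train", "test"):
        for domain in ("A", "B"):
            (out_dir / f"{split}{domain}").mkdir(exist_ok=True)
        grades = _allocate(n_per_domain, grading)
        rng.shuffle(grades)
        for i in range(n_per_domain):
            # clear domain
            seed_a = int(rng.integers(2 ** 31))
            clear = make_tissue_phantom(size, seed_a)
            path_a = out_dir / f"{split}A" / f"{split}A_{i:04d}.png"
            save_image(clear, path_a)
            manifest["images"].append(
                {"path": str(path_a.relative_to(out_dir)), "domain": "clear",
                 "phantom_seed": seed_a})
            # hazy domain: a different phantom, smoke applied
            seed_b = int(rng.integers(2 ** 31))
            params = _grade_params(grades[i], int(rng.integers(2 ** 31)))
            base = make_tissue_phantom(size, seed_b)
            t = make_transmission_field(size, params)
            hazy = apply_scattering(base, t, params.atmos_light)
            path_b = out_dir / f"{split}B" / f"{split}B_{i:04d}.png"
            save_image(hazy, path_b)
            manifest["images"].append(
                {"path": str(path_b.relative_to(out_dir)), "domain": "hazy",
                 "grade": grades[i], "phantom_seed": seed_b,
                 "density": params.density,
                 "partial_fraction": params.partial_fraction,
                 "smoke_seed": params.seed,
                 "mean_transmission": float(t.mean())})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
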