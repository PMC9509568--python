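"""Synthetic citrus-leaf fixtures: six lesion classes under field conditions.

The generator paints a green leaf-like background and overlays class-specific
lesion blobs (count, radius, colour and texture per class), then applies one
of four acquisition conditions: uniform sunlight (none), cloudy low light
(global luminance scaling), fog (an additive smooth white veil) or uneven
illumination (a linear gradient).  Two class pairs are deliberately similar
— small dark scar-like particles for the corynespora/fat-spot pair and
yellow-white raised pustules for the scab/canker pair — so the detail path
has genuinely confusable fine-grained structure to separate.

Everything is deterministic per (label, condition, seed).  The images are
cartoons of orchard photographs: they reproduce the statistical structure
the pipeline cares about (class-specific lesion morphology, illumination
degradations), not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import (LABELS, CONDITIONS, DatasetManifest,
                   largest_remainder_allocation)
from .image import RgbImage, as_pixels


@dataclass
class ClassParams:
    """Lesion descriptors for one class."""

    blob_count: tuple          # inclusive (lo, hi)
    radius: tuple              # pixels at 224, scaled to image size
    color: tuple               # RGB in [0, 1]
    texture_amplitude: float
    ring: bool = False         # darker halo around each blob (canker-like)


# Lesion morphology follows the diseases' verbal field descriptions: the
# corynespora/fat-spot pair shares dark-brown concave particles (differing in
# count and size), the scab/canker pair shares yellow-white convex pustules
# (canker adds a dark ring).
CLASS_PARAMS: dict = {
    "normal":      ClassParams((0, 0),  (0, 0),    (0.0, 0.0, 0.0),    0.00),
    "huanglong":   ClassParams((3, 5),  (22, 34),  (0.80, 0.74, 0.16), 0.06),
    "corynespora": ClassParams((8, 12), (4, 7),    (0.28, 0.16, 0.07), 0.05),
    "fat_spot":    ClassParams((2, 3),  (13, 19),  (0.50, 0.33, 0.11), 0.05),
    "scab":        ClassParams((10, 14), (3, 6),   (0.93, 0.89, 0.62), 0.04),
    "canker":      ClassParams((3, 5),  (9, 14),   (0.78, 0.70, 0.45), 0.04, ring=True),
}

#: aggregate acquisition-condition shares of the study distribution
DEFAULT_CONDITION_MIX = (2748 / 10100, 2096 / 10100, 3028 / 10100, 2228 / 10100)

LEAF_GREEN = np.array([0.18, 0.46, 0.16], dtype=np.float64)


@dataclass
class SyntheticSpec:
    n_per_class: int = 20
    image_size: tuple = (224, 224)
    class_params: dict = field(default_factory=lambda: dict(CLASS_PARAMS))
    condition_mix: tuple = DEFAULT_CONDITION_MIX
    seed: int = 0

    def __post_init__(self):
        mix = np.asarray(self.condition_mix, dtype=np.float64)
        if len(mix) != len(CONDITIONS) or (mix < 0).any():
            raise ValueError("condition_mix needs one nonnegative share per condition")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("condition_mix must sum to 1")
        if set(self.class_params) != set(LABELS):
            raise ValueError("class_params must cover exactly the six labels")


@dataclass
class NoiseSpec:
    kind: str = "gaussian"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("gaussian", "salt"):
            raise ValueError("noise kind must be 'gaussian' or 'salt'")
        if self.level < 0:
            raise ValueError("noise level must be nonnegative")
        if self.kind == "salt" and self.level > 1:
            raise ValueError("salt corruption probability must be <= 1")


def _smooth_field(rng: np.random.Generator, shape: tuple, coarse: int = 6) -> np.ndarray:
    """Smooth random field in [0, 1]: bilinear upsampling of coarse noise."""
    from .nn.ops import bilinear_matrix

    base = rng.random((coarse, coarse))
    ah = bilinear_matrix(coarse, shape[0]).astype(np.float64)
    aw = bilinear_matrix(coarse, shape[1]).astype(np.float64)
    return ah @ base @ aw.T


def generate_image(label: str, condition: str, class_params: dict | None = None,
                   seed: int = 0, image_size: tuple = (224, 224)) -> RgbImage:
    """One synthetic leaf image, deterministic per (label, condition, seed)."""
    if label not in LABELS:
        raise ValueError(f"unknown class label {label!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    params = (class_params or CLASS_PARAMS)[label]
    h, w = image_size
    scale = min(h, w) / 224.0
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(LABELS.index(label), CONDITIONS.index(condition))))

    # leaf background: green base, smooth mottling, vein stripes, fine grain
    img = np.empty((h, w, 3), dtype=np.float64)
    mottle = 0.10 * (_smooth_field(rng, (h, w)) - 0.5)
    yy, xx = np.mgrid[0:h, 0:w]
    veins = 0.02 * np.cos(2 * np.pi * (xx + 0.35 * yy) / max(8.0, 18.0 * scale))
    for c in range(3):
        img[:, :, c] = LEAF_GREEN[c] * (1.0 + mottle + veins)
    img += rng.normal(0.0, 0.012, img.shape)

    # lesions
    lo, hi = params.blob_count
    n_blobs = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    color = np.asarray(params.color, dtype=np.float64)
    for _ in range(n_blobs):
        r = float(rng.uniform(*params.radius)) * scale
        cy = float(rng.uniform(r, h - r))
        cx = float(rng.uniform(r, w - r))
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        core = 1.0 / (1.0 + np.exp((np.sqrt(d2) - r) / (0.25 * r + 0.5)))
        tex = 1.0 + params.texture_amplitude * np.sin(np.sqrt(d2) / max(0.8, 0.15 * r)
                                                      + rng.uniform(0, 2 * np.pi))
        blob_color = np.clip(color * tex[..., None], 0.0, 1.0)
        img = img * (1.0 - core[..., None]) + blob_color * core[..., None]
        if params.ring:
            ring = np.exp(-((np.sqrt(d2) - 1.25 * r) ** 2) / (2 * (0.18 * r + 0.4) ** 2))
            img *= 1.0 - 0.45 * ring[..., None]

    # acquisition condition
    if condition == "cloudy":
        img *= rng.uniform(0.3, 0.5)
    elif condition == "foggy":
        veil = 0.35 + 0.2 * _smooth_field(rng, (h, w))
        img = img * (1.0 - veil[..., None]) + veil[..., None]
    elif condition == "uneven":
        theta = rng.uniform(0, 2 * np.pi)
        ramp = (np.cos(theta) * xx / max(w - 1, 1)
                + np.sin(theta) * yy / max(h - 1, 1))
        ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-9)
        low = rng.uniform(0.25, 0.5)
        img *= (low + (1.0 - low) * ramp)[..., None]

    return RgbImage(np.clip(img, 0.0, 1.0).astype(np.float32))


def generate_dataset(spec: SyntheticSpec, out_dir) -> DatasetManifest:
    """Write ``n_per_class`` images per class plus a manifest CSV.

    Condition tags are allocated per class by largest-remainder rounding of
    ``condition_mix`` and assigned in a seeded shuffle; image seeds derive
    from the spec seed, so the whole dataset is reproducible byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label in LABELS:
        cond_counts = largest_remainder_allocation(spec.n_per_class, spec.condition_mix)
        conditions = np.repeat(CONDITIONS, cond_counts)
        conditions = conditions[rng.permutation(len(conditions))]
        for i, cond in enumerate(conditions):
            img_seed = int(rng.integers(0, 2 ** 31 - 1))
            img = generate_image(label, cond, spec.class_params, img_seed,
                                 spec.image_size)
            name = f"{label}_{i:04d}.png"
            img.save(out_dir / name)
            rows.append((name, label, cond, "unassigned", "source"))
    manifest = DatasetManifest.from_rows(rows)
    manifest.write_csv(out_dir / "manifest.csv")
    return manifest


def add_noise(image, spec: NoiseSpec) -> RgbImage:
    """Seeded test-time degradation: additive Gaussian or white salt impulses.

    Level 0 returns the input unchanged.  Gaussian noise is zero-mean with
    the given standard deviation on the [0, 1] scale, clipped; salt noise
    sets each pixel to pure white independently with the given probability.
    """
    px = as_pixels(image)
    if spec.level == 0:
        return RgbImage(px.copy())
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gaussian":
        out = np.clip(px + rng.normal(0.0, spec.level, px.shape), 0.0, 1.0)
    else:
        mask = rng.random(px.shape[:2]) < spec.level
        out = px.copy()
        out[mask] = 1.0
    return RgbImage(out.astype(np.float32))
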