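"""8-bit RGB raster I/O and the unit-interval working representation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass
class RgbImage:
    """H×W×3 image; storage is 8-bit, the working domain is float in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("RgbImage requires an H×W×3 array")
        if not np.isfinite(px).all():
            raise ValueError("RgbImage pixels must be finite")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_uint8(cls, arr: np.ndarray) -> "RgbImage":
        return cls(np.asarray(arr, dtype=np.float32) / 255.0)

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.pixels * 255.0), 0, 255).astype(np.uint8)

    @classmethod
    def load(cls, path) -> "RgbImage":
        with Image.open(path) as im:
            return cls.from_uint8(np.asarray(im.convert("RGB")))

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(self.to_uint8()).save(path)


def as_pixels(image) -> np.ndarray:
    """Accept an :class:`RgbImage` or a float H×W×3 array; return the array."""
    if isinstance(image, RgbImage):
        return image.pixels
    return np.asarray(image, dtype=np.float32)
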