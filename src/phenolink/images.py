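"""Raster image container with [0,1]-normalized pixels, plus PNG I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass
class ImageTensor:
    """Height x width x channels pixel array with intensities in [0,1]."""

    pixels: np.ndarray
    image_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be H x W x C")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError("pixel values must lie in [0, 1]")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def load_png(path: str | Path, image_id: str | None = None) -> ImageTensor:
    """Load a PNG, rescaling 8-bit intensities to [0,1]."""
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return ImageTensor(arr, image_id or path.stem)


def save_png(image: ImageTensor, path: str | Path) -> None:
    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(str(path))
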