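"""Image and dataset I/O.

Raw inputs are directories of PNG/JPEG kernel images, one subdirectory per
grade label; images are read as 8-bit RGB and scaled to [0, 1] floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["SeedImage", "load_image", "save_image", "load_dataset_dir"]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


@dataclass
class SeedImage:
    """An RGB kernel image in [0, 1] with an optional grade label."""

    pixels: np.ndarray  # (H, W, 3) floats in [0, 1]
    id: str
    label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        h, w = self.pixels.shape[:2]
        if h < 32 or w < 32:
            raise ValueError("kernel images must be at least 32 x 32")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")


def load_image(path, label: str | None = None) -> SeedImage:
    """Read a PNG/JPEG file as a [0, 1]-scaled RGB :class:`SeedImage`."""
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return SeedImage(pixels=arr, id=path.stem, label=label)


def save_image(image: SeedImage, path) -> None:
    """Write a :class:`SeedImage` as an 8-bit PNG/JPEG."""
    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def load_dataset_dir(root) -> list[SeedImage]:
    """Load a labeled dataset: one subdirectory of images per grade.

    Files are ordered deterministically (sorted grade, then sorted name).
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory {root} does not exist")
    images: list[SeedImage] = []
    for grade_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(grade_dir.iterdir()):
            if f.suffix.lower() in IMAGE_EXTENSIONS:
                img = load_image(f, label=grade_dir.name)
                img.id = f"{grade_dir.name}/{f.stem}"
                images.append(img)
    if not images:
        raise ValueError(f"no images found under {root}")
    return images
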