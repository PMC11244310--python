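"""Image and dataset I/O.

Images are held internally as float grids on the 0-255 scale; binary masks
as {0, 1} uint8 (on disk: 8-bit {0, 255}, which is unambiguous across
PNG/GIF dialects).  Coordinates are (row, col), 0-based.

Dataset layouts pair images with ground-truth and FOV files by filename
stem: ``flat``/``hrf`` match the full stem, ``drive`` matches the leading
``_``-separated token (``21_training`` ~ ``21_manual1`` ~ ``21_training_mask``),
``stare`` the leading ``.``-separated token (``im0001`` ~ ``im0001.ah``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".gif", ".jpg", ".jpeg", ".ppm")


def read_image(path) -> np.ndarray:
    """Read an image as float on the 0-255 scale (gray 2-D or RGB 3-D)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.bool_:
        return arr.astype(float) * 255.0
    if arr.dtype == np.uint16:
        logger.info("%s: 16-bit image rescaled to the 0-255 scale", path.name)
        return arr.astype(float) * (255.0 / 65535.0)
    return arr.astype(float)


def write_image(path, image) -> None:
    """Write a 0-255 image as 8-bit, clipping and rounding."""
    arr = np.clip(np.asarray(image, dtype=float), 0, 255)
    iio.imwrite(Path(path), np.round(arr).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Read a binary mask as {0, 1} uint8 (any nonzero pixel is foreground)."""
    arr = read_image(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > 127.5).astype(np.uint8) if arr.max() > 1 else (arr > 0).astype(np.uint8)


def write_mask(path, mask) -> None:
    """Write a {0, 1} mask to disk as 8-bit {0, 255}."""
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


@dataclass
class DatasetLayout:
    name: str = "flat"
    image_dir: Path | str = "."
    truth_dir: Path | str | None = None
    fov_dir: Path | str | None = None

    def __post_init__(self):
        if self.name not in ("drive", "stare", "hrf", "flat"):
            raise ValueError(f"unknown layout {self.name!r}")


@dataclass
class ImagePair:
    image: Path
    truth: Path | None
    fov: Path | None
    id: str


def _stem_key(stem: str, layout: str) -> str:
    if layout == "drive":
        return stem.split("_")[0]
    if layout == "stare":
        return stem.split(".")[0]
    return stem


def _index_dir(directory, layout: str) -> dict[str, Path]:
    index: dict[str, Path] = {}
    for p in sorted(Path(directory).iterdir()):
        if p.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        key = _stem_key(p.stem, layout)
        if key in index:
            raise ValueError(f"duplicate stem {key!r} in {directory}")
        index[key] = p
    return index


def discover_pairs(layout: DatasetLayout) -> list[ImagePair]:
    """Deterministic (lexicographic) list of image/truth/fov triples.

    Images without a matching truth or FOV file are included with the
    missing member set to None.
    """
    images = _index_dir(layout.image_dir, layout.name)
    if not images:
        raise ValueError(f"no images found in {layout.image_dir}")
    truths = _index_dir(layout.truth_dir, layout.name) if layout.truth_dir else {}
    fovs = _index_dir(layout.fov_dir, layout.name) if layout.fov_dir else {}
    pairs = []
    for key in sorted(images):
        pairs.append(
            ImagePair(
                image=images[key],
                truth=truths.get(key),
                fov=fovs.get(key),
                id=key,
            )
        )
    return pairs
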