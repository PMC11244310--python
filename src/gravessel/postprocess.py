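"""Morphological cleanup of the raw vessel mask.

Fixed order: disc-shaped closing (bridges 1-2 px vessel breaks), cavity
filling, then removal of connected components under ``min_component`` pixels
(strictly fewer — a 70-pixel component survives at the default of 70).

Cavity filling is bounded by default: only enclosed background regions
smaller than ``max_hole`` pixels are filled.  Vessel-interior cavities are
small; the large background regions enclosed by crossing vessel branches
are anatomy, not holes, and flooding them would wreck precision.  Set
``max_hole=None`` for unbounded border-connectivity filling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.morphology import closing, disk, remove_small_holes, remove_small_objects


@dataclass
class PostprocessConfig:
    disc_radius: int = 2
    min_component: int = 70
    connectivity: int = 8  # 8-connectivity suits thin diagonal vessels
    fill_holes: bool = True
    max_hole: int | None = 70  # fill only cavities below the significance scale

    def __post_init__(self):
        if self.disc_radius < 1 or self.min_component < 1:
            raise ValueError("disc_radius and min_component must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def close_mask(mask, config: PostprocessConfig | None = None) -> np.ndarray:
    """Binary closing (dilation then erosion) with a disc structuring element."""
    config = config or PostprocessConfig()
    return closing(_as_bool(mask), disk(config.disc_radius)).astype(np.uint8)


def fill_holes(mask, max_hole: int | None = None) -> np.ndarray:
    """Fill enclosed background regions (holes).

    With ``max_hole=None`` every background region not connected to the
    image border is filled; otherwise only holes of at most ``max_hole``
    pixels are.  Holes are tracked with 4-connectivity, the complement of
    the 8-connected foreground.
    """
    m = _as_bool(mask)
    if max_hole is None:
        return binary_fill_holes(m).astype(np.uint8)
    return remove_small_holes(m, max_size=max_hole, connectivity=1).astype(np.uint8)


def remove_small_components(mask, config: PostprocessConfig | None = None) -> np.ndarray:
    """Drop connected components with strictly fewer than min_component pixels."""
    config = config or PostprocessConfig()
    conn = 2 if config.connectivity == 8 else 1
    # max_size removes components <= its value; "fewer than N" keeps size N
    return remove_small_objects(
        _as_bool(mask), max_size=config.min_component - 1, connectivity=conn
    ).astype(np.uint8)


def postprocess_mask(mask, config: PostprocessConfig | None = None) -> np.ndarray:
    """close -> fill holes -> remove small components."""
    config = config or PostprocessConfig()
    out = close_mask(mask, config)
    if config.fill_holes:
        out = fill_holes(out, config.max_hole)
    return remove_small_components(out, config)
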