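"""Noise-Adaptive Discrimination Filtering via grey relational analysis (NADF-GRA).

Two stages. *Detection*: for every pixel, the nine grey relational
coefficients of its 3x3 window against the window median are ranked
ascending; the pixel is flagged as noise (0) when its own coefficient falls
among the three smallest, i.e. its intensity deviates most from the local
median — the signature of salt-and-pepper impulses.  The whole flag matrix is
computed from the original image in a single pass.

*Replacement*: pixels flagged normal are untouched.  A noise pixel is
replaced by the grey-relational weighted mean of the normal pixels among its
8 neighbors, with weights ``1/(1+|v - f_h|)`` against the current window
median ``v``; if every neighbor is noisy (a noise block), a 5x5 median takes
over.  Traversal is raster order (top-to-bottom, left-to-right) writing in
place, so repaired values feed the windows of later noise pixels and large
noise blocks heal progressively from their top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gra_core import CENTER, coefficient_field

_OFFSETS3 = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
_NEIGHBOR_OFFSETS = [o for o in _OFFSETS3 if o != (0, 0)]
_OFFSETS5 = [(di, dj) for di in (-2, -1, 0, 1, 2) for dj in (-2, -1, 0, 1, 2)]


@dataclass
class FilterConfig:
    """Window sizes and traversal policy for NADF-GRA.

    window / fallback_window are fixed at 3 and 5 by the method; border_mode
    controls how out-of-image neighbors are synthesized; inplace=False gives
    an out-of-place (two-pass) replacement for comparison, in which every
    noise pixel is repaired from the original intensities only.
    """

    window: int = 3
    fallback_window: int = 5
    border_mode: str = "replicate"
    inplace: bool = True

    def __post_init__(self):
        if self.window != 3 or self.fallback_window != 5:
            raise ValueError("window sizes are fixed at 3 (detection) and 5 (fallback)")
        if self.border_mode not in ("replicate", "reflect"):
            raise ValueError(f"unknown border_mode {self.border_mode!r}")


def _map_index(idx: int, n: int, mode: str) -> int:
    if 0 <= idx < n:
        return idx
    if mode == "replicate":
        return min(max(idx, 0), n - 1)
    # reflect without repeating the edge sample (numpy 'reflect')
    if idx < 0:
        return -idx
    return 2 * (n - 1) - idx


def detect_noise(image) -> np.ndarray:
    """Flag matrix: 0 = noise, 1 = normal, same shape as ``image``.

    Vectorized over the whole image; the center's ascending rank under the
    stable (value, window-position) order is computed by counting strictly
    smaller coefficients plus equal coefficients at earlier positions.
    """
    coeffs, _ = coefficient_field(image, reference="median")
    center = coeffs[..., CENTER]
    below = np.count_nonzero(coeffs < center[..., None], axis=-1)
    tied_before = np.count_nonzero(coeffs[..., :CENTER] == center[..., None], axis=-1)
    rank = below + tied_before + 1
    return (rank > 3).astype(np.uint8)


def replace_noise(image, flags, config: FilterConfig | None = None) -> np.ndarray:
    """Repair the pixels flagged 0, leaving flag-1 pixels bit-identical."""
    config = config or FilterConfig()
    img = np.asarray(image, dtype=float).copy()
    flags = np.asarray(flags)
    if img.shape != flags.shape:
        raise ValueError(f"image shape {img.shape} != flags shape {flags.shape}")
    src = img if config.inplace else np.asarray(image, dtype=float)
    M, N = img.shape
    mode = config.border_mode
    noise_rows, noise_cols = np.nonzero(flags == 0)
    # np.nonzero already yields raster (row-major) order
    for i, j in zip(noise_rows.tolist(), noise_cols.tolist()):
        vals = []
        normal_vals = []
        for di, dj in _OFFSETS3:
            r = _map_index(i + di, M, mode)
            c = _map_index(j + dj, N, mode)
            v = src[r, c]
            vals.append(v)
            if (di, dj) != (0, 0) and flags[r, c] == 1:
                normal_vals.append(v)
        if normal_vals:
            v = float(np.median(vals))
            f = np.array(normal_vals)
            g = 1.0 / (1.0 + np.abs(v - f))
            img[i, j] = float(np.dot(g, f) / g.sum())
        else:
            vals5 = [
                src[_map_index(i + di, M, mode), _map_index(j + dj, N, mode)]
                for di, dj in _OFFSETS5
            ]
            img[i, j] = float(np.median(vals5))
    return img


def nadf_gra(image, config: FilterConfig | None = None) -> np.ndarray:
    """Full filter: detect noise on the original image, then repair it."""
    flags = detect_noise(image)
    return replace_noise(image, flags, config)
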