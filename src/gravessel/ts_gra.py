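"""Threshold Segmentation via grey relational analysis (TS-GRA).

Edges carry local grey-level transitions, so the mean of a pixel's 3x3
window is taken as the reference sequence and the nine window intensities as
the comparison sequence.  The per-pixel grey relational degree

    gamma(i, j) = (1/9) * sum_u 1 / (1 + |mean - x_u|)

is 1 exactly on locally constant neighborhoods and drops toward 0 where an
edge crosses the window.  Pixels whose degree falls strictly below a
threshold theta — chosen between the map's minimum and maximum — are marked
as edge/vessel points.

The degree is invariant to a global additive intensity shift (the mean
shifts with the data), which makes the segmenter robust to slowly varying
illumination once the image has been vesselness-enhanced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .gra_core import coefficient_field

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    """Threshold policy for TS-GRA.

    threshold_mode:
        ``fixed``    — use ``theta`` as given (default, theta=0.1: on a
                       vesselness map rescaled to 0-255, vessel edges score
                       well below 0.1 while background texture stays above);
        ``fraction`` — theta = gmin + alpha * (gmax - gmin);
        ``otsu``     — histogram-bimodality split of the degree values.
    The selected theta is always clamped into [gmin, gmax].
    """

    threshold_mode: str = "fixed"
    theta: float = 0.1
    alpha: float = 0.5
    border_mode: str = "replicate"

    def __post_init__(self):
        if self.threshold_mode not in ("fixed", "fraction", "otsu"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.threshold_mode == "fixed" and not 0.0 < self.theta <= 1.0:
            raise ValueError("theta must lie in (0, 1]")


def degree_map(image) -> np.ndarray:
    """Per-pixel grey relational degree against the 3x3 window mean.

    Values in (0, 1]; equal to 1 iff the neighborhood is constant.  Borders
    are replicate-padded so the map has full image size.
    """
    coeffs, _ = coefficient_field(image, reference="mean")
    return coeffs.mean(axis=-1)


def select_threshold(degrees, config: SegmentationConfig | None = None) -> float:
    """Choose theta within [min, max] of the degree map per the configured mode."""
    config = config or SegmentationConfig()
    d = np.asarray(degrees, dtype=float)
    gmin, gmax = float(d.min()), float(d.max())
    if gmin == gmax:
        logger.warning("degenerate degree map (constant %g); returning it as theta", gmin)
        return gmin
    if config.threshold_mode == "fixed":
        theta = config.theta
    elif config.threshold_mode == "fraction":
        theta = gmin + config.alpha * (gmax - gmin)
    else:
        theta = float(threshold_otsu(d.ravel(), nbins=256))
    return float(min(max(theta, gmin), gmax))


def threshold_edges(degrees, theta: float) -> np.ndarray:
    """Binary mask: 1 exactly where degree < theta (strict), else 0."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    return (np.asarray(degrees, dtype=float) < theta).astype(np.uint8)


def ts_gra_segment(image, config: SegmentationConfig | None = None) -> np.ndarray:
    """degree_map -> select_threshold -> threshold_edges, composed."""
    config = config or SegmentationConfig()
    d = degree_map(image)
    theta = select_threshold(d, config)
    return threshold_edges(d, theta)
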