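"""End-to-end composition of the segmentation stages, with ablation switches.

Fixed stage order: green channel -> NADF-GRA (optional) -> CLAHE -> Frangi
vesselness -> TS-GRA thresholding -> morphological post-processing.  The
filter stage can be switched to ``none`` for ablation-style comparisons of
the noise filter's contribution; when a FOV mask is supplied the final mask
is zeroed outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enhancement import (
    EnhanceConfig,
    clahe,
    extend_beyond_fov,
    extract_green,
    frangi_vesselness,
)
from .nadf import FilterConfig, nadf_gra
from .postprocess import PostprocessConfig, postprocess_mask
from .ts_gra import SegmentationConfig, degree_map, select_threshold, threshold_edges

_FILTER_STAGES = ("nadf_gra", "none")
_SEGMENT_STAGES = ("ts_gra",)


@dataclass
class PipelineConfig:
    filter_stage: str = "nadf_gra"
    segment_stage: str = "ts_gra"
    filter: FilterConfig = field(default_factory=FilterConfig)
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    segment: SegmentationConfig = field(default_factory=SegmentationConfig)
    post: PostprocessConfig = field(default_factory=PostprocessConfig)

    def __post_init__(self):
        if self.filter_stage not in _FILTER_STAGES:
            raise ValueError(f"filter_stage must be one of {_FILTER_STAGES}")
        if self.segment_stage not in _SEGMENT_STAGES:
            raise ValueError(f"segment_stage must be one of {_SEGMENT_STAGES}")


def run_pipeline(image, fov=None, config: PipelineConfig | None = None):
    """Segment one fundus image; returns ``(mask, stages)``.

    ``stages`` maps stage names to their intermediate images: green,
    denoised, clahe, frangi, degree, theta, raw (pre-morphology mask) and
    mask.  Deterministic for fixed inputs and configuration.
    """
    config = config or PipelineConfig()
    stages: dict[str, np.ndarray | float] = {}
    g = extract_green(image)
    stages["green"] = g
    if config.filter_stage == "nadf_gra":
        g = nadf_gra(g, config.filter)
    stages["denoised"] = g
    if fov is not None:
        # kill the aperture rim before contrast/Hessian stages
        g = extend_beyond_fov(g, fov)
    c = clahe(g, config.enhance)
    stages["clahe"] = c
    f = frangi_vesselness(c, config.enhance)
    stages["frangi"] = f
    d = degree_map(f)
    stages["degree"] = d
    theta = select_threshold(d, config.segment)
    stages["theta"] = theta
    raw = threshold_edges(d, theta)
    if fov is not None:
        raw = (raw.astype(bool) & np.asarray(fov).astype(bool)).astype(np.uint8)
    stages["raw"] = raw
    mask = postprocess_mask(raw, config.post)
    if fov is not None:
        mask = (mask.astype(bool) & np.asarray(fov).astype(bool)).astype(np.uint8)
    stages["mask"] = mask
    return mask, stages
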