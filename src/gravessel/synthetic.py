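"""Deterministic synthetic fundus generator.

Emulates the structure the pipeline is built for: dark branching curvilinear
vessels with Gaussian cross-profiles on a brighter, smoothly varying
background inside a circular field of view, contaminated with additive
Gaussian noise and salt-and-pepper impulses, with pixel-aligned vessel
ground truth derived from the clean geometry only.

Vessel trees are grown as direction-persistent random walks that branch
stochastically and taper; each centerline point stamps a Gaussian intensity
profile whose half-width defines the ground-truth support.  Everything is a
pure function of the configuration (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class SynthConfig:
    size: tuple[int, int] = (256, 256)
    n_trees: int = 3
    branch_prob: float = 0.02  # per-step probability of spawning a branch
    vessel_width_range: tuple[float, float] = (3.0, 8.0)  # FWHM at the root, px
    vessel_contrast: float = 90.0  # intensity drop at the centerline
    background_level: float = 170.0
    background_gradient: float = 25.0  # amplitude of the smooth illumination field
    sp_density: float = 0.05
    gaussian_sigma: float = 5.0
    n_blobs: int = 0  # optional bright/dark pathology-like stressor blobs
    seed: int = 0

    def __post_init__(self):
        if self.size[0] < 16 or self.size[1] < 16:
            raise ValueError("size must be at least 16x16")
        if not 0.0 <= self.sp_density < 1.0:
            raise ValueError("sp_density must lie in [0, 1)")


@dataclass
class SyntheticSample:
    image: np.ndarray  # noisy observation, 0-255 float
    clean: np.ndarray  # pre-noise image
    truth: np.ndarray  # vessel ground truth {0,1}
    fov: np.ndarray  # circular field of view {0,1}
    meta: dict = field(default_factory=dict)


def add_salt_pepper(image, density: float, seed) -> np.ndarray:
    """Drive a seeded random fraction of pixels to 0 or 255 (equal odds)."""
    if not 0.0 <= density < 1.0:
        raise ValueError("density must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.asarray(image, dtype=float).copy()
    hit = rng.random(img.shape) < density
    salt = rng.random(img.shape) < 0.5
    img[hit & salt] = 255.0
    img[hit & ~salt] = 0.0
    return img


def _background(shape, level, amplitude, rng):
    """Smooth illumination: a tilted plane plus one broad radial falloff."""
    M, N = shape
    yy, xx = np.mgrid[0:M, 0:N]
    u, v = yy / (M - 1) - 0.5, xx / (N - 1) - 0.5
    tilt = rng.uniform(-1, 1, size=2)
    cy, cx = rng.uniform(-0.25, 0.25, size=2)
    radial = np.exp(-((u - cy) ** 2 + (v - cx) ** 2) / 0.18)
    bg = level + amplitude * (0.5 * (tilt[0] * u + tilt[1] * v) + radial - 0.5)
    return bg


def _grow_tree(start, direction, width, fov, rng, branch_prob, max_steps):
    """Direction-persistent random walk; returns centerline (y, x, width) points."""
    points = []
    stack = [(np.array(start, dtype=float), float(direction), float(width), 0)]
    M, N = fov.shape
    while stack:
        pos, ang, w, depth = stack.pop()
        steps = 0
        while steps < max_steps and w >= 1.0:
            iy, ix = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= iy < M and 0 <= ix < N) or not fov[iy, ix]:
                break
            points.append((pos[0], pos[1], w))
            ang += rng.normal(0.0, 0.12)
            pos = pos + np.array([np.sin(ang), np.cos(ang)])
            w *= 0.995
            steps += 1
            if depth < 3 and rng.random() < branch_prob:
                side = 1.0 if rng.random() < 0.5 else -1.0
                stack.append(
                    (pos.copy(), ang + side * rng.uniform(0.4, 0.9), w * 0.75, depth + 1)
                )
    return points


#: a Gaussian falls to half its peak at FWHM/2 = sigma * sqrt(2 ln 2)
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _rasterize(points, shape):
    """Max-combine Gaussian cross-profiles stamped at each centerline point.

    The nominal width is the profile's full width at half maximum, so the
    ground truth — the region above half the centerline drop — is exactly
    the nominal width around the centerline.
    """
    M, N = shape
    V = np.zeros(shape)
    for y, x, w in points:
        sigma = max(w / _FWHM_PER_SIGMA, 0.5)
        r = int(np.ceil(3 * sigma))
        y0, y1 = max(0, int(y) - r), min(M, int(y) + r + 1)
        x0, x1 = max(0, int(x) - r), min(N, int(x) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - y) ** 2 + (xx - x) ** 2
        np.maximum(V[y0:y1, x0:x1], np.exp(-d2 / (2 * sigma**2)), out=V[y0:y1, x0:x1])
    return V


def generate(config: SynthConfig | None = None) -> SyntheticSample:
    """Generate one sample; bit-identical for identical configurations."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    M, N = config.size
    yy, xx = np.mgrid[0:M, 0:N]
    cy, cx = (M - 1) / 2.0, (N - 1) / 2.0
    radius = 0.48 * min(M, N)
    fov = (((yy - cy) ** 2 + (xx - cx) ** 2) <= radius**2).astype(np.uint8)

    bg = _background((M, N), config.background_level, config.background_gradient, rng)

    points = []
    for _ in range(config.n_trees):
        # roots sit on the FOV rim and grow inward
        theta = rng.uniform(0, 2 * np.pi)
        start = (cy + 0.92 * radius * np.sin(theta), cx + 0.92 * radius * np.cos(theta))
        inward = np.arctan2(cy - start[0], cx - start[1])
        direction = inward + rng.normal(0.0, 0.3)
        width = rng.uniform(*config.vessel_width_range)
        points.extend(
            _grow_tree(
                start, direction, width, fov.astype(bool), rng,
                config.branch_prob, max_steps=int(0.4 * min(M, N)),
            )
        )
    V = _rasterize(points, (M, N))
    truth = ((V >= 0.5) & fov.astype(bool)).astype(np.uint8)

    clean = bg - config.vessel_contrast * V
    for _ in range(config.n_blobs):
        by, bx = rng.uniform(0.2, 0.8) * M, rng.uniform(0.2, 0.8) * N
        br = rng.uniform(4, 12)
        amp = rng.choice([-1, 1]) * rng.uniform(20, 50)
        clean += amp * np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2) / (2 * br**2)))
    clean = np.where(fov.astype(bool), clean, 8.0)
    clean = np.clip(clean, 0.0, 255.0)

    image = clean.copy()
    if config.gaussian_sigma > 0:
        image = np.clip(image + rng.normal(0.0, config.gaussian_sigma, clean.shape), 0, 255)
    if config.sp_density > 0:
        image = add_salt_pepper(image, config.sp_density, rng)

    meta = asdict(config)
    return SyntheticSample(image=image, clean=clean, truth=truth, fov=fov, meta=meta)
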