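"""Seeded synthetic fundus images with ground-truth vessel masks.

Real fundus photographs show a dark reddish, mildly textured circular field
of view on a black frame, threaded by low-contrast curvilinear vessel trees;
in a typical 447x447 frame the background:vessel pixel ratio is near 9:1.
This module emulates exactly those properties — and nothing more (no optic
disc, fovea, or lesions) — so that the full segmentation pipeline can run
without downloading clinical data.

Vessel trees are grown as biased random walks: stems start near the center,
walk outward with small heading noise, occasionally branch at a random
angle, and taper in stroke width; each step stamps a disk of the current
width.  Trees are added until the vessel fraction of the frame enters a
configured band (default 5-15%, bracketing the real-image ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk

from .augment import SamplePair

__all__ = ["SynthParams", "generate_vessel_tree", "render_fundus", "generate_dataset"]


@dataclass(frozen=True)
class SynthParams:
    image_size: int = 128
    n_trees: int = 3                      # minimum stems grown per attempt
    branch_prob: float = 0.02             # per-step branching probability
    width_range: tuple[float, float] = (1, 2.5)  # stroke radius, stem -> capillary
    vessel_contrast: float = 0.35         # fractional darkening of vessel pixels
    noise_sd: float = 0.03                # additive Gaussian noise, 0-1 scale
    fov_radius: float = 0.95              # fraction of the half-size
    fraction_band: tuple[float, float] = (0.05, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_range[0] < 1 or self.width_range[1] < self.width_range[0]:
            raise ValueError("width_range must be >= 1 px and ordered")
        if not 0 <= self.vessel_contrast < 1:
            raise ValueError("vessel_contrast must lie in [0, 1)")
        lo, hi = self.fraction_band
        if not 0 < lo < hi < 1:
            raise ValueError("infeasible vessel-fraction band")


def _walk(mask, rng, params, start, heading, width, fov_center, fov_r, depth=0):
    """Grow one vessel branch; recursively spawns children."""
    size = params.image_size
    pos = np.array(start, dtype=float)
    w = float(width)
    taper = rng.uniform(0.985, 0.995)
    max_steps = size * 2
    hi = params.fraction_band[1]
    for step in range(max_steps):
        r, c = pos
        if (r - fov_center) ** 2 + (c - fov_center) ** 2 > fov_r**2:
            break
        if step % 32 == 0 and mask.mean() >= hi:
            break
        rr, cc = draw_disk((r, c), max(w, 1.0), shape=mask.shape)
        mask[rr, cc] = 1
        heading += rng.normal(0.0, 0.12)
        pos += np.array([math.sin(heading), math.cos(heading)])
        w *= taper
        if w < 0.5:
            break
        if depth < 3 and rng.random() < params.branch_prob:
            child_heading = heading + rng.choice([-1, 1]) * rng.uniform(0.4, 1.0)
            _walk(mask, rng, params, pos.copy(), child_heading,
                  max(w * rng.uniform(0.6, 0.9), 1.0), fov_center, fov_r, depth + 1)


def _grow(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    size = params.image_size
    mask = np.zeros((size, size), dtype=np.uint8)
    center = size / 2
    fov_r = params.fov_radius * size / 2
    lo, hi = params.fraction_band
    mid = 0.5 * (lo + hi)
    stems = 0
    # sprout thin stems until the mid-band fraction is reached (or give up)
    while stems < params.n_trees or mask.mean() < mid:
        if stems >= 40 or mask.mean() >= hi:
            break
        theta = rng.uniform(0, 2 * math.pi)
        start = (
            center + 0.15 * fov_r * math.sin(theta) * rng.uniform(0, 1),
            center + 0.15 * fov_r * math.cos(theta) * rng.uniform(0, 1),
        )
        width = rng.uniform(*params.width_range)
        _walk(mask, rng, params, start, theta, width, center, fov_r)
        stems += 1
    return mask


def generate_vessel_tree(params: SynthParams) -> np.ndarray:
    """Binary vessel mask with fraction inside ``params.fraction_band``.

    Deterministic for a fixed seed; retries with derived sub-seeds if an
    attempt lands outside the band, and raises after repeated failure.
    """
    lo, hi = params.fraction_band
    for attempt in range(20):
        rng = np.random.default_rng(
            np.random.SeedSequence((params.seed, attempt))
        )
        mask = _grow(params, rng)
        if lo <= mask.mean() <= hi:
            return mask
    raise RuntimeError(
        f"could not reach vessel fraction in [{lo}, {hi}] "
        f"with the given parameters (last attempt: {mask.mean():.3f})"
    )


def render_fundus(mask: np.ndarray, params: SynthParams) -> np.ndarray:
    """RGB fundus-like rendering of a vessel mask (uint8).

    Dark reddish textured disc, vessels darkened by ``vessel_contrast``,
    additive Gaussian noise, black outside the circular field of view.
    """
    size = mask.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 2**16 + 1)))
    yy, xx = np.mgrid[0:size, 0:size]
    center = size / 2
    fov_r = params.fov_radius * size / 2
    fov = (yy - center) ** 2 + (xx - center) ** 2 <= fov_r**2

    texture = gaussian_filter(rng.normal(0, 1, (size, size)), sigma=size / 16)
    texture = 1.0 + 0.15 * texture / max(np.abs(texture).max(), 1e-9)
    base = np.array([0.62, 0.30, 0.16])  # dark reddish retina tone
    img = base[None, None, :] * texture[:, :, None]
    img = img * (1.0 - params.vessel_contrast * mask[:, :, None])
    if params.noise_sd > 0:
        img = img + rng.normal(0, params.noise_sd, img.shape)
    img *= fov[:, :, None]
    return (img.clip(0, 1) * 255).round().astype(np.uint8)


def generate_dataset(n: int, params: SynthParams | None = None) -> list[SamplePair]:
    """n seeded image/mask pairs with disjoint per-pair sub-seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or SynthParams()
    pairs = []
    for i in range(n):
        p = replace(params, seed=int(np.random.SeedSequence((params.seed, i)).generate_state(1)[0] % (2**31)))
        mask = generate_vessel_tree(p)
        image = render_fundus(mask, p)
        pairs.append(SamplePair(image, mask, provenance=f"synthetic[{params.seed}:{i}]"))
    return pairs
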