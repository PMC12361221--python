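"""Seeded synthetic leaf/lesion scene generator.

Renders the structural features of field photographs of diseased leaves:
overlapping leaf-shaped blobs (smooth radial-Fourier closed curves) in
textured green over a soil-textured background, small irregular dark lesion
spots inside leaves (possibly adjacent or merging), a linear illumination
gradient and bright raindrop-like specular discs.  The returned mask is
exact by construction: 0 background, 1 leaf, 2 disease.

Determinism: the same :class:`SceneSpec` (including seed) always renders a
pixel-identical sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw

from .data import Sample


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    seed: int = 0
    size: int = 512
    n_leaves: int = 3
    overlap_fraction: float = 0.35       # how close leaf centres may sit
    lesion_density: float = 3.0          # mean lesions per leaf (Poisson)
    lesion_radius_px: tuple[float, float] = (8.0, 24.0)
    lighting_gradient: float = 0.35      # relative strength, 0 disables
    raindrop_count: int = 2
    max_lesion_fraction: float = 0.6     # cap on lesion area per leaf

    def __post_init__(self):
        if self.n_leaves < 0 or self.raindrop_count < 0 or self.lesion_density < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")


def _blob_mask(size: int, cy: float, cx: float, radius: float,
               rng: np.random.Generator, wobble: float = 0.25,
               n_harmonics: int = 5) -> np.ndarray:
    """Smooth closed curve: radius perturbed by random low-order harmonics."""
    theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
    r = np.ones_like(theta)
    for k in range(2, 2 + n_harmonics):
        amp = wobble * rng.uniform(0, 1) / k
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.3, None) * radius
    rows = cy + r * np.sin(theta)
    cols = cx + r * np.cos(theta)
    rr, cc = draw.polygon(rows, cols, shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    return mask


def _texture(size: int, rng: np.random.Generator, scale: float, strength: float) -> np.ndarray:
    noise = rng.normal(0, 1, (size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=scale)
    smooth /= max(np.abs(smooth).max(), 1e-9)
    return 1.0 + strength * smooth


def render_lesions(spec: SceneSpec) -> list[np.ndarray]:
    """Individual lesion footprints (booleans), before leaf clipping.

    Re-renders exactly the lesion stamps :func:`generate_scene` uses, so the
    scene's class-2 pixels can be checked against their union with the
    visible leaf area.
    """
    _, _, lesions, _ = _layout(spec)
    return lesions


def _layout(spec: SceneSpec):
    """Deterministic geometry: leaf masks, per-leaf visible area, lesion stamps."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    leaf_masks: list[np.ndarray] = []
    centres: list[tuple[float, float]] = []
    # close-up framing: leaves fill a large fraction of the field of view,
    # as in handheld disease photography taken tens of centimetres away
    base_r = size * 0.32
    span = (1.0 - spec.overlap_fraction) * size * 0.35
    for _ in range(spec.n_leaves):
        cy = size / 2 + rng.uniform(-span, span)
        cx = size / 2 + rng.uniform(-span, span)
        radius = base_r * rng.uniform(0.7, 1.25)
        leaf_masks.append(_blob_mask(size, cy, cx, radius, rng))
        centres.append((cy, cx))
    # painter's order: later leaves occlude earlier ones
    visible: list[np.ndarray] = []
    occupied = np.zeros((size, size), dtype=bool)
    for m in reversed(leaf_masks):
        visible.append(m & ~occupied)
        occupied |= m
    visible = visible[::-1]

    lesions: list[np.ndarray] = []
    lesion_owner: list[int] = []
    want_lesions = spec.lesion_density > 0
    for li, vis in enumerate(visible):
        # at least one lesion per leaf whenever lesions are requested, so
        # every rendered scene carries all three classes
        count = max(1, rng.poisson(spec.lesion_density)) if want_lesions else 0
        ys, xs = np.nonzero(vis)
        if len(ys) == 0:
            continue
        leaf_area = len(ys)
        budget = spec.max_lesion_fraction * leaf_area
        used = 0.0
        capped = False
        for k in range(count):
            j = rng.integers(len(ys))
            r = rng.uniform(*spec.lesion_radius_px)
            if used + np.pi * r * r > budget:
                if k == 0:   # shrink the first lesion into the budget instead
                    r = max(2.0, np.sqrt(budget / np.pi) * 0.8)
                else:
                    capped = True
                    continue
            stamp = _blob_mask(size, float(ys[j]), float(xs[j]), r, rng, wobble=0.45)
            lesions.append(stamp)
            lesion_owner.append(li)
            used += np.pi * r * r
        if capped:
            warnings.warn("lesion_density exceeds the leaf-area budget; "
                          "extra lesions were dropped", stacklevel=3)
    return leaf_masks, visible, lesions, lesion_owner


def generate_scene(spec: SceneSpec) -> Sample:
    """Render one scene; image uint8 RGB, mask uint8 in {0,1,2}."""
    rng = np.random.default_rng(spec.seed ^ 0x5EED)   # colour/texture stream
    size = spec.size
    leaf_masks, visible, lesions, _ = _layout(spec)

    # soil background
    soil = np.array([112.0, 84.0, 60.0])
    img = soil[None, None, :] * _texture(size, rng, size / 24, 0.25)[..., None]
    mask = np.zeros((size, size), dtype=np.uint8)

    for vis in visible:
        green = np.array([rng.uniform(40, 70), rng.uniform(110, 160), rng.uniform(40, 70)])
        tex = _texture(size, rng, size / 40, 0.18)
        img[vis] = green[None, :] * tex[vis, None]
        mask[vis] = 1

    lesion_union = np.zeros((size, size), dtype=bool)
    for stamp in lesions:
        lesion_union |= stamp
    lesion_px = lesion_union & (mask == 1)
    brown = np.array([96.0, 62.0, 38.0])
    img[lesion_px] = brown[None, :] * _texture(size, rng, size / 60, 0.2)[lesion_px, None]
    mask[lesion_px] = 2

    if spec.lighting_gradient > 0:
        angle = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:size, 0:size] / max(size - 1, 1)
        ramp = (yy - 0.5) * np.sin(angle) + (xx - 0.5) * np.cos(angle)
        img *= (1.0 + spec.lighting_gradient * ramp)[..., None]

    for _ in range(spec.raindrop_count):
        cy, cx = rng.uniform(0, size, 2)
        r = rng.uniform(size / 60, size / 25)
        rr, cc = draw.disk((cy, cx), r, shape=(size, size))
        img[rr, cc] = 0.55 * img[rr, cc] + 0.45 * 255.0

    image = np.clip(img, 0, 255).astype(np.uint8)
    return Sample(image=image, mask=mask, stem=f"scene_{spec.seed:06d}",
                  source_tag="synthetic",
                  disease_type="diseased" if (mask == 2).any() else "healthy")


def generate_dataset(n: int, seed: int = 0, size: int = 512,
                     **spec_kwargs) -> list[Sample]:
    """n scenes with seeds derived from ``seed`` (reproducible)."""
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n)
    return [generate_scene(SceneSpec(seed=int(s), size=size, **spec_kwargs))
            for s in seeds]


def smoke_spec_kwargs(size: int = 64) -> dict:
    """Scene parameters for CPU-scale experiments at small resolutions.

    Structures must be resolvable at the network's stride-8 output grid:
    lesion radii are floored at 4 px so every lesion spans at least one
    logit cell, and leaves occupy a large fraction of the frame (close-up
    framing) so leaf interiors span many cells — smaller structures are
    unresolvable for any stride-8 decoder and would measure the grid, not
    the model.
    """
    lo = max(4.0, size * 0.07)
    hi = max(lo + 2.0, size * 0.16)
    return dict(size=size, n_leaves=2, lesion_density=2.5,
                lesion_radius_px=(lo, hi), raindrop_count=1)
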