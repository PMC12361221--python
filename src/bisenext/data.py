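"""Dataset handling: image/mask pairs, augmentation and splitting.

Masks are single-channel index PNGs with labels {0 background, 1 leaf,
2 disease}; colour masks (black/green/red) are accepted and mapped.  Images
are resized bilinearly, masks with nearest-neighbour so labels stay exact.

The augmentation scheme produces exactly six derived samples per original —
saturation, brightness, contrast, crop, rotation and horizontal flip — each
applied once (not composed), so n originals expand to 7n samples in total.
Geometric transforms are applied identically to the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageEnhance
from scipy import ndimage

MASK_PALETTE = {0: (0, 0, 0), 1: (0, 128, 0), 2: (128, 0, 0)}  # black/green/red
AUGMENTATION_METHODS = ("saturation", "brightness", "contrast",
                        "crop", "rotation", "flip")


@dataclass
class Sample:
    """One RGB image with its index mask and provenance tags."""

    image: np.ndarray                 # (H, W, 3) uint8
    mask: np.ndarray                  # (H, W) uint8, values in {0, 1, 2}
    stem: str = "sample"
    source_tag: str = "synthetic"     # indoor | outdoor | synthetic
    augmentation_tag: str = "none"
    disease_type: str = "unknown"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask must be spatially congruent")
        extra = set(np.unique(self.mask)) - {0, 1, 2}
        if extra:
            raise ValueError(f"mask contains invalid labels {sorted(extra)}")


def _palette_image(mask: np.ndarray) -> Image.Image:
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    pal = [0] * 768
    for idx, rgb in MASK_PALETTE.items():
        pal[3 * idx:3 * idx + 3] = rgb
    img.putpalette(pal)
    return img


def write_sample(sample: Sample, image_dir: Path | str, mask_dir: Path | str) -> None:
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    image_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    Image.fromarray(sample.image).save(image_dir / f"{sample.stem}.png")
    _palette_image(sample.mask).save(mask_dir / f"{sample.stem}.png")


def _decode_mask(path: Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode == "P" or img.mode == "L":
        arr = np.asarray(img.convert("L") if img.mode == "L" else img)
        extra = set(np.unique(arr)) - {0, 1, 2}
        if extra:
            raise ValueError(f"{path.name}: mask index {sorted(extra)[0]} is not a valid label")
        return arr.astype(np.uint8)
    rgb = np.asarray(img.convert("RGB"))
    out = np.full(rgb.shape[:2], 255, dtype=np.uint8)
    for idx, colour in MASK_PALETTE.items():
        out[(rgb == colour).all(axis=-1)] = idx
    if (out == 255).any():
        bad = rgb[out == 255][0]
        raise ValueError(f"{path.name}: unmapped mask colour {tuple(int(v) for v in bad)}")
    return out


def resize_sample(sample: Sample, size: int) -> Sample:
    img = Image.fromarray(sample.image).resize((size, size), Image.BILINEAR)
    mask = Image.fromarray(sample.mask).resize((size, size), Image.NEAREST)
    return replace(sample, image=np.asarray(img), mask=np.asarray(mask))


def load_dataset(image_dir: str | Path, mask_dir: str | Path,
                 target_size: int = 512) -> list[Sample]:
    """Load image/mask pairs matched by file stem, resized to target_size."""
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    images = {p.stem: p for p in sorted(image_dir.iterdir())
              if p.suffix.lower() in (".jpg", ".jpeg", ".png")}
    masks = {p.stem: p for p in sorted(mask_dir.iterdir()) if p.suffix.lower() == ".png"}
    unpaired = sorted(set(images) ^ set(masks))
    if unpaired:
        raise ValueError(f"unpaired dataset entries: {unpaired}")
    samples = []
    for stem in sorted(images):
        img = np.asarray(Image.open(images[stem]).convert("RGB"))
        sample = Sample(image=img, mask=_decode_mask(masks[stem]), stem=stem)
        samples.append(resize_sample(sample, target_size))
    return samples


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _photometric(sample: Sample, method: str, factor: float) -> Sample:
    enhancer = {"saturation": ImageEnhance.Color,
                "brightness": ImageEnhance.Brightness,
                "contrast": ImageEnhance.Contrast}[method]
    img = enhancer(Image.fromarray(sample.image)).enhance(factor)
    return replace(sample, image=np.asarray(img), augmentation_tag=method)


def _crop(sample: Sample, area_frac: float, cx: float, cy: float) -> Sample:
    H, W = sample.mask.shape
    side = np.sqrt(area_frac)
    h, w = max(1, int(round(H * side))), max(1, int(round(W * side)))
    y0 = int(round(cy * (H - h)))
    x0 = int(round(cx * (W - w)))
    img = Image.fromarray(sample.image[y0:y0 + h, x0:x0 + w]).resize((W, H), Image.BILINEAR)
    mask = Image.fromarray(sample.mask[y0:y0 + h, x0:x0 + w]).resize((W, H), Image.NEAREST)
    return replace(sample, image=np.asarray(img), mask=np.asarray(mask),
                   augmentation_tag="crop")


def _rotate(sample: Sample, angle: float) -> Sample:
    img = ndimage.rotate(sample.image, angle, axes=(1, 0), reshape=False,
                         order=1, mode="reflect")
    mask = ndimage.rotate(sample.mask, angle, reshape=False, order=0, mode="reflect")
    return replace(sample, image=img.astype(np.uint8), mask=mask.astype(np.uint8),
                   augmentation_tag="rotation")


def _flip(sample: Sample) -> Sample:
    return replace(sample, image=sample.image[:, ::-1].copy(),
                   mask=sample.mask[:, ::-1].copy(), augmentation_tag="flip")


def augment_six(sample: Sample, seed: int = 0) -> list[Sample]:
    """Exactly six derived samples, one per augmentation method.

    Photometric factors ~ U(0.6, 1.4); crop keeps 70-90% of the area;
    rotation ~ U(-30, 30) degrees with reflection padding; horizontal flip.
    Photometric transforms leave the mask untouched bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    out = [
        _photometric(sample, "saturation", rng.uniform(0.6, 1.4)),
        _photometric(sample, "brightness", rng.uniform(0.6, 1.4)),
        _photometric(sample, "contrast", rng.uniform(0.6, 1.4)),
        _crop(sample, rng.uniform(0.7, 0.9), rng.uniform(), rng.uniform()),
        _rotate(sample, rng.uniform(-30, 30)),
        _flip(sample),
    ]
    for s, method in zip(out, AUGMENTATION_METHODS):
        s.stem = f"{sample.stem}_{method}"
    return out


def augment_dataset(samples: list[Sample], seed: int = 0) -> list[Sample]:
    """Originals plus six augmentations each: n -> 7n samples."""
    out = []
    for i, s in enumerate(samples):
        out.append(s)
        out.extend(augment_six(s, seed + i))
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split(dataset: list[Sample], ratios=(7, 2, 1), seed: int = 0,
          strata: list | None = None):
    """Disjoint, exhaustive train/val/test split, stratified.

    ``strata`` defaults to each sample's disease_type (falling back to
    lesion presence); within each stratum sizes follow ``ratios`` with
    largest-remainder rounding, so overall sizes are within +-1 per stratum
    of the exact proportion.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if strata is None:
        strata = [s.disease_type if s.disease_type != "unknown"
                  else ("diseased" if (s.mask == 2).any() else "healthy")
                  for s in dataset]
    rng = np.random.default_rng(seed)
    ratios = np.asarray(ratios, dtype=float)
    fractions = ratios / ratios.sum()
    splits: tuple[list, list, list] = ([], [], [])
    for value in sorted(set(strata)):
        idx = [i for i, s in enumerate(strata) if s == value]
        idx = list(rng.permutation(idx))
        n = len(idx)
        exact = fractions * n
        counts = np.floor(exact).astype(int)
        for _ in range(n - counts.sum()):        # largest remainders first
            counts[np.argmax(exact - counts)] += 1
        start = 0
        for part, c in zip(splits, counts):
            part.extend(dataset[i] for i in idx[start:start + c])
            start += c
    return splits


def manifest(samples: list[Sample], split_names: list[str] | None = None):
    """DataFrame manifest (stem, split, disease_type, source_tag, augmentation)."""
    import pandas as pd

    rows = [{"stem": s.stem,
             "split": split_names[i] if split_names else "",
             "disease_type": s.disease_type,
             "source_tag": s.source_tag,
             "augmentation": s.augmentation_tag} for i, s in enumerate(samples)]
    return pd.DataFrame(rows)
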