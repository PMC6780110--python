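"""Deterministic three-stage dataset expansion.

A small paired set of fundus images and vessel masks is expanded without any
randomness:

* stage 1 adds a horizontal and a vertical flip of every pair (n -> 3n);
* stage 2 applies three fixed translate-crop-resize recipes *recursively* —
  each recipe is applied to the whole accumulated set and the results kept,
  doubling it per recipe (3n -> 3n * 2^3 = 24n);
* stage 3 applies three further recipes independently to the stage-2 set
  (24n -> 72n of new pairs).

The training set is stage2 ∪ stage3 = 96n pairs; 20 input pairs therefore
yield 1920.  Every transform is applied identically to image and mask with
nearest-neighbor resampling, so masks stay strictly binary.

Sign convention: positive ``dx`` shifts content rightward (toward larger
column indices), positive ``dy`` downward.  Flips are applied before the
translation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from PIL import Image

__all__ = [
    "AugCombo",
    "SamplePair",
    "STAGE2_COMBOS",
    "STAGE3_COMBOS",
    "translate_crop_resize",
    "stage1_flips",
    "stage2_recursive",
    "stage3_nonrecursive",
    "augment_dataset",
]


@dataclass(frozen=True)
class AugCombo:
    """One translate/flip/resize recipe."""

    dx: int
    dy: int
    flip: str = "none"  # none | horizontal | vertical
    resized: bool = True

    def __post_init__(self) -> None:
        if self.flip not in ("none", "horizontal", "vertical"):
            raise ValueError(f"unknown flip {self.flip!r}")

    def label(self) -> str:
        return f"(X={self.dx},Y={self.dy},{self.flip},{'resized' if self.resized else 'crop'})"


@dataclass(frozen=True)
class SamplePair:
    """An RGB image with its binary vessel mask and transformation lineage."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    provenance: str = "original"

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} differ"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary {0,1}")


# the six fixed recipes of the published expansion
STAGE2_COMBOS = (
    AugCombo(10, -10, "none"),
    AugCombo(15, 15, "vertical"),
    AugCombo(20, -20, "horizontal"),
)
STAGE3_COMBOS = (
    AugCombo(-10, 10, "none"),
    AugCombo(-15, 15, "vertical"),
    AugCombo(-20, 20, "horizontal"),
)


def _flip(arr: np.ndarray, flip: str) -> np.ndarray:
    if flip == "horizontal":
        return arr[:, ::-1]
    if flip == "vertical":
        return arr[::-1]
    return arr


def _nearest_resize(arr: np.ndarray, size_hw: tuple[int, int]) -> np.ndarray:
    im = Image.fromarray(arr)
    return np.asarray(im.resize((size_hw[1], size_hw[0]), Image.NEAREST))


def translate_crop_resize(pair: SamplePair, combo: AugCombo) -> SamplePair:
    """Flip, shift content by (dx, dy), crop the in-bounds region, resize back.

    Shifting content by +dx leaves the first dx output columns empty, so the
    maximal in-bounds region is the source rectangle that survives the shift;
    cropping it and resizing to the original dims (nearest neighbor for both
    image and mask) is equivalent and never introduces blank borders.
    """
    h, w = pair.mask.shape
    if abs(combo.dx) >= w / 2 or abs(combo.dy) >= h / 2:
        raise ValueError(f"shift {combo.label()} too large for {h}x{w} image")
    img = _flip(pair.image, combo.flip)
    msk = _flip(pair.mask, combo.flip)
    r0, r1 = max(0, -combo.dy), h - max(0, combo.dy)
    c0, c1 = max(0, -combo.dx), w - max(0, combo.dx)
    img = np.ascontiguousarray(img[r0:r1, c0:c1])
    msk = np.ascontiguousarray(msk[r0:r1, c0:c1])
    if combo.resized and img.shape[:2] != (h, w):
        img = _nearest_resize(img, (h, w))
        msk = _nearest_resize(msk, (h, w))
    return SamplePair(img, msk, provenance=f"{pair.provenance}|{combo.label()}")


def stage1_flips(pairs: list[SamplePair]) -> list[SamplePair]:
    """Originals plus a horizontal and a vertical flip of each (n -> 3n)."""
    out = list(pairs)
    for tag, flip in (("hflip", "horizontal"), ("vflip", "vertical")):
        for p in pairs:
            out.append(
                SamplePair(
                    np.ascontiguousarray(_flip(p.image, flip)),
                    np.ascontiguousarray(_flip(p.mask, flip)),
                    provenance=f"{p.provenance}|{tag}",
                )
            )
    return out


def stage2_recursive(
    pairs: list[SamplePair], combos: tuple[AugCombo, ...] = STAGE2_COMBOS
) -> list[SamplePair]:
    """Apply each recipe to the accumulated set, doubling per recipe (n -> n*2^k)."""
    if len(combos) != 3:
        raise ValueError("stage 2 uses exactly 3 recipes")
    acc = list(pairs)
    for combo in combos:
        acc = acc + [translate_crop_resize(p, combo) for p in acc]
    return acc


def stage3_nonrecursive(
    pairs: list[SamplePair], combos: tuple[AugCombo, ...] = STAGE3_COMBOS
) -> list[SamplePair]:
    """Apply each recipe once, independently, to the input set (n -> 3n new)."""
    if len(combos) != 3:
        raise ValueError("stage 3 uses exactly 3 recipes")
    return [translate_crop_resize(p, combo) for combo in combos for p in pairs]


def augment_dataset(pairs: list[SamplePair]) -> list[SamplePair]:
    """Full expansion: flips, recursive stage, non-recursive stage (n -> 96n)."""
    s1 = stage1_flips(pairs)
    s2 = stage2_recursive(s1, STAGE2_COMBOS)
    s3 = stage3_nonrecursive(s2, STAGE3_COMBOS)
    return s2 + s3
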