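"""Dataset readers/writers and manifests.

Conventions: coordinates are 0-based (row, col); masks are stored on disk as
8-bit PNG with values {0, 255} and held in memory as {0, 1}; images are RGB
uint8.  Dataset directories follow the paired-subdirectory layout of the
public retinal benchmarks (an image directory and a name-matched mask
directory); when several observers' annotations exist, the first observer's
directory is the loader default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .augment import SamplePair

__all__ = ["DatasetManifest", "load_pair", "save_pair", "scan_dataset",
           "read_mask", "write_mask"]

_IMAGE_EXTS = {".png", ".tif", ".tiff", ".gif", ".ppm", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class DatasetManifest:
    root: Path
    entries: tuple[tuple[str, str, str], ...]  # (image path, mask path, split)

    def to_tsv(self) -> str:
        lines = ["image\tmask\tsplit"]
        for img, msk, split in self.entries:
            lines.append(f"{img}\t{msk}\t{split}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, root: str | Path = ".") -> "DatasetManifest":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:] if ln]
        return cls(Path(root), tuple((r[0], r[1], r[2]) for r in rows))

    def load(self, target_size: int | None = None) -> list[SamplePair]:
        return [
            load_pair(self.root / img, self.root / msk, target_size)
            for img, msk, _ in self.entries
        ]


def read_mask(path: str | Path) -> np.ndarray:
    """Load a mask image and binarize at half intensity -> uint8 {0,1}."""
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Store a {0,1} mask as 8-bit {0,255} PNG."""
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask is not binary {0,1}")
    Image.fromarray((mask * 255).astype(np.uint8)).save(path)


def load_pair(
    image_path: str | Path,
    mask_path: str | Path,
    target_size: int | None = None,
) -> SamplePair:
    """Load an image/mask pair, optionally resizing to target_size x target_size.

    The image is resampled bilinearly, the mask with nearest neighbor and
    re-binarized at half intensity, so it stays strictly {0, 1}.
    """
    img = Image.open(image_path).convert("RGB")
    msk = Image.open(mask_path).convert("L")
    if img.size != msk.size:
        raise ValueError(
            f"image {img.size} and mask {msk.size} dims differ "
            f"({image_path} / {mask_path})"
        )
    if target_size is not None:
        img = img.resize((target_size, target_size), Image.BILINEAR)
        msk = msk.resize((target_size, target_size), Image.NEAREST)
    mask = (np.asarray(msk) > 127).astype(np.uint8)
    return SamplePair(
        np.asarray(img), mask, provenance=str(Path(image_path).name)
    )


def save_pair(pair: SamplePair, image_path: str | Path, mask_path: str | Path) -> None:
    Image.fromarray(pair.image).save(image_path)
    write_mask(mask_path, pair.mask)


def scan_dataset(
    root: str | Path,
    layout: tuple[str, str] = ("images", "masks"),
    split: str = "train",
) -> DatasetManifest:
    """Deterministic manifest of name-matched image/mask pairs.

    ``layout`` names the image and mask subdirectories.  Files are matched on
    their stem, in lexicographic order regardless of filesystem order; an
    image without a mask (or vice versa) raises.  An empty directory yields
    an empty manifest with a warning.
    """
    root = Path(root)
    img_dir, mask_dir = root / layout[0], root / layout[1]
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"expected {img_dir} and {mask_dir}")

    def stems(d: Path) -> dict[str, Path]:
        return {
            p.stem: p
            for p in sorted(d.iterdir())
            if p.suffix.lower() in _IMAGE_EXTS
        }

    imgs, msks = stems(img_dir), stems(mask_dir)
    orphans = set(imgs) ^ set(msks)
    if orphans:
        raise ValueError(f"orphan image or mask files: {sorted(orphans)}")
    if not imgs:
        warnings.warn(f"no image pairs found under {root}", stacklevel=2)
    entries = tuple(
        (str(imgs[s].relative_to(root)), str(msks[s].relative_to(root)), split)
        for s in sorted(imgs)
    )
    return DatasetManifest(root, entries)
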