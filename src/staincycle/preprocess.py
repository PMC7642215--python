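"""Foreground extraction and two-scale patch extraction.

The pipeline works at two patch scales: large patches (default 2240 px, one
weak tumour/normal label each — the MIL bags) and small patches (default
224 px — the classifier / GAN instances), a 10x10 grid of small patches per
large patch at the defaults. Tissue foreground is separated from the bright
slide background with Otsu's threshold on the grayscale histogram; background
large patches are discarded for MIL, while GAN tiling keeps the background
because the generator must synthesize it too.

Desk-scale note: sizes are configurable; tests use 320/32 which preserves the
10x10 bag geometry at CPU scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .config import NORMAL_LABEL, TUMOR_LABEL, logger
from .synthetic_slides import GroundTruth, SlideImage

LARGE_SIZE_DEFAULT = 2240
SMALL_SIZE_DEFAULT = 224
MIN_FG_FRACTION_DEFAULT = 0.05

#: Rec. 601 luma weights used for RGB -> grayscale before thresholding.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class ForegroundMask:
    mask: np.ndarray          # uint8 {0,1}, H x W
    threshold_used: float     # grayscale level; pixels darker than this are tissue

    @property
    def coverage(self) -> float:
        return float(self.mask.mean())


@dataclass
class SmallPatch:
    pixels: np.ndarray                 # small x small x 3 uint8
    origin: tuple[int, int]            # (row, col) in the source image, 0-based
    domain: str


@dataclass
class Bag:
    bag_id: str
    weak_label: str                    # TUMOR | NORMAL
    large_patch_origin: tuple[int, int]
    instances: list[SmallPatch] = field(default_factory=list)

    def instance_array(self) -> np.ndarray:
        """Stack instances into (n, small, small, 3) uint8 for batching."""
        return np.stack([p.pixels for p in self.instances])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB uint8 -> float grayscale with Rec. 601 luma weights."""
    w = np.asarray(LUMA_WEIGHTS)
    return image.astype(np.float64) @ w


def otsu_foreground(image: SlideImage) -> ForegroundMask:
    """Tissue mask by Otsu's threshold; tissue is darker than background.

    A constant image (no variance to split) yields an all-background mask
    with a warning instead of an error.
    """
    gray = to_grayscale(image.pixels)
    gray_u8 = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    if gray_u8.min() == gray_u8.max():
        logger.warning("constant image: returning all-background mask")
        return ForegroundMask(mask=np.zeros(gray_u8.shape, dtype=np.uint8),
                              threshold_used=float(gray_u8.min()))
    thr = float(threshold_otsu(gray_u8, nbins=256))
    mask = (gray_u8 <= thr).astype(np.uint8)
    return ForegroundMask(mask=mask, threshold_used=thr)


def extract_large_patches(image: SlideImage, fg: ForegroundMask,
                          large_size: int = LARGE_SIZE_DEFAULT,
                          min_fg_fraction: float = MIN_FG_FRACTION_DEFAULT,
                          ) -> list[tuple[int, int]]:
    """Origins of retained large patches on a non-overlapping grid from (0,0).

    Border remainders are dropped; a patch is retained when its foreground
    coverage reaches ``min_fg_fraction``.
    """
    h, w = image.shape
    if large_size > min(h, w):
        logger.warning("image %dx%d smaller than large patch %d; no patches",
                       h, w, large_size)
        return []
    origins = []
    for r in range(0, h - large_size + 1, large_size):
        for c in range(0, w - large_size + 1, large_size):
            cov = fg.mask[r:r + large_size, c:c + large_size].mean()
            if cov >= min_fg_fraction:
                origins.append((r, c))
    return origins


def tile_small_patches(region: np.ndarray, small_size: int = SMALL_SIZE_DEFAULT,
                       domain: str = "HE",
                       origin_offset: tuple[int, int] = (0, 0)) -> list[SmallPatch]:
    """Row-major non-overlapping tiling; border remainders dropped.

    No foreground filter is applied here: for GAN input the whole image,
    background included, is tiled.
    """
    h, w = region.shape[:2]
    if h < small_size or w < small_size:
        return []
    patches = []
    for r in range(0, h - small_size + 1, small_size):
        for c in range(0, w - small_size + 1, small_size):
            patches.append(SmallPatch(
                pixels=region[r:r + small_size, c:c + small_size].copy(),
                origin=(origin_offset[0] + r, origin_offset[1] + c),
                domain=domain))
    return patches


def stitch_patches(patches: list[SmallPatch], shape: tuple[int, int],
                   fill: int = 248) -> np.ndarray:
    """Reassemble patches by origin into an image of the given (H, W)."""
    out = np.full((*shape, 3), fill, dtype=np.uint8)
    for p in patches:
        r, c = p.origin
        s = p.pixels.shape[0]
        out[r:r + s, c:c + s] = p.pixels
    return out


def save_bags(bags: list[Bag], out_dir, slide_id: str = "slide") -> None:
    """Persist bags as <slide>/<bag_id>/<row>_<col>.png + bag.json."""
    import json
    from pathlib import Path

    from PIL import Image

    root = Path(out_dir) / slide_id
    for bag in bags:
        bag_dir = root / bag.bag_id
        bag_dir.mkdir(parents=True, exist_ok=True)
        for p in bag.instances:
            Image.fromarray(p.pixels).save(
                bag_dir / f"{p.origin[0]}_{p.origin[1]}.png", format="PNG")
        (bag_dir / "bag.json").write_text(json.dumps({
            "bag_id": bag.bag_id, "weak_label": bag.weak_label,
            "origin": list(bag.large_patch_origin),
            "domain": bag.instances[0].domain if bag.instances else "HE"}))


def load_bags(out_dir, slide_id: str = "slide") -> list[Bag]:
    """Inverse of :func:`save_bags`; instances ordered row-major by origin."""
    import json
    from pathlib import Path

    import numpy as np
    from PIL import Image

    root = Path(out_dir) / slide_id
    bags = []
    for bag_dir in sorted(d for d in root.iterdir() if d.is_dir()):
        meta = json.loads((bag_dir / "bag.json").read_text())
        instances = []
        for png in bag_dir.glob("*.png"):
            r, c = (int(x) for x in png.stem.split("_"))
            instances.append(SmallPatch(
                pixels=np.asarray(Image.open(png).convert("RGB")),
                origin=(r, c), domain=meta["domain"]))
        instances.sort(key=lambda p: p.origin)
        bags.append(Bag(bag_id=meta["bag_id"], weak_label=meta["weak_label"],
                        large_patch_origin=tuple(meta["origin"]),
                        instances=instances))
    return bags


def _weak_label_from_gt(gt: GroundTruth, origin: tuple[int, int],
                        large_size: int) -> str:
    """TUMOR iff the large patch contains at least one tumour cell center."""
    r0, c0 = origin
    for (x, y), label in zip(gt.cell_centers, gt.cell_labels):
        if label == TUMOR_LABEL and r0 <= y < r0 + large_size and c0 <= x < c0 + large_size:
            return TUMOR_LABEL
    return NORMAL_LABEL


def build_bags(image: SlideImage,
               ground_truth_or_labels: GroundTruth | dict[tuple[int, int], str],
               large_size: int = LARGE_SIZE_DEFAULT,
               small_size: int = SMALL_SIZE_DEFAULT,
               min_fg_fraction: float = MIN_FG_FRACTION_DEFAULT) -> list[Bag]:
    """One weakly labelled bag per retained large patch.

    Labels come from the ground-truth sidecar (a bag is TUMOR if the large
    patch contains at least one tumour cell, NORMAL if it contains only
    normal cells) or from an explicit {origin: label} mapping standing in for
    manual annotation of real slides.
    """
    fg = otsu_foreground(image)
    origins = extract_large_patches(image, fg, large_size, min_fg_fraction)
    bags = []
    for origin in origins:
        if isinstance(ground_truth_or_labels, GroundTruth):
            label = _weak_label_from_gt(ground_truth_or_labels, origin, large_size)
        else:
            if origin not in ground_truth_or_labels:
                raise KeyError(f"no label for large patch at origin {origin} "
                               f"of slide {image.slide_id}")
            label = ground_truth_or_labels[origin]
        if label not in (TUMOR_LABEL, NORMAL_LABEL):
            raise ValueError(f"invalid label {label!r} for origin {origin}")
        r, c = origin
        region = image.pixels[r:r + large_size, c:c + large_size]
        instances = tile_small_patches(region, small_size, domain=image.domain,
                                       origin_offset=origin)
        bags.append(Bag(bag_id=f"{image.slide_id}_{r}_{c}", weak_label=label,
                        large_patch_origin=origin, instances=instances))
    return bags
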