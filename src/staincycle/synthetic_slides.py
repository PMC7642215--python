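"""Synthetic two-domain histology slide generator with exact ground truth.

Renders pixel-aligned pairs of HE-like and Ki-67-like microscopy images that
idealize consecutive tissue sections: identical cell geometry, a deterministic
colour mapping between domains. Tissue is a desaturated textured field on a
near-white background; nuclei are non-touching filled ellipses. In the HE
domain every nucleus is hematoxylin purple; in the Ki-67 domain tumour nuclei
flagged positive are DAB brown and all others counterstain blue.

Two deliberate idealizations make the downstream stages oracle-testable:

* nuclei never touch (radius-aware minimum clearance), so connected-component
  counting recovers the exact cell count;
* Ki-67 positivity is drawn per tumour cell as Bernoulli(positive_fraction)
  but positive cells are rendered with a strictly larger nucleus radius band,
  so positivity is a function of HE-visible morphology — without that, no
  translator could recover the positivity ratio from an HE image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from . import config as cfg
from .config import NORMAL_LABEL, TUMOR_LABEL, logger

HE = "HE"
KI67 = "KI67"


class SyntheticSlideSpec(BaseModel):
    """Parameters of one synthetic slide pair."""

    width: int = Field(default=256, ge=64)
    height: int = Field(default=256, ge=64)
    tissue_fraction: float = Field(default=0.75, gt=0.0, le=1.0)
    n_cells: int = Field(default=120, ge=0)
    tumor_region_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    positive_fraction: float = Field(default=0.4, ge=0.0, le=1.0)
    cell_radius_px: tuple[float, float] = (2.0, 3.0)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_radius(self) -> "SyntheticSlideSpec":
        lo, hi = self.cell_radius_px
        if not (0.5 <= lo <= hi):
            raise ValueError("cell_radius_px must satisfy 0.5 <= min <= max")
        return self


@dataclass
class GroundTruth:
    """Per-slide ground truth sidecar.

    ``cell_centers`` are (x, y) pixel coordinates (x = column, 0-based).
    """

    cell_centers: list[tuple[int, int]]
    cell_labels: list[str]
    cell_positive: list[bool]
    tumor_mask: np.ndarray       # uint8 {0,1}, H x W
    foreground_mask: np.ndarray  # uint8 {0,1}, H x W

    @property
    def n_cells(self) -> int:
        return len(self.cell_centers)

    def positivity_ratio(self) -> float | None:
        if not self.cell_centers:
            return None
        return sum(self.cell_positive) / len(self.cell_positive)

    def to_json(self) -> str:
        return json.dumps({
            "cell_centers": [list(c) for c in self.cell_centers],
            "cell_labels": self.cell_labels,
            "cell_positive": self.cell_positive,
            "tumor_mask": _rle_encode(self.tumor_mask),
            "foreground_mask": _rle_encode(self.foreground_mask),
        })

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            cell_centers=[tuple(c) for c in d["cell_centers"]],
            cell_labels=d["cell_labels"],
            cell_positive=d["cell_positive"],
            tumor_mask=_rle_decode(d["tumor_mask"]),
            foreground_mask=_rle_decode(d["foreground_mask"]),
        )


@dataclass
class SlideImage:
    """An RGB microscopy image with its domain tag and optional ground truth."""

    pixels: np.ndarray            # H x W x 3 uint8
    domain: str                   # HE | KI67
    slide_id: str = "slide"
    ground_truth: GroundTruth | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def save(self, path) -> None:
        Image.fromarray(self.pixels).save(path, format="PNG")

    @classmethod
    def load(cls, path: str | Path, domain: str, slide_id: str | None = None) -> "SlideImage":
        path = Path(path)
        pixels = np.asarray(Image.open(path).convert("RGB"))
        sidecar = path.parent / (path.stem + ".gt.json")
        gt = GroundTruth.from_json(sidecar.read_text()) if sidecar.exists() else None
        return cls(pixels=pixels, domain=domain,
                   slide_id=slide_id or path.stem, ground_truth=gt)


def _rle_encode(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=np.uint8).ravel()
    if flat.size == 0:
        return {"shape": list(mask.shape), "first": 0, "runs": []}
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    runs = np.diff(bounds)
    return {"shape": list(mask.shape), "first": int(flat[0]),
            "runs": [int(r) for r in runs]}


def _rle_decode(d: dict) -> np.ndarray:
    shape = tuple(d["shape"])
    runs = d["runs"]
    out = np.zeros(int(np.prod(shape)), dtype=np.uint8)
    val = d["first"]
    pos = 0
    for r in runs:
        out[pos:pos + r] = val
        pos += r
        val = 1 - val
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# Region synthesis
# ---------------------------------------------------------------------------

def _blob_mask(shape: tuple[int, int], fraction: float, rng: np.random.Generator,
               within: np.ndarray | None = None) -> np.ndarray:
    """Smoothed-noise blob covering ``fraction`` of the frame (or of ``within``)."""
    if fraction <= 0.0:
        return np.zeros(shape, dtype=np.uint8)
    h, w = shape
    noise = rng.standard_normal((h, w))
    smooth = ndi.gaussian_filter(noise, sigma=max(h, w) / 8.0)
    if within is not None:
        vals = smooth[within.astype(bool)]
        if vals.size == 0:
            return np.zeros(shape, dtype=np.uint8)
        if fraction >= 1.0:
            return within.astype(np.uint8).copy()
        thr = np.quantile(vals, 1.0 - fraction)
        return ((smooth >= thr) & within.astype(bool)).astype(np.uint8)
    if fraction >= 1.0:
        return np.ones(shape, dtype=np.uint8)
    thr = np.quantile(smooth, 1.0 - fraction)
    return (smooth >= thr).astype(np.uint8)


@dataclass
class _Cell:
    cy: float
    cx: float
    r_row: float
    r_col: float
    angle: float
    label: str
    positive: bool

    @property
    def r_max(self) -> float:
        return max(self.r_row, self.r_col)


def _radius_bands(spec: SyntheticSlideSpec) -> dict:
    lo, hi = spec.cell_radius_px
    t_lo, t_hi = cfg.TUMOR_NEGATIVE_RADIUS_OFFSET
    p_lo, p_hi = cfg.POSITIVE_RADIUS_OFFSET
    return {
        "normal": (lo, hi),
        "tumor_negative": (lo + t_lo, hi + t_hi),
        "positive": (hi + p_lo, hi + p_hi),
    }


def _place_cells(spec: SyntheticSlideSpec, fg: np.ndarray, tumor: np.ndarray,
                 rng: np.random.Generator) -> list[_Cell]:
    bands = _radius_bands(spec)
    edt = ndi.distance_transform_edt(fg)
    h, w = fg.shape
    cells: list[_Cell] = []
    attempts = 0
    max_attempts = 300 * max(spec.n_cells, 1)
    while len(cells) < spec.n_cells and attempts < max_attempts:
        attempts += 1
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        iy, ix = int(cy), int(cx)
        if iy >= h or ix >= w or not fg[iy, ix]:
            continue
        in_tumor = bool(tumor[iy, ix])
        label = TUMOR_LABEL if in_tumor else NORMAL_LABEL
        positive = in_tumor and (rng.random() < spec.positive_fraction)
        band = bands["positive" if positive else
                     ("tumor_negative" if in_tumor else "normal")]
        r = rng.uniform(*band)
        ecc = rng.uniform(0.75, 1.0)
        angle = rng.uniform(0, np.pi)
        r_row, r_col = r, r * ecc
        if edt[iy, ix] <= r + 1.5:   # whole ellipse must stay inside foreground
            continue
        ok = True
        for c in cells:
            min_d = c.r_max + r + cfg.MIN_CELL_GAP_PX
            if (c.cy - cy) ** 2 + (c.cx - cx) ** 2 < min_d * min_d:
                ok = False
                break
        if ok:
            cells.append(_Cell(cy, cx, r_row, r_col, angle, label, positive))
    if len(cells) < spec.n_cells:
        logger.warning("placed %d of %d requested cells (slide too crowded)",
                       len(cells), spec.n_cells)
    return cells


def _paint(canvas: np.ndarray, mask: np.ndarray, base_rgb: tuple, noise: np.ndarray,
           lo: int = 0, hi: int = 255) -> None:
    """Fill masked pixels with base colour + shared-channel luminance noise."""
    idx = mask.astype(bool)
    for ch in range(3):
        vals = base_rgb[ch] + noise[idx]
        canvas[idx, ch] = np.clip(vals, lo, hi).astype(np.uint8)


def render_slide_pair(spec: SyntheticSlideSpec,
                      slide_id: str = "slide") -> tuple[SlideImage, SlideImage, GroundTruth]:
    """Render an aligned HE / Ki-67 image pair plus its ground-truth sidecar.

    Identical spec + seed gives bit-identical images; the two domains share
    geometry and texture noise and differ only in the colour mapping.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    fg = _blob_mask((h, w), spec.tissue_fraction, rng)
    tumor = _blob_mask((h, w), spec.tumor_region_fraction, rng, within=fg)
    cells = _place_cells(spec, fg, tumor, rng)

    # Shared noise fields (common offset across channels preserves R-B and hue).
    bg_noise = rng.uniform(-cfg.BACKGROUND_NOISE_AMPLITUDE,
                           cfg.BACKGROUND_NOISE_AMPLITUDE, size=(h, w))
    tissue_noise = rng.uniform(-cfg.TISSUE_NOISE_AMPLITUDE,
                               cfg.TISSUE_NOISE_AMPLITUDE, size=(h, w))
    nucleus_noise = rng.uniform(-cfg.NUCLEUS_NOISE_AMPLITUDE,
                                cfg.NUCLEUS_NOISE_AMPLITUDE, size=(h, w))

    he = np.zeros((h, w, 3), dtype=np.uint8)
    ki = np.zeros((h, w, 3), dtype=np.uint8)
    bg_mask = 1 - fg
    _paint(he, bg_mask, cfg.BACKGROUND_RGB, bg_noise, lo=cfg.BACKGROUND_MIN)
    _paint(ki, bg_mask, cfg.BACKGROUND_RGB, bg_noise, lo=cfg.BACKGROUND_MIN)
    _paint(he, fg, cfg.HE_TISSUE_RGB, tissue_noise)
    _paint(ki, fg, cfg.KI67_TISSUE_RGB, tissue_noise)

    centers: list[tuple[int, int]] = []
    labels: list[str] = []
    positives: list[bool] = []
    for c in cells:
        rr, cc = draw_ellipse(c.cy, c.cx, c.r_row, c.r_col,
                              rotation=c.angle, shape=(h, w))
        cell_mask = np.zeros((h, w), dtype=bool)
        cell_mask[rr, cc] = True
        _paint(he, cell_mask, cfg.HE_NUCLEUS_RGB, nucleus_noise)
        ki_rgb = cfg.KI67_POSITIVE_RGB if c.positive else cfg.KI67_NEGATIVE_RGB
        _paint(ki, cell_mask, ki_rgb, nucleus_noise)
        centers.append((int(c.cx), int(c.cy)))
        labels.append(c.label)
        positives.append(bool(c.positive))

    gt = GroundTruth(cell_centers=centers, cell_labels=labels,
                     cell_positive=positives, tumor_mask=tumor,
                     foreground_mask=fg)
    he_img = SlideImage(pixels=he, domain=HE, slide_id=slide_id, ground_truth=gt)
    ki_img = SlideImage(pixels=ki, domain=KI67, slide_id=slide_id, ground_truth=gt)
    return he_img, ki_img, gt


def render_cohort(n_slides: int, spec_template: SyntheticSlideSpec,
                  out_dir: str | Path) -> dict:
    """Render ``n_slides`` slide pairs to disk and return (and write) a manifest.

    Slide ``i`` uses seed ``template.seed + i``. The manifest records file
    paths, per-slide seeds and ground-truth positivity ratios.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n_slides):
        spec_i = spec_template.model_copy(update={"seed": spec_template.seed + i})
        sid = f"slide_{i:03d}"
        he_img, ki_img, gt = render_slide_pair(spec_i, slide_id=sid)
        he_path = out_dir / f"{sid}_he.png"
        ki_path = out_dir / f"{sid}_ki67.png"
        gt_path = out_dir / f"{sid}.gt.json"
        he_img.save(he_path)
        ki_img.save(ki_path)
        gt_path.write_text(gt.to_json())
        entries.append({
            "slide_id": sid,
            "seed": spec_i.seed,
            "he": he_path.name,
            "ki67": ki_path.name,
            "ground_truth": gt_path.name,
            "positivity_ratio": gt.positivity_ratio(),
            "n_cells": gt.n_cells,
        })
    manifest = {"n_slides": n_slides,
                "spec_template": spec_template.model_dump(),
                "slides": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
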