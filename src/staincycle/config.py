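"""Shared configuration: stain palettes, detection thresholds, logging.

All tunable constants of the pipeline live here rather than inline in the
modules that consume them, so that the synthetic renderer, the foreground
extractor and the positivity counter stay mutually consistent: the palette
guarantees (nuclei saturated and dark, tissue desaturated, background
near-white, brown vs blue separated by the R-B sign) are exactly what the
Otsu foreground rule and the colour-rule counter rely on.
"""

from __future__ import annotations

import logging

from pydantic import BaseModel, Field

logger = logging.getLogger("staincycle")
if not logger.handlers:  # library default: quiet unless the app configures logging
    logger.addHandler(logging.NullHandler())


# ---------------------------------------------------------------------------
# Palette (8-bit RGB). Nuclei are saturated and dark; tissue is a desaturated
# mid-light field; background is near-white (>= 240 in every channel).
# Texture noise is applied as a common per-pixel luminance offset on all three
# channels, which leaves R-B differences and (approximately) saturation
# invariant -- the properties the counting rules depend on.
# ---------------------------------------------------------------------------

HE_NUCLEUS_RGB = (91, 42, 134)       # hematoxylin-like purple
HE_TISSUE_RGB = (170, 150, 158)      # eosin-like desaturated pink
KI67_POSITIVE_RGB = (139, 69, 19)    # DAB-like brown (R - B = +120)
KI67_NEGATIVE_RGB = (43, 75, 140)    # counterstain blue (R - B = -97)
KI67_TISSUE_RGB = (168, 158, 150)    # desaturated warm gray
BACKGROUND_RGB = (248, 248, 248)
BACKGROUND_MIN = 240                 # background never drops below this level

TISSUE_NOISE_AMPLITUDE = 8           # +/- luminance jitter on tissue pixels
NUCLEUS_NOISE_AMPLITUDE = 6          # +/- luminance jitter on nucleus pixels
BACKGROUND_NOISE_AMPLITUDE = 4

# Nucleus radius bands, derived from a spec's base (min, max) radius for
# normal cells. Bands are disjoint so that nuclear size is a noiseless proxy
# for cell class: normal < tumour-negative < Ki-67-positive. Proliferating
# (Ki-67-positive) nuclei being the largest is the biologically motivated
# ordering, and it is what makes positivity recoverable from HE morphology.
TUMOR_NEGATIVE_RADIUS_OFFSET = (1.2, 1.6)   # added to (min, max) of the base band
POSITIVE_RADIUS_OFFSET = (2.6, 4.0)         # added to (max, max) of the base band

MIN_CELL_GAP_PX = 3.0   # enforced clearance between nucleus boundaries

TUMOR_LABEL = "TUMOR"
NORMAL_LABEL = "NORMAL"


class QuantifyConfig(BaseModel):
    """Thresholds for the colour-rule nucleus counter.

    A pixel is a nucleus pixel when it is both saturated and dark enough to
    exclude background and desaturated tissue; a detected nucleus is positive
    when its mean red-minus-blue difference exceeds ``rb_margin`` (brown DAB
    chromogen) and negative otherwise (blue counterstain).
    """

    min_saturation: float = Field(default=0.15, ge=0.0, le=1.0)
    max_value: float = Field(default=0.85, ge=0.0, le=1.0)
    rb_margin: float = Field(default=20.0, description="8-bit R-B threshold for positivity")
    min_area_px: int = Field(default=9, ge=1, description="minimum connected-component area")


DEFAULT_QUANTIFY = QuantifyConfig()
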