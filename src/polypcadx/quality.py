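"""Capture-quality gate: is the boxed region sharp and not overexposed?

Sharpness is the variance of the Laplacian of the in-box luminance — the
standard focus measure: zero on constant patches, invariant to a global
intensity offset, and strictly decreasing under Gaussian blur of growing
sigma. Overexposure is the fraction of in-box pixels whose luminance reaches
a near-saturation level (default 250/255).

The pass thresholds are free parameters of the deployment; the shipped
defaults were calibrated on the synthetic fixture distribution (see
``scripts/calibrate_quality.py``) so that undegraded captures pass and
sigma >= 3 blurred captures fail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .localization import BoundingBox, luminance

#: calibrated on the default synthetic fixtures (geometric midpoint between
#: the blurred and undegraded Laplacian-variance distributions; see
#: scripts/calibrate_quality.py)
DEFAULT_MIN_SHARPNESS = 3.8
DEFAULT_MAX_OVEREXPOSED = 0.2
DEFAULT_OVEREXPOSURE_LEVEL = 250.0

MIN_BOX_AREA = 16


def _check_box(image: np.ndarray, box: BoundingBox) -> None:
    h, w = np.asarray(image).shape[:2]
    if box.x + box.w > w or box.y + box.h > h:
        raise ValueError("box extends outside the image frame")
    if box.area < MIN_BOX_AREA:
        raise ValueError(f"box area must be >= {MIN_BOX_AREA} px")


def sharpness(image: np.ndarray, box: BoundingBox) -> float:
    """Variance of the Laplacian response over the in-box luminance."""
    _check_box(image, box)
    lum = box.crop(luminance(image))
    lap = ndimage.laplace(lum)
    return float(lap.var())


def overexposure_fraction(image: np.ndarray, box: BoundingBox,
                          level: float = DEFAULT_OVEREXPOSURE_LEVEL) -> float:
    """Fraction of in-box pixels with luminance >= ``level``."""
    _check_box(image, box)
    lum = box.crop(luminance(image))
    return float(np.mean(lum >= level))


@dataclass(frozen=True)
class QualityConfig:
    min_sharpness: float = DEFAULT_MIN_SHARPNESS
    max_overexposed_fraction: float = DEFAULT_MAX_OVEREXPOSED
    overexposure_level: float = DEFAULT_OVEREXPOSURE_LEVEL

    def __post_init__(self) -> None:
        if self.min_sharpness < 0:
            raise ValueError("min_sharpness must be >= 0")
        if not 0.0 <= self.max_overexposed_fraction <= 1.0:
            raise ValueError("max_overexposed_fraction must be in [0, 1]")


DEFAULT_QUALITY = QualityConfig()


@dataclass(frozen=True)
class QualityReport:
    sharpness_score: float
    overexposed_fraction: float
    passed: bool
    fail_reasons: frozenset[str]   # subset of {"not_sharp", "overexposed"}

    def __post_init__(self) -> None:
        if self.passed != (not self.fail_reasons):
            raise ValueError("passed must be equivalent to empty fail_reasons")


def check_quality(image: np.ndarray, box: BoundingBox,
                  config: QualityConfig = DEFAULT_QUALITY) -> QualityReport:
    """Evaluate both criteria; every violated criterion is listed."""
    s = sharpness(image, box)
    o = overexposure_fraction(image, box, config.overexposure_level)
    reasons = set()
    if s < config.min_sharpness:
        reasons.add("not_sharp")
    if o > config.max_overexposed_fraction:
        reasons.add("overexposed")
    return QualityReport(sharpness_score=s, overexposed_fraction=o,
                         passed=not reasons, fail_reasons=frozenset(reasons))
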