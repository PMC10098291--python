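"""Calibrated 2D digital subtraction radiography.

Follow-up radiographs acquired in period-identical geometry are subtracted
from the baseline; pixels whose gray level changed beyond a noise threshold
are counted as gained or lost radiopaque area and converted to mm^2 using the
scale recovered from a 5-mm stainless-steel calibration ball.

Images are 8-bit grayscale, standardized to a uniform width of 620 pixels.
The convention throughout is radiographic: denser material renders *darker*,
so material gain makes the (follow-up - baseline) difference negative.  A
``darker_is_denser=False`` flag restores the opposite reading.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage import measure

from .errors import DetectionError, ValidationError

log = logging.getLogger(__name__)

STANDARD_WIDTH = 620
BALL_DIAMETER_MM = 5.0


@dataclass
class Radiograph:
    pixels: np.ndarray                 # (h, w) uint8
    mm_per_px: float | None = None     # set after calibration
    time_label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("radiograph must be a non-empty 2D array")
        if px.dtype != np.uint8:
            raise ValidationError("radiograph must be 8-bit grayscale")
        self.pixels = px

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def save(self, path) -> None:
        Image.fromarray(self.pixels, mode="L").save(path, format="TIFF")


def load_and_standardize(image_file, time_label=None) -> Radiograph:
    """Load an image, convert to 8-bit grayscale and standardize to 620 px width.

    Rescaling (when needed) is aspect-preserving bilinear; images already at
    the standard width pass through with identical pixels.
    """
    try:
        img = Image.open(image_file)
    except Exception as exc:  # non-image / unreadable file
        raise ValidationError(f"cannot read image {image_file!r}: {exc}") from exc
    if img.size[0] == 0 or img.size[1] == 0:
        raise ValidationError("zero-size image")
    if img.mode != "L":
        img = img.convert("L")
    w, h = img.size
    if w != STANDARD_WIDTH:
        new_h = max(1, round(h * STANDARD_WIDTH / w))
        img = img.resize((STANDARD_WIDTH, new_h), Image.BILINEAR)
    return Radiograph(np.asarray(img, dtype=np.uint8), time_label=time_label)


def calibrate_scale(ball_diameter_px: float,
                    ball_diameter_mm: float = BALL_DIAMETER_MM) -> float:
    """mm-per-pixel scale from the imaged diameter of the calibration ball."""
    if not np.isfinite(ball_diameter_px) or ball_diameter_px <= 0:
        raise ValidationError("ball diameter in pixels must be positive")
    return ball_diameter_mm / float(ball_diameter_px)


def detect_ball(img: Radiograph, threshold: float | None = None,
                min_area_px: int = 50, min_circularity: float = 0.9) -> float:
    """Diameter (px) of the calibration ball: the largest round dark blob.

    Thresholds the image (Otsu by default), labels connected components and
    keeps those with circularity ``4 pi A / P^2 > min_circularity`` (Crofton
    perimeter); the largest survivor's equivalent-circle diameter
    ``sqrt(4 A / pi)`` is returned.  Raises :class:`DetectionError` when no
    circular component exists (manual diameter entry is then the fallback,
    via :func:`calibrate_scale`).
    """
    px = img.pixels
    if threshold is None:
        from skimage.filters import threshold_otsu
        if px.min() == px.max():
            raise DetectionError("blank image: no circular component found")
        threshold = threshold_otsu(px)
    binary = px <= threshold
    labels = measure.label(binary)
    candidates = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        perim = region.perimeter_crofton
        if perim <= 0:
            continue
        circ = 4.0 * np.pi * region.area / perim ** 2
        if circ > min_circularity:
            candidates.append(region)
    if not candidates:
        raise DetectionError("no circular component found for calibration")
    if len(candidates) > 1:
        log.info("detect_ball: %d circular components, selecting the largest",
                 len(candidates))
    best = max(candidates, key=lambda r: r.area)
    return float(np.sqrt(4.0 * best.area / np.pi))


@dataclass
class DifferenceImage:
    data: np.ndarray               # int16, follow-up minus baseline
    mm_per_px: float | None = None
    meta: dict = field(default_factory=dict)


def subtract(followup: Radiograph, baseline: Radiograph) -> DifferenceImage:
    """Signed pixelwise difference (follow-up - baseline), range [-255, 255]."""
    if followup.pixels.shape != baseline.pixels.shape:
        raise ValidationError(
            f"shape mismatch: {followup.pixels.shape} vs {baseline.pixels.shape}")
    if (followup.mm_per_px and baseline.mm_per_px
            and not np.isclose(followup.mm_per_px, baseline.mm_per_px)):
        raise ValidationError("radiographs have different calibrated scales")
    diff = followup.pixels.astype(np.int16) - baseline.pixels.astype(np.int16)
    return DifferenceImage(diff, mm_per_px=followup.mm_per_px or baseline.mm_per_px)


def robust_threshold(diff: np.ndarray, background_mask: np.ndarray | None = None,
                     k: float = 3.0, floor: float = 5.0) -> float:
    """Data-driven change threshold: ``k`` robust noise SDs of the background.

    The robust SD is MAD-based (1.4826 x median absolute deviation).  The
    floor (default 5 gray levels) guards against degenerate, noise-free
    backgrounds where the MAD collapses to zero and against 8-bit
    quantization flicker.
    """
    d = diff[background_mask] if background_mask is not None else diff.ravel()
    if d.size == 0:
        return float(floor)
    mad = np.median(np.abs(d - np.median(d)))
    return float(max(floor, k * 1.4826 * mad))


@dataclass
class AreaChangeRecord:
    specimen_id: str | None
    time_label: str | None
    delta_area: float              # mm^2, net (negative = radiopaque loss)
    n_gained_px: int
    n_lost_px: int
    threshold: float
    mm_per_px: float
    group: str | None = None

    @property
    def n_changed_px(self) -> int:
        return self.n_gained_px + self.n_lost_px


def measure_area_change(diff: DifferenceImage, roi_mask: np.ndarray,
                        intensity_threshold: float | None = None,
                        mm_per_px: float | None = None,
                        darker_is_denser: bool = True,
                        specimen_id=None, time_label=None) -> AreaChangeRecord:
    """Net radiopaque-area change within the ROI, in mm^2.

    Pixels whose difference exceeds ``intensity_threshold`` count as gained
    (darker in the follow-up, under the default convention) or lost;
    ``delta_area = (n_gained - n_lost) * mm_per_px^2``.  The threshold
    defaults to :func:`robust_threshold` evaluated outside the ROI and is
    recorded in the returned record.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != diff.data.shape:
        raise ValidationError("ROI mask shape must match the difference image")
    if not roi_mask.any():
        raise ValidationError("empty ROI mask")
    scale = mm_per_px or diff.mm_per_px
    if scale is None or scale <= 0:
        raise ValidationError("a positive mm-per-pixel scale is required")
    if intensity_threshold is None:
        intensity_threshold = robust_threshold(diff.data, ~roi_mask)
    if intensity_threshold < 1:
        raise ValidationError("intensity threshold must be >= 1 gray level")
    d = diff.data[roi_mask]
    darker = int((d < -intensity_threshold).sum())
    brighter = int((d > intensity_threshold).sum())
    gained, lost = (darker, brighter) if darker_is_denser else (brighter, darker)
    return AreaChangeRecord(
        specimen_id=specimen_id, time_label=time_label,
        delta_area=(gained - lost) * scale ** 2,
        n_gained_px=gained, n_lost_px=lost,
        threshold=float(intensity_threshold), mm_per_px=float(scale))
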