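"""Specimen ROI extraction: Otsu thresholding, morphology, geometric checks.

The specimen is located by two-class Otsu thresholding of the luminance
channel, cleaned up with binary morphology and hole filling, reduced to its
largest 8-connected component and validated against the expected physical
geometry: area 620-630 mm^2, circularity > 0.85 and a centroid inside the
central 80% of the frame.  Both threshold polarities are tried, since a
specimen may be darker or brighter than the stage background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "OtsuResult",
    "RoiCriteria",
    "SegmentationResult",
    "otsu_threshold",
    "refine_mask",
    "select_roi",
    "segment_specimen",
    "mask_perimeter",
]

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class OtsuResult:
    """Optimal two-class threshold with its diagnostics.

    ``threshold`` is the bin index T such that pixels with intensity <= T
    form class 0; ``inter_class_variance`` is the maximized
    w0 w1 (mu0 - mu1)^2.
    """

    threshold: float
    class_probabilities: tuple[float, float]
    class_means: tuple[float, float]
    inter_class_variance: float


@dataclass(frozen=True)
class RoiCriteria:
    """Geometric acceptance rules for the specimen region."""

    area_mm2_min: float = 620.0
    area_mm2_max: float = 630.0
    circularity_min: float = 0.85
    centroid_central_fraction: float = 0.80


@dataclass
class SegmentationResult:
    mask: np.ndarray
    area_mm2: float
    circularity: float
    centroid_px: tuple[float, float]
    n_components_rejected: int
    valid: bool
    failure_reasons: list[str] = field(default_factory=list)
    threshold: float | None = None

    def to_json(self, **kwargs) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "mask"}
        return json.dumps(d, **kwargs)


def otsu_threshold(histogram: np.ndarray) -> OtsuResult:
    """Exhaustive scan for the threshold maximizing inter-class variance.

    ``histogram`` is a vector of bin counts (typically 256 bins).  Every
    cut point T (class 0 = bins 0..T) is evaluated and the argmax of
    w0(T) w1(T) (mu0(T) - mu1(T))^2 returned.  A bimodal histogram with an
    empty valley makes every cut inside the valley exactly optimal; the
    midpoint of the maximal plateau is returned.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size < 2:
        raise ValueError("histogram must be a 1-D vector with >= 2 bins")
    if h.sum() <= 0:
        raise ValueError("histogram is empty")
    if np.count_nonzero(h) < 2:
        raise ValueError("degenerate histogram: single occupied bin")

    p = h / h.sum()
    bins = np.arange(h.size, dtype=float)
    w0 = np.cumsum(p)[:-1]                      # P(class 0) for T = 0..n-2
    w1 = 1.0 - w0
    m0 = np.cumsum(p * bins)[:-1]               # unnormalized class-0 means
    mu_total = float(np.sum(p * bins))

    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mu_total - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0)

    best = float(np.max(sigma_b))
    plateau = np.flatnonzero(sigma_b >= best * (1.0 - 1e-12))
    t = int(round(plateau.mean()))
    return OtsuResult(
        threshold=float(t),
        class_probabilities=(float(w0[t]), float(w1[t])),
        class_means=(float(mu0[t]), float(mu1[t])),
        inter_class_variance=float(sigma_b[t]),
    )


def refine_mask(binary: np.ndarray) -> np.ndarray:
    """Morphological cleanup: 3x3 opening, 5x5 closing, hole filling."""
    m = np.asarray(binary, dtype=bool)
    m = morphology.opening(m, morphology.footprint_rectangle((3, 3)))
    m = morphology.closing(m, morphology.footprint_rectangle((5, 5)))
    return ndimage.binary_fill_holes(m)


def mask_perimeter(mask: np.ndarray, smooth_window: int = 7) -> float:
    """Boundary length (pixels) of the largest contour of a binary mask.

    The marching-squares contour is smoothed with a circular moving
    average before summing segment lengths, removing the staircase bias of
    digitized smooth shapes (a digitized disc then scores circularity 1.00
    while a sharp square stays near pi/4).
    """
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return 0.0
    c = max(contours, key=len)[:-1]  # closed contour: drop duplicate point
    w = min(smooth_window, len(c))
    if w >= 3:
        k = np.ones(w) / w
        sm = np.empty_like(c)
        for j in range(2):
            ext = np.r_[c[-(w // 2):, j], c[:, j], c[: w - 1 - w // 2, j]]
            sm[:, j] = np.convolve(ext, k, mode="valid")
        c = sm
    d = np.diff(np.vstack([c, c[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def select_roi(
    mask: np.ndarray,
    pixel_pitch_mm: float = 0.5,
    criteria: RoiCriteria | None = None,
) -> SegmentationResult:
    """Keep the largest 8-connected component and validate its geometry.

    Raises
    ------
    ValueError
        If the mask is empty (no specimen found; reacquisition required).
    """
    if criteria is None:
        criteria = RoiCriteria()
    m = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(m, structure=_EIGHT_CONN)
    if n == 0:
        raise ValueError("no specimen found in mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    roi = labels == keep

    area_px = int(roi.sum())
    area_mm2 = area_px * pixel_pitch_mm**2
    perim_px = mask_perimeter(roi)
    circularity = float(4 * np.pi * area_px / perim_px**2) if perim_px > 0 else 0.0
    cy, cx = ndimage.center_of_mass(roi)

    h, w = roi.shape
    margin = (1.0 - criteria.centroid_central_fraction) / 2.0
    centered = (margin * h <= cy <= (1 - margin) * h) and (
        margin * w <= cx <= (1 - margin) * w
    )

    reasons = []
    if not criteria.area_mm2_min <= area_mm2 <= criteria.area_mm2_max:
        reasons.append(
            f"area {area_mm2:.1f} mm^2 outside "
            f"[{criteria.area_mm2_min}, {criteria.area_mm2_max}]"
        )
    if not circularity > criteria.circularity_min:
        reasons.append(f"circularity {circularity:.3f} <= {criteria.circularity_min}")
    if not centered:
        reasons.append(
            f"centroid ({cy:.1f}, {cx:.1f}) outside central "
            f"{criteria.centroid_central_fraction:.0%} of frame"
        )

    return SegmentationResult(
        mask=roi,
        area_mm2=float(area_mm2),
        circularity=circularity,
        centroid_px=(float(cy), float(cx)),
        n_components_rejected=int(n - 1),
        valid=not reasons,
        failure_reasons=reasons,
    )


def segment_specimen(
    img: np.ndarray,
    pixel_pitch_mm: float = 0.5,
    criteria: RoiCriteria | None = None,
    full_scale: float = 255.0,
) -> SegmentationResult:
    """Full segmentation of a corrected image: Otsu + morphology + ROI.

    The luminance channel is histogrammed into 256 bins; both foreground
    polarities (below and above the Otsu threshold) are refined and
    validated, and the hypothesis yielding a valid ROI wins — ties broken
    by larger area.
    """
    from .preprocess import luminance  # local import to avoid cycle

    lum = luminance(img)
    scaled = np.clip(lum / full_scale * 255.0, 0, 255)
    hist, _ = np.histogram(scaled, bins=256, range=(0, 256))
    otsu = otsu_threshold(hist)

    candidates = []
    for fg in (scaled <= otsu.threshold, scaled > otsu.threshold):
        if not fg.any():
            continue
        try:
            res = select_roi(refine_mask(fg), pixel_pitch_mm, criteria)
        except ValueError:
            continue
        res.threshold = otsu.threshold
        candidates.append(res)
    if not candidates:
        raise ValueError("no specimen found in image")
    candidates.sort(key=lambda r: (r.valid, r.area_mm2), reverse=True)
    return candidates[0]
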