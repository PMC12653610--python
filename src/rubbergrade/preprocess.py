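"""Radiometric correction, denoising, frame averaging and quality gating.

Operations run on float rasters of shape (H, W, 3) on the stored-intensity
scale (0..255 for 8-bit data).  The order in the standard pipeline is:
multi-frame averaging, flat-field correction against dark/white references,
Gaussian denoising, then the three acquisition quality gates (focus,
illumination uniformity, saturation).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "RawFrameSet",
    "QualityMetrics",
    "PreprocessConfig",
    "FlatFieldResult",
    "ExposureStatus",
    "average_frames",
    "flat_field_correct",
    "gaussian_denoise",
    "luminance",
    "compute_quality",
    "check_exposure",
    "central_window",
]

# Rec. 709 / sRGB luminance weights, matching the Y row of the XYZ matrix.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class RawFrameSet:
    """Raw specimen frames plus dark and white reference frames.

    All rasters share shape (H, W, 3).  ``pixel_pitch_mm`` is the physical
    size of a pixel at the specimen plane (0.5 mm at the working
    magnification).
    """

    frames: list[np.ndarray]
    dark: np.ndarray
    white: np.ndarray
    bit_depth: int = 8
    exposure_ms: float = 50.0
    pixel_pitch_mm: float = 0.5

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("at least one specimen frame is required")
        shape = np.asarray(self.frames[0]).shape
        for i, f in enumerate(self.frames):
            if np.asarray(f).shape != shape:
                raise ValueError(f"frame {i} shape {np.asarray(f).shape} != {shape}")
        if self.dark.shape != shape or self.white.shape != shape:
            raise ValueError("dark/white reference shape mismatch with frames")
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")
        if float(np.mean(self.white)) <= float(np.mean(self.dark)):
            raise ValueError("white reference must exceed dark frame on average")

    @property
    def full_scale(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass
class QualityMetrics:
    snr_db: float
    uniformity_cv: float
    saturation_fraction: float
    focus_score: float
    pass_flags: dict[str, bool]
    snr_infinite: bool = False

    @property
    def all_pass(self) -> bool:
        return all(self.pass_flags.values())

    def to_json(self, **kwargs) -> str:
        d = dict(self.__dict__)
        d["all_pass"] = self.all_pass
        return json.dumps(d, **kwargs)


@dataclass(frozen=True)
class PreprocessConfig:
    """Denoising and quality-gate thresholds.

    ``gaussian_sigma`` (pixels) balances noise suppression against edge
    blur; the gates mirror the acquisition protocol: focus contrast > 0.7,
    white-reference uniformity CV < 5%, saturated pixels < 0.1%.
    ``target_range`` is the acceptable span for the 99th-percentile
    luminance as a fraction of full scale.
    """

    gaussian_sigma: float = 1.2
    gate_focus_min: float = 0.7
    gate_uniformity_cv_max: float = 0.05
    gate_saturation_max: float = 0.001
    target_range: tuple[float, float] = (0.60, 0.80)
    analysis_window_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        for name in ("gate_focus_min", "gate_uniformity_cv_max", "gate_saturation_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class FlatFieldResult:
    """Corrected raster plus the mask of pixels with a usable reference.

    ``valid`` is False where |white - dark| fell below the division floor;
    such pixels hold 0 in ``corrected`` and must be excluded from
    downstream statistics rather than treated as measurements.
    """

    corrected: np.ndarray
    valid: np.ndarray
    n_masked: int


def average_frames(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Pixel-wise arithmetic mean of congruent frames.

    With n i.i.d. noisy frames the residual noise SD shrinks by sqrt(n).
    """
    if len(frames) == 0:
        raise ValueError("no frames to average")
    shape = np.asarray(frames[0]).shape
    for i, f in enumerate(frames):
        if np.asarray(f).shape != shape:
            raise ValueError(f"frame {i} shape {np.asarray(f).shape} != {shape}")
    return np.mean(np.stack([np.asarray(f, dtype=float) for f in frames]), axis=0)


def flat_field_correct(
    raw: np.ndarray,
    dark: np.ndarray,
    white: np.ndarray,
    eps_fraction: float = 1e-6,
    full_scale: float = 255.0,
) -> FlatFieldResult:
    """Per-pixel, per-channel flat-field correction.

    corrected = (raw - dark) / (white - dark) * gain

    where ``gain`` is the spatial mean of the dark-subtracted white
    reference per channel over the usable region, so a specimen imaged
    under the same illumination field as the white tile recovers its true
    (dark-free) intensity.  Pixels where |white - dark| is below
    ``eps_fraction * full_scale`` are masked out instead of dividing.
    """
    raw = np.asarray(raw, dtype=float)
    dark = np.asarray(dark, dtype=float)
    white = np.asarray(white, dtype=float)
    if raw.shape != dark.shape or raw.shape != white.shape:
        raise ValueError("raw/dark/white shapes differ")

    denom = white - dark
    valid = np.abs(denom) > eps_fraction * full_scale
    valid_px = valid.all(axis=-1) if valid.ndim == 3 else valid

    if white.ndim == 3:
        gain = np.array(
            [np.mean(denom[..., c][valid[..., c]]) for c in range(white.shape[-1])]
        )
    else:
        gain = np.mean(denom[valid])
    corrected = np.zeros_like(raw)
    np.divide(raw - dark, denom, out=corrected, where=valid)
    corrected *= gain

    return FlatFieldResult(
        corrected=corrected,
        valid=valid_px,
        n_masked=int(valid_px.size - valid_px.sum()),
    )


def gaussian_denoise(img: np.ndarray, sigma: float = 1.2) -> np.ndarray:
    """Convolve each channel with a normalized Gaussian kernel.

    Uses nearest-neighbour boundary handling so constant images are fixed
    points.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return ndimage.gaussian_filter(img, sigma, mode="nearest")
    out = np.empty_like(img)
    for c in range(img.shape[-1]):
        out[..., c] = ndimage.gaussian_filter(img[..., c], sigma, mode="nearest")
    return out


def luminance(img: np.ndarray) -> np.ndarray:
    """Scalar luminance channel (Y row of the RGB->XYZ matrix)."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img
    return img @ _LUMA


def central_window(shape: tuple[int, int], window_mm: float, pixel_pitch_mm: float):
    """Slices selecting the central analysis window (e.g. 30 x 30 mm)."""
    h, w = shape
    wh = min(h, int(round(window_mm / pixel_pitch_mm)))
    ww = min(w, int(round(window_mm / pixel_pitch_mm)))
    r0 = (h - wh) // 2
    c0 = (w - ww) // 2
    return slice(r0, r0 + wh), slice(c0, c0 + ww)


def _focus_score(lum: np.ndarray) -> float:
    """Normalized gradient-contrast focus metric in [0, 1].

    Peak Sobel gradient magnitude (99.9th percentile) divided by the
    robust intensity range and the Sobel step response (4): an ideal
    one-pixel edge scores ~1, and defocus spreads the edge, lowering the
    peak gradient proportionally.  A contrast-free image scores 0.
    """
    gx = ndimage.sobel(lum, axis=0, mode="nearest")
    gy = ndimage.sobel(lum, axis=1, mode="nearest")
    grad_peak = float(np.percentile(np.hypot(gx, gy), 99.9))
    lo, hi = np.percentile(lum, [0.5, 99.5])
    if hi <= lo:
        return 0.0
    return float(np.clip(grad_peak / (4.0 * (hi - lo)), 0.0, 1.0))


def compute_quality(frameset: RawFrameSet, cfg: PreprocessConfig | None = None) -> QualityMetrics:
    """Image-quality metrics and the three acquisition gates.

    * SNR (dB) = 20 log10(mean white-reference luminance / dark-frame
      luminance SD); infinite SNR (zero dark noise) is reported as a
      sentinel with ``snr_infinite`` set.
    * Uniformity CV = SD/mean of the white-reference luminance over the
      central analysis window (illumination uniformity as measured on a
      white tile; vignetting is mild near the optical axis).
    * Saturation fraction counts pixels at 0 or full scale in any channel
      of the averaged specimen frame.
    * Focus score: normalized gradient contrast of the flat-field-corrected
      averaged frame (vignetting would otherwise dilute the contrast
      normalization).
    """
    if cfg is None:
        cfg = PreprocessConfig()
    avg = average_frames(frameset.frames)
    lum = luminance(avg)
    full = frameset.full_scale

    mu_signal = float(np.mean(luminance(frameset.white)))
    sigma_noise = float(np.std(luminance(frameset.dark)))
    if sigma_noise == 0:
        snr_db, snr_inf = float("inf"), True
    else:
        snr_db, snr_inf = 20.0 * np.log10(mu_signal / sigma_noise), False

    win = central_window(lum.shape, cfg.analysis_window_mm, frameset.pixel_pitch_mm)
    wlum = luminance(frameset.white)[win]
    uniformity_cv = float(np.std(wlum) / np.mean(wlum)) if wlum.size else float("nan")

    saturated = (avg <= 0).any(axis=-1) | (avg >= full).any(axis=-1)
    saturation_fraction = float(saturated.mean())

    ff = flat_field_correct(avg, frameset.dark, frameset.white, full_scale=full)
    focus = _focus_score(luminance(ff.corrected) / full)

    flags = {
        "focus": focus > cfg.gate_focus_min,
        "uniformity": uniformity_cv < cfg.gate_uniformity_cv_max,
        "saturation": saturation_fraction < cfg.gate_saturation_max,
    }
    return QualityMetrics(
        snr_db=snr_db,
        uniformity_cv=uniformity_cv,
        saturation_fraction=saturation_fraction,
        focus_score=focus,
        pass_flags=flags,
        snr_infinite=snr_inf,
    )


class ExposureStatus(str, enum.Enum):
    OK = "ok"
    TOO_LOW = "too_low"
    TOO_HIGH = "too_high"


def check_exposure(
    img: np.ndarray,
    cfg: PreprocessConfig | None = None,
    full_scale: float = 255.0,
) -> ExposureStatus:
    """Classify exposure by the 99th-percentile luminance vs full scale."""
    if cfg is None:
        cfg = PreprocessConfig()
    p99 = float(np.percentile(luminance(img), 99)) / full_scale
    lo, hi = cfg.target_range
    if p99 < lo:
        return ExposureStatus.TOO_LOW
    if p99 > hi:
        return ExposureStatus.TOO_HIGH
    return ExposureStatus.OK
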