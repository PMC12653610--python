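"""Seeded synthetic scene and colorimetric-sample generation.

Emulates the imaging rig for testing without hardware: a rounded-square
rubber specimen on a mid-gray stage, a shared multiplicative radial
vignetting field (spatial CV ~12.3% before correction), additive Gaussian
sensor noise, a dark-current frame, and a uniform white-reference tile.
Per-grade specimen RGB means and standard deviations follow the published
characterization of the five commercial grades.

Scenes are bit-identical for identical seeds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .classify import Grade
from .preprocess import RawFrameSet

__all__ = [
    "GradeStats",
    "GRADE_TABLE",
    "SpecimenShape",
    "SceneConfig",
    "SyntheticScene",
    "radial_vignetting_field",
    "specimen_mask",
    "make_scene",
    "sample_color_vectors",
]


@dataclass(frozen=True)
class GradeStats:
    """Per-grade colorimetric population parameters (mean, SD)."""

    rgb_mean: tuple[float, float, float]
    rgb_sd: tuple[float, float, float]
    yi: tuple[float, float]
    l_star: tuple[float, float]
    a_star: tuple[float, float]
    b_star: tuple[float, float]


#: Reference per-grade statistics of the five commercial rubber grades
#: (mean +/- SD over 20 specimens each).
GRADE_TABLE: dict[Grade, GradeStats] = {
    Grade.WHITE_CREPE: GradeStats(
        rgb_mean=(124.7, 122.3, 120.2), rgb_sd=(3.2, 2.8, 2.5),
        yi=(8.52, 0.52), l_star=(51.5, 1.1), a_star=(0.52, 0.15), b_star=(1.43, 0.22),
    ),
    Grade.STR5: GradeStats(
        rgb_mean=(129.0, 107.6, 43.2), rgb_sd=(8.1, 6.9, 4.2),
        yi=(62.8, 6.08), l_star=(46.3, 3.8), a_star=(0.61, 0.28), b_star=(38.1, 4.7),
    ),
    Grade.STR5L: GradeStats(
        rgb_mean=(128.9, 109.9, 40.9), rgb_sd=(7.8, 7.2, 3.9),
        yi=(64.3, 6.21), l_star=(46.9, 3.6), a_star=(-0.88, 0.31), b_star=(39.8, 4.9),
    ),
    Grade.RSS3: GradeStats(
        rgb_mean=(80.4, 59.1, 21.2), rgb_sd=(9.5, 7.2, 3.1),
        yi=(72.2, 7.47), l_star=(26.5, 4.2), a_star=(4.85, 0.89), b_star=(26.4, 5.3),
    ),
    Grade.RSS5: GradeStats(
        rgb_mean=(27.6, 25.0, 19.4), rgb_sd=(2.1, 1.9, 1.5),
        yi=(28.8, 1.81), l_star=(8.86, 0.95), a_star=(0.02, 0.18), b_star=(4.17, 0.48),
    ),
}


class SpecimenShape(str, enum.Enum):
    SQUARE = "square"
    ROUNDED_SQUARE = "rounded_square"
    DISC = "disc"


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic acquisition.

    The default geometry (121 x 121 px at 0.5 mm/px, 25 mm specimen with
    4.5 mm corner radius) digitizes to 623.25 mm^2 and circularity ~0.92,
    inside the ROI acceptance gates.  ``vignetting_cv`` is the spatial CV
    of the multiplicative illumination field over the frame before
    correction; ``noise_sd`` is the additive Gaussian sensor noise per
    frame in 8-bit counts.
    """

    grade: Grade = Grade.WHITE_CREPE
    image_size_px: tuple[int, int] = (121, 121)
    pixel_pitch_mm: float = 0.5
    specimen_shape: SpecimenShape = SpecimenShape.ROUNDED_SQUARE
    specimen_side_mm: float = 25.0
    corner_radius_mm: float = 4.5
    rgb_mean: tuple[float, float, float] | None = None
    rgb_sd: tuple[float, float, float] | None = None
    background_level: float = 170.0
    white_level: float = 190.0
    dark_level: float = 8.0
    vignetting_cv: float = 0.123
    noise_sd: float = 2.0
    n_frames: int = 3
    specimen_to_specimen_variation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if self.specimen_side_mm / self.pixel_pitch_mm > min(h, w):
            raise ValueError("specimen does not fit inside the image")
        if self.noise_sd < 0 or self.vignetting_cv < 0:
            raise ValueError("noise_sd and vignetting_cv must be non-negative")

    def grade_stats(self) -> GradeStats:
        return GRADE_TABLE[Grade(self.grade)]

    @property
    def effective_rgb_mean(self) -> tuple[float, float, float]:
        return self.rgb_mean if self.rgb_mean is not None else self.grade_stats().rgb_mean

    @property
    def effective_rgb_sd(self) -> tuple[float, float, float]:
        return self.rgb_sd if self.rgb_sd is not None else self.grade_stats().rgb_sd


@dataclass
class SyntheticScene:
    frameset: RawFrameSet
    truth_mask: np.ndarray
    grade: Grade
    specimen_rgb: tuple[float, float, float]
    config: SceneConfig


def radial_vignetting_field(shape: tuple[int, int], cv: float) -> np.ndarray:
    """Radial-quadratic illumination field with mean 1 and spatial CV ``cv``.

    field = 1 + beta * (mean(u) - u) with u = (r / r_max)^2, beta scaled so
    the standard deviation over the frame hits the target CV (center
    bright, corners dark).
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    y = (yy + 0.5 - h / 2) / (h / 2)
    x = (xx + 0.5 - w / 2) / (w / 2)
    u = (y**2 + x**2) / 2.0  # in [0, 1] at the corners
    if cv == 0:
        return np.ones(shape)
    beta = cv / float(np.std(u))
    field = 1.0 + beta * (float(np.mean(u)) - u)
    if field.min() <= 0:
        raise ValueError(f"vignetting_cv={cv} drives the field non-positive")
    return field


def specimen_mask(cfg: SceneConfig) -> np.ndarray:
    """Ground-truth binary specimen mask, centered in the frame."""
    h, w = cfg.image_size_px
    yy, xx = np.mgrid[0:h, 0:w]
    y = (yy + 0.5 - h / 2) * cfg.pixel_pitch_mm
    x = (xx + 0.5 - w / 2) * cfg.pixel_pitch_mm
    half = cfg.specimen_side_mm / 2.0
    shape = SpecimenShape(cfg.specimen_shape)
    if shape is SpecimenShape.SQUARE:
        return (np.abs(y) <= half) & (np.abs(x) <= half)
    if shape is SpecimenShape.DISC:
        return y**2 + x**2 <= half**2
    r = cfg.corner_radius_mm
    qy = np.maximum(np.abs(y) - (half - r), 0.0)
    qx = np.maximum(np.abs(x) - (half - r), 0.0)
    return qy**2 + qx**2 <= r**2


def make_scene(cfg: SceneConfig | None = None, **overrides) -> SyntheticScene:
    """Generate a full synthetic acquisition: frames + dark + white + truth.

    The specimen region carries the grade RGB level, the background the
    stage level; the same vignetting field multiplies the specimen frames
    and the white reference so flat-field correction can cancel it.  Each
    frame receives independent Gaussian sensor noise and is quantized to
    integer counts.
    """
    if cfg is None:
        cfg = SceneConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size_px
    mask = specimen_mask(cfg)
    field = radial_vignetting_field((h, w), cfg.vignetting_cv)

    rgb = np.asarray(cfg.effective_rgb_mean, dtype=float)
    if cfg.specimen_to_specimen_variation:
        rgb = rgb + rng.normal(0.0, np.asarray(cfg.effective_rgb_sd, dtype=float))
        rgb = np.clip(rgb, 0.0, 255.0)

    ideal = np.empty((h, w, 3))
    ideal[...] = cfg.background_level
    ideal[mask] = rgb

    def acquire(signal: np.ndarray, vignette: bool) -> np.ndarray:
        img = signal * field[..., None] if vignette else signal.copy()
        img = img + cfg.dark_level
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        return np.clip(np.rint(img), 0, 255).astype(float)

    frames = [acquire(ideal, True) for _ in range(cfg.n_frames)]
    white = acquire(np.full((h, w, 3), cfg.white_level), True)
    dark = acquire(np.zeros((h, w, 3)), False)

    frameset = RawFrameSet(
        frames=frames,
        dark=dark,
        white=white,
        bit_depth=8,
        exposure_ms=50.0,
        pixel_pitch_mm=cfg.pixel_pitch_mm,
    )
    return SyntheticScene(
        frameset=frameset,
        truth_mask=mask,
        grade=Grade(cfg.grade),
        specimen_rgb=tuple(float(v) for v in rgb),
        config=cfg,
    )


# Physical truncation bounds for sampled colorimetric parameters.
_PARAM_BOUNDS = {
    "yi": (-150.0, 150.0),
    "l_star": (0.0, 100.0),
    "a_star": (-128.0, 128.0),
    "b_star": (-128.0, 128.0),
}


def sample_color_vectors(
    grade: Grade | str,
    n: int,
    seed: int | None = None,
    stats: Mapping[Grade, GradeStats] | None = None,
) -> list[dict[str, float]]:
    """Gaussian draws of (YI, L*, a*, b*) from the per-grade distribution.

    Returns plain parameter dicts accepted by the classifier; draws are
    truncated (clipped) to physical ranges.  ``n=1`` with zero SDs returns
    the grade means exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    g = Grade(grade)
    table = stats if stats is not None else GRADE_TABLE
    gs = table[g]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        row = {}
        for p, (mu, sd) in (
            ("yi", gs.yi), ("l_star", gs.l_star),
            ("a_star", gs.a_star), ("b_star", gs.b_star),
        ):
            lo, hi = _PARAM_BOUNDS[p]
            row[p] = float(np.clip(rng.normal(mu, sd), lo, hi))
        out.append(row)
    return out
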