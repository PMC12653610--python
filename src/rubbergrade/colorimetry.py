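"""Device-independent color math for rubber colorimetry.

Converts camera RGB to CIE XYZ tristimulus values, CIELAB coordinates and
the yellowness index used for grade classification.  Two conversion paths
are maintained side by side:

``gamma_linearized``
    8-bit RGB is normalized, linearized with the sRGB inverse transfer
    function (or a pure power law) and multiplied by the sRGB/D65 matrix,
    scaled so that reference white has Y = 100.  This path yields CIELAB
    coordinates on the conventional 0-100 lightness scale.

``raw_linear``
    The matrix is applied directly to the 8-bit RGB means with no transfer
    function.  The yellowness index of rubber specimens is reported on this
    path with the table-consistent coefficient pair (1.28, 1.06); the ASTM
    E313 D65 pair (1.2985, 1.1335) is available as a preset.

Both paths, and the coefficient preset, are recorded on the output objects
so downstream consumers can verify which variant they received.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "LinearizationMode",
    "LinearizationConfig",
    "ColorTransformConfig",
    "WhitePoint",
    "XYZPath",
    "TristimulusXYZ",
    "LabColor",
    "YellownessPreset",
    "YellownessConfig",
    "ColorVector",
    "SRGB_D65_MATRIX",
    "linearize",
    "rgb_to_xyz",
    "xyz_to_lab",
    "yellowness_index",
    "delta_e_ab",
    "color_vector_from_rgb",
]

#: sRGB -> CIE 1931 XYZ conversion matrix for the D65 illuminant and the
#: 2 degree standard observer.
SRGB_D65_MATRIX = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)


class LinearizationMode(str, enum.Enum):
    NONE = "none"
    POWER_GAMMA = "power_gamma"
    SRGB_PIECEWISE = "srgb_piecewise"


@dataclass(frozen=True)
class LinearizationConfig:
    """Transfer-function settings mapping stored intensities to linear light.

    Parameters
    ----------
    mode:
        ``none`` divides by ``bit_depth_max`` only; ``power_gamma`` applies
        a pure power law with exponent ``gamma``; ``srgb_piecewise`` applies
        the IEC 61966-2-1 inverse transfer function.
    gamma:
        Exponent for ``power_gamma`` mode (dimensionless, default 2.2).
    bit_depth_max:
        Full-scale stored intensity (255 for 8-bit data).
    """

    mode: LinearizationMode = LinearizationMode.SRGB_PIECEWISE
    gamma: float = 2.2
    bit_depth_max: float = 255.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.bit_depth_max <= 0:
            raise ValueError(
                f"bit_depth_max must be positive, got {self.bit_depth_max}"
            )


@dataclass(frozen=True)
class ColorTransformConfig:
    """3x3 RGB->XYZ matrix plus an output scale.

    ``output_scale`` is 100 for normalized linear input (CIELAB convention
    where reference white has Y = 100) and 1 for the raw 8-bit passthrough
    path.
    """

    matrix: np.ndarray = field(default_factory=lambda: SRGB_D65_MATRIX.copy())
    output_scale: float = 100.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or not np.all(np.isfinite(m)):
            raise ValueError("matrix must be a finite 3x3 array")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class WhitePoint:
    """Tristimulus values of the reference white (default: D65, Yn=100)."""

    Xn: float = 95.047
    Yn: float = 100.000
    Zn: float = 108.883

    def __post_init__(self) -> None:
        if min(self.Xn, self.Yn, self.Zn) <= 0:
            raise ValueError("white point components must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.Xn, self.Yn, self.Zn])


class XYZPath(str, enum.Enum):
    GAMMA_LINEARIZED = "gamma_linearized"
    RAW_LINEAR = "raw_linear"


@dataclass(frozen=True)
class TristimulusXYZ:
    X: float
    Y: float
    Z: float
    path: XYZPath

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z])


@dataclass(frozen=True)
class LabColor:
    L_star: float
    a_star: float
    b_star: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L_star, self.a_star, self.b_star])


class YellownessPreset(str, enum.Enum):
    #: ASTM E313 coefficients for D65 / 2 degree observer.
    ASTM_E313_D65 = "astm_e313_d65"
    #: Coefficient pair consistent with the published per-grade YI table.
    TABLE_CONSISTENT = "table_consistent"


_YI_COEFFS = {
    YellownessPreset.ASTM_E313_D65: (1.2985, 1.1335),
    YellownessPreset.TABLE_CONSISTENT: (1.28, 1.06),
}


@dataclass(frozen=True)
class YellownessConfig:
    """Coefficients of the yellowness index YI = 100 (cx X - cz Z) / Y."""

    preset: YellownessPreset = YellownessPreset.TABLE_CONSISTENT
    cx: float | None = None
    cz: float | None = None

    def coefficients(self) -> tuple[float, float]:
        cx, cz = _YI_COEFFS[YellownessPreset(self.preset)]
        if self.cx is not None:
            cx = self.cx
        if self.cz is not None:
            cz = self.cz
        if cx <= 0 or cz <= 0:
            raise ValueError("yellowness coefficients must be positive")
        return cx, cz


def linearize(rgb: Sequence[float] | np.ndarray, cfg: LinearizationConfig) -> np.ndarray:
    """Map stored intensities in [0, bit_depth_max] to linear reflectance in [0, 1].

    Monotone non-decreasing in the input; 0 maps to 0 and full scale to 1
    in every mode.

    Raises
    ------
    ValueError
        If any value lies outside [0, bit_depth_max]; the message names the
        offending channel for 3-channel input.
    """
    arr = np.asarray(rgb, dtype=float)
    below, above = arr < 0, arr > cfg.bit_depth_max
    if below.any() or above.any():
        bad = np.flatnonzero((below | above).reshape(-1))[0]
        channel = "RGB"[bad % 3] if arr.size % 3 == 0 else str(bad)
        raise ValueError(
            f"intensity out of range [0, {cfg.bit_depth_max}] in channel {channel}"
        )
    u = arr / cfg.bit_depth_max
    mode = LinearizationMode(cfg.mode)
    if mode is LinearizationMode.NONE:
        return u
    if mode is LinearizationMode.POWER_GAMMA:
        return u**cfg.gamma
    # IEC 61966-2-1 inverse transfer function
    return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)


def rgb_to_xyz(
    rgb_linear: Sequence[float] | np.ndarray,
    cfg: ColorTransformConfig | None = None,
    path: XYZPath = XYZPath.GAMMA_LINEARIZED,
) -> TristimulusXYZ:
    """Apply the 3x3 conversion matrix: XYZ = M @ rgb * output_scale."""
    if cfg is None:
        cfg = ColorTransformConfig()
    v = np.asarray(rgb_linear, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite RGB input")
    xyz = cfg.matrix @ v * cfg.output_scale
    return TristimulusXYZ(float(xyz[0]), float(xyz[1]), float(xyz[2]), XYZPath(path))


# CIE 15:2004 break point of the f(t) function.
_CIE_DELTA = 6.0 / 29.0


def _cie_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(
        t > _CIE_DELTA**3,
        np.cbrt(t),
        t / (3 * _CIE_DELTA**2) + 4.0 / 29.0,
    )


def xyz_to_lab(xyz: TristimulusXYZ, wp: WhitePoint | None = None) -> LabColor:
    """CIE 15:2004 XYZ -> CIELAB, with the linear branch below (6/29)^3.

    ``xyz`` must be on the same scale as the white point (Yn = 100
    convention for the gamma-linearized path).
    """
    if wp is None:
        wp = WhitePoint()
    v = xyz.as_array()
    if np.any(v < 0):
        raise ValueError(f"negative tristimulus value: {tuple(v)}")
    fx, fy, fz = _cie_f(v / wp.as_array())
    return LabColor(
        L_star=float(116.0 * fy - 16.0),
        a_star=float(500.0 * (fx - fy)),
        b_star=float(200.0 * (fy - fz)),
    )


def yellowness_index(xyz: TristimulusXYZ, cfg: YellownessConfig | None = None) -> float:
    """YI = 100 (cx X - cz Z) / Y.  Positive values indicate yellowness."""
    if cfg is None:
        cfg = YellownessConfig()
    if xyz.Y <= 0:
        raise ValueError(f"yellowness index requires Y > 0, got Y={xyz.Y}")
    cx, cz = cfg.coefficients()
    return float(100.0 * (cx * xyz.X - cz * xyz.Z) / xyz.Y)


def delta_e_ab(a: LabColor, b: LabColor) -> float:
    """CIE76 color difference: Euclidean distance in (L*, a*, b*)."""
    return float(np.linalg.norm(a.as_array() - b.as_array()))


@dataclass(frozen=True)
class ColorVector:
    """Per-specimen colorimetric summary.

    Carries the mean ROI RGB, both tristimulus variants, CIELAB from the
    linearized path and both yellowness-index variants.  ``yi`` is the
    grading value: table-consistent coefficients on the raw-linear path.
    """

    rgb_mean: tuple[float, float, float]
    xyz_raw: TristimulusXYZ
    xyz_linearized: TristimulusXYZ
    lab: LabColor
    yi: float
    yi_astm: float
    specimen_id: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["xyz_raw"]["path"] = self.xyz_raw.path.value
        d["xyz_linearized"]["path"] = self.xyz_linearized.path.value
        d["yi_preset"] = YellownessPreset.TABLE_CONSISTENT.value
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def color_vector_from_rgb(
    rgb_mean: Sequence[float],
    lin_cfg: LinearizationConfig | None = None,
    wp: WhitePoint | None = None,
    specimen_id: str = "",
) -> ColorVector:
    """Build the full dual-path colorimetric summary from a mean RGB triple.

    This is the grade-table reproduction mode: CIELAB comes from the
    linearized (default sRGB piecewise) path scaled to Yn = 100, while the
    yellowness index is evaluated on the raw 8-bit matrix transform with
    the table-consistent coefficients.
    """
    lin_cfg = lin_cfg or LinearizationConfig()
    rgb = np.asarray(rgb_mean, dtype=float)

    xyz_raw = rgb_to_xyz(
        rgb, ColorTransformConfig(output_scale=1.0), path=XYZPath.RAW_LINEAR
    )
    xyz_lin = rgb_to_xyz(
        linearize(rgb, lin_cfg),
        ColorTransformConfig(output_scale=100.0),
        path=XYZPath.GAMMA_LINEARIZED,
    )
    lab = xyz_to_lab(xyz_lin, wp)
    if xyz_raw.Y > 0:
        yi = yellowness_index(xyz_raw, YellownessConfig(YellownessPreset.TABLE_CONSISTENT))
        yi_astm = yellowness_index(xyz_raw, YellownessConfig(YellownessPreset.ASTM_E313_D65))
    else:  # zero-luminance input: yellowness undefined
        yi = yi_astm = float("nan")
    return ColorVector(
        rgb_mean=(float(rgb[0]), float(rgb[1]), float(rgb[2])),
        xyz_raw=xyz_raw,
        xyz_linearized=xyz_lin,
        lab=lab,
        yi=yi,
        yi_astm=yi_astm,
        specimen_id=specimen_id,
    )
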