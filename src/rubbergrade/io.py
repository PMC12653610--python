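"""Raster and scene I/O: 8/16-bit TIFF/PNG in, float TIFF and masks out."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .preprocess import RawFrameSet

__all__ = [
    "load_raster",
    "save_raster",
    "save_mask_png",
    "load_mask_png",
    "save_scene",
    "load_frameset",
]


def load_raster(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit or float TIFF/PNG as a float (H, W[, 3]) array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return np.asarray(arr, dtype=float)


def save_raster(path: str | Path, img: np.ndarray, as_uint8: bool = False) -> None:
    """Write a raster: uint8 PNG/TIFF for display, float32 TIFF otherwise."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if as_uint8:
        data = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    else:
        data = np.asarray(img, dtype=np.float32)
    if path.suffix.lower() in {".tif", ".tiff"}:
        photometric = "rgb" if data.ndim == 3 and data.shape[-1] == 3 else "minisblack"
        tifffile.imwrite(path, data, photometric=photometric)
    else:
        iio.imwrite(path, np.clip(np.rint(img), 0, 255).astype(np.uint8))


def save_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Binary mask as a 0/255 PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def load_mask_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def save_scene(directory: str | Path, scene) -> Path:
    """Persist a synthetic scene: frames/dark/white TIFFs + truth JSON."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fs = scene.frameset
    for i, frame in enumerate(fs.frames):
        save_raster(d / f"frame_{i}.tiff", frame, as_uint8=True)
    save_raster(d / "dark.tiff", fs.dark, as_uint8=True)
    save_raster(d / "white.tiff", fs.white, as_uint8=True)
    save_mask_png(d / "truth_mask.png", scene.truth_mask)
    truth = {
        "grade": scene.grade.value,
        "specimen_rgb": list(scene.specimen_rgb),
        "pixel_pitch_mm": fs.pixel_pitch_mm,
        "bit_depth": fs.bit_depth,
        "seed": scene.config.seed,
    }
    (d / "truth.json").write_text(json.dumps(truth, indent=2))
    return d


def load_frameset(directory: str | Path) -> tuple[RawFrameSet, dict]:
    """Load a scene directory written by :func:`save_scene`."""
    d = Path(directory)
    frames = sorted(d.glob("frame_*.tiff"))
    if not frames:
        raise FileNotFoundError(f"no frame_*.tiff files under {d}")
    meta = {}
    truth_path = d / "truth.json"
    if truth_path.exists():
        meta = json.loads(truth_path.read_text())
    fs = RawFrameSet(
        frames=[load_raster(p) for p in frames],
        dark=load_raster(d / "dark.tiff"),
        white=load_raster(d / "white.tiff"),
        bit_depth=int(meta.get("bit_depth", 8)),
        pixel_pitch_mm=float(meta.get("pixel_pitch_mm", 0.5)),
    )
    return fs, meta
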