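"""Raster image input and luminance conversion.

Images come from a smartphone camera photographing quantum-dot fluorescence
through a 610 nm long-pass filter, so essentially all signal lands in the
sensor's red channel. Luminance is kept real-valued on the [0, 255] scale
throughout the pipeline (no 8-bit requantization) to avoid rounding bias in
the per-spot medians.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ConfigError, FormatError, InputError

#: Supported RGB -> luminance conversions.
LUMINANCE_MODES = ("red_only", "rec601", "equal")

_REC601 = np.array([0.299, 0.587, 0.114])


def load_image(path: str | Path, as_gray: bool = False) -> np.ndarray:
    """Load a PNG/TIFF/JPEG image as float64 on the [0, 255] scale.

    Returns an ``(H, W)`` array for grayscale inputs and ``(H, W, 3)`` for
    RGB(A) inputs (alpha is dropped). 16-bit inputs are rescaled by
    255/65535. With ``as_gray=True`` RGB inputs are collapsed with the
    default luminance mode.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot decode image {path}: {exc}")
    if arr.dtype == np.uint16:
        img = arr.astype(np.float64) * (255.0 / 65535.0)
    elif arr.dtype == np.uint8:
        img = arr.astype(np.float64)
    elif np.issubdtype(arr.dtype, np.floating):
        img = arr.astype(np.float64)
    else:
        raise FormatError(f"unsupported pixel dtype {arr.dtype} in {path}")
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        img = img[:, :, :3]
        if as_gray:
            return to_luminance(img)
        return img
    raise FormatError(
        f"unsupported channel layout {img.shape} in {path} (need gray or RGB)"
    )


def to_luminance(img: np.ndarray, mode: str = "red_only") -> np.ndarray:
    """Collapse an RGB image to a single luminance plane.

    Modes
    -----
    ``red_only``
        The red plane alone — the default, because the long-pass emission
        filter confines the quantum-dot signal to the red sensor channel.
    ``rec601``
        Y = 0.299 R + 0.587 G + 0.114 B (generic video luminance).
    ``equal``
        (R + G + B) / 3 (ImageJ-default behaviour).

    Grayscale input is returned unchanged regardless of mode; all modes
    agree on achromatic pixels.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        return img
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(f"expected (H, W, 3) RGB image, got shape {img.shape}")
    if mode == "red_only":
        return img[:, :, 0].copy()
    if mode == "rec601":
        return img @ _REC601
    if mode == "equal":
        return img.mean(axis=2)
    raise ConfigError(
        f"unknown luminance mode {mode!r}; expected one of {LUMINANCE_MODES}"
    )


def save_gray_png(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 255] luminance raster as an 8-bit PNG (debug output)."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0, 255)
    iio.imwrite(Path(path), np.round(arr).astype(np.uint8))
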