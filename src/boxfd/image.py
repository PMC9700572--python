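"""Calibrated slice images and TIFF round-tripping.

Pixel values are on an HU-like non-negative integer scale stored as 16-bit.
The compass calibration ring is drawn at :data:`RING_INTENSITY`, the top of
the representable range, so it is separable from anatomy (lumen contrast and
calcium both live far below it).

Coordinate convention: origin at the top-left pixel centre, x rightward
(columns), y downward (rows); physical position = pixel index * mm_per_pixel.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidParameterError

__all__ = ["CalibratedImage", "RING_INTENSITY", "read_tiff", "write_tiff"]

RING_INTENSITY = 65535  # uint16 max; reserved for the compass ring

PLANES = ("annulus", "lvot")
PHASES = ("systole", "diastole")


@dataclass
class CalibratedImage:
    """A 2D HU-like intensity grid with physical scale and slice metadata."""

    pixels: np.ndarray
    mm_per_pixel: float
    plane: str = "annulus"
    phase: str = "diastole"
    subject_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidParameterError("pixels must be a non-empty 2D array")
        if not self.mm_per_pixel > 0:
            raise InvalidParameterError("mm_per_pixel must be positive")
        if self.plane not in PLANES:
            raise InvalidParameterError(f"plane must be one of {PLANES}")
        if self.phase not in PHASES:
            raise InvalidParameterError(f"phase must be one of {PHASES}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def extent_mm(self) -> tuple[float, float]:
        """(width, height) of the pixel-centre lattice in mm."""
        h, w = self.pixels.shape
        return (w - 1) * self.mm_per_pixel, (h - 1) * self.mm_per_pixel


def write_tiff(image: CalibratedImage, path) -> None:
    """Write the grid as 16-bit grayscale TIFF; metadata travels in the manifest."""
    px = np.clip(np.rint(np.asarray(image.pixels, dtype=float)), 0, 65535)
    tifffile.imwrite(str(path), px.astype(np.uint16))


def read_tiff(path, mm_per_pixel: float | None = None, plane: str = "annulus",
              phase: str = "diastole", subject_id: str = "") -> CalibratedImage:
    """Read an 8- or 16-bit grayscale TIFF into a CalibratedImage.

    ``mm_per_pixel`` may be left to 0/None and set later via compass
    calibration; a placeholder of 1.0 is stored in that case and flagged.
    """
    p = Path(path)
    px = tifffile.imread(str(p))
    if px.ndim == 3 and px.shape[-1] == 1:
        px = px[..., 0]
    if px.ndim != 2:
        raise InvalidParameterError(f"{p}: expected a 2D grayscale image, got shape {px.shape}")
    if px.dtype.kind not in "ui" or px.dtype.itemsize > 2:
        raise InvalidParameterError(f"{p}: expected 8- or 16-bit integer pixels, got {px.dtype}")
    meta = {}
    if mm_per_pixel is None or mm_per_pixel <= 0:
        mm_per_pixel = 1.0
        meta["calibration_pending"] = True
    return CalibratedImage(px.astype(np.uint16), mm_per_pixel, plane=plane,
                           phase=phase, subject_id=subject_id, metadata=meta)
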