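"""Semi-automatic lumen border detection on calibrated slice images.

The border is found by thresholding: the connected bright-lumen component
containing a seed point is grown (pixels at or above the lumen threshold and
below the calcium ceiling — very bright calcium is deliberately excluded so
foci indent the border), and its outer boundary is traced sub-pixel along
the threshold isocontour with marching squares. A pixel-resolution boundary
mode is kept behind a switch for sensitivity analysis.

Calibration uses the compass ring burned into exported images: ring pixels
sit at the top of the intensity range, a circle is fitted to them, and
mm_per_pixel = known diameter / fitted pixel diameter.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .contours import ContourPolyline
from .errors import (CalibrationError, FragmentationError, InvalidContourError,
                     InvalidParameterError, OpenBoundaryError, SeedError)
from .image import RING_INTENSITY, CalibratedImage

__all__ = [
    "SegmentationConfig", "check_luminal_attenuation", "calibrate_from_compass",
    "detect_border", "override_contour", "write_contour_csv", "read_contour_csv",
]

DEFAULT_THRESHOLD = 300.0     # HU-like lumen/tissue decision boundary (= suitability gate)
DEFAULT_CALCIUM_CEILING = 800.0
_RING_FLOOR = 0.98 * RING_INTENSITY


@dataclass(frozen=True)
class SegmentationConfig:
    threshold: float = DEFAULT_THRESHOLD
    calcium_ceiling: float = DEFAULT_CALCIUM_CEILING
    gate_hu: float = 300.0
    subpixel: bool = True     # marching-squares isocontour vs pixel-chain boundary


def check_luminal_attenuation(image: CalibratedImage, lumen_probe,
                              gate_hu: float = 300.0,
                              probe_radius_px: int = 5) -> tuple[bool, float]:
    """Median intensity over a disk probe and whether it exceeds the gate.

    ``lumen_probe`` is an (x, y) pixel point or ((row_lo, row_hi),
    (col_lo, col_hi)) region; the point form uses a disk of
    ``probe_radius_px`` around it.
    """
    h, w = image.shape
    first = lumen_probe[0]
    if not hasattr(first, "__len__"):  # (x, y) point form
        x, y = float(lumen_probe[0]), float(lumen_probe[1])
        if not (0 <= x < w and 0 <= y < h):
            raise InvalidParameterError(f"probe point ({x}, {y}) outside image {w}x{h}")
        rr, cc = np.ogrid[:h, :w]
        mask = (rr - y) ** 2 + (cc - x) ** 2 <= probe_radius_px ** 2
        values = image.pixels[mask]
    else:
        (r0, r1), (c0, c1) = lumen_probe
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise InvalidParameterError("probe region outside image bounds")
        values = image.pixels[int(r0):int(r1), int(c0):int(c1)].ravel()
    med = float(np.median(values.astype(float)))
    return med > gate_hu, med


def _fit_circle(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit; returns (row_c, col_c, radius)."""
    A = np.column_stack([cols, rows, np.ones_like(cols, dtype=float)])
    b = cols.astype(float) ** 2 + rows.astype(float) ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    col_c = sol[0] / 2.0
    row_c = sol[1] / 2.0
    radius = np.sqrt(max(sol[2] + col_c ** 2 + row_c ** 2, 0.0))
    return float(row_c), float(col_c), float(radius)


def calibrate_from_compass(image: CalibratedImage, known_diameter_mm: float) -> float:
    """mm_per_pixel from the burned-in compass ring of known physical diameter."""
    if not known_diameter_mm > 0:
        raise InvalidParameterError("known_diameter_mm must be positive")
    ring = np.asarray(image.pixels, dtype=float) >= _RING_FLOOR
    n_px = int(ring.sum())
    if n_px < 16:
        raise CalibrationError(
            "no compass ring found (too few maximal-intensity pixels); "
            "supply mm_per_pixel explicitly in the manifest/config")
    labeled, n_comp = ndimage.label(ring, structure=np.ones((3, 3), dtype=int))
    if n_comp != 1:
        raise CalibrationError(
            f"{n_comp} maximal-intensity components found, expected one ring; "
            "supply mm_per_pixel explicitly in the manifest/config")
    rows, cols = np.nonzero(ring)
    row_c, col_c, radius = _fit_circle(rows, cols)
    radial = np.hypot(rows - row_c, cols - col_c)
    if radius < 4 or np.std(radial) > 0.15 * radius:
        raise CalibrationError(
            "maximal-intensity pixels do not form a thin circular ring; "
            "supply mm_per_pixel explicitly in the manifest/config")
    return known_diameter_mm / (2.0 * radius)


def _lumen_component(image: CalibratedImage, lumen_seed, threshold: float,
                     calcium_ceiling: float) -> np.ndarray:
    """Boolean mask of the seed's lumen-intensity connected component."""
    h, w = image.shape
    x, y = float(lumen_seed[0]), float(lumen_seed[1])
    r, c = int(round(y)), int(round(x))
    if not (0 <= r < h and 0 <= c < w):
        raise InvalidParameterError(f"seed ({x}, {y}) outside image {w}x{h}")
    px = np.asarray(image.pixels, dtype=float)
    lumen = (px >= threshold) & (px < calcium_ceiling) & (px < _RING_FLOOR)
    if not lumen[r, c]:
        raise SeedError(
            f"seed pixel intensity {px[r, c]:g} is not within the lumen band "
            f"[{threshold:g}, {calcium_ceiling:g})")
    labeled, _ = ndimage.label(lumen)
    comp = labeled == labeled[r, c]
    if comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any():
        raise OpenBoundaryError("lumen component touches the image frame; border would be clipped")
    return comp


def _smooth_closed(vertices: np.ndarray, window: int) -> np.ndarray:
    """Periodic moving average; window is ~1 px, far below the minimum caliber."""
    if window <= 1:
        return vertices
    kernel = np.ones(window) / window
    pad = window
    out = np.empty_like(vertices)
    for axis in range(2):
        wrapped = np.r_[vertices[-pad:, axis], vertices[:, axis], vertices[:pad, axis]]
        out[:, axis] = np.convolve(wrapped, kernel, mode="same")[pad:-pad]
    return out


def detect_border(image: CalibratedImage, lumen_seed=None,
                  threshold: float = DEFAULT_THRESHOLD,
                  calcium_ceiling: float = DEFAULT_CALCIUM_CEILING,
                  subpixel: bool = True, smooth_window: int = 3) -> ContourPolyline:
    """Trace the closed outer lumen border in mm.

    ``lumen_seed`` is an (x, y) pixel point, default image centre. Compass
    ring pixels and calcium pixels (>= ``calcium_ceiling``) are treated as
    non-lumen, so calcium foci indent the border. Holes inside the lumen are
    ignored; only the single external boundary enclosing the seed is
    returned. ``smooth_window`` (vertices) damps marching-squares staircase
    artefacts; it acts below the caliber range, so FD is unaffected; set 1
    to disable.
    """
    h, w = image.shape
    if lumen_seed is None:
        lumen_seed = ((w - 1) / 2.0, (h - 1) / 2.0)
    comp = _lumen_component(image, lumen_seed, threshold, calcium_ceiling)
    # fill holes so interior isocontours vanish; exterior boundary is unaffected
    filled = ndimage.binary_fill_holes(comp)

    if subpixel:
        # sub-pixel isocontour of the intensity field at the threshold level,
        # restricted to the seed component: outside pixels are clamped below
        # threshold so only this component's border is traced
        px = np.asarray(image.pixels, dtype=float)
        field = np.where(filled, np.maximum(px, threshold), np.minimum(px, threshold - 1.0))
        contours = measure.find_contours(field, level=threshold)
    else:
        contours = measure.find_contours(filled.astype(float), level=0.5)

    sx, sy = float(lumen_seed[0]), float(lumen_seed[1])
    best = None
    best_area = -1.0
    for rc in contours:
        closed = np.allclose(rc[0], rc[-1])
        if not closed:
            raise OpenBoundaryError("traced border is open (touches the image frame)")
        if len(rc) < 4:
            continue
        xy = np.column_stack([rc[:-1, 1], rc[:-1, 0]])  # (col, row) -> (x, y) px
        if len(xy) < 3:
            continue
        x, ycoord = xy[:, 0], xy[:, 1]
        area = abs(np.dot(x, np.roll(ycoord, -1)) - np.dot(ycoord, np.roll(x, -1))) / 2.0
        if area > best_area and measure.points_in_poly([[sy, sx]], rc[:-1])[0]:
            best, best_area = xy, area
    if best is None:
        raise FragmentationError(
            "no closed border enclosing the seed could be traced; "
            "correct manually via override_contour")
    if subpixel:
        best = _smooth_closed(best, smooth_window)
    vertices_mm = best * image.mm_per_pixel
    return ContourPolyline(vertices_mm, closed=True, source="detected",
                           metadata={"threshold": threshold,
                                     "calcium_ceiling": calcium_ceiling,
                                     "subpixel": subpixel,
                                     "subject_id": image.subject_id})


def override_contour(image: CalibratedImage, vertices_mm) -> ContourPolyline:
    """Accept a manually corrected contour after closure/simplicity checks."""
    contour = ContourPolyline(vertices_mm, closed=True, source="manual",
                              metadata={"subject_id": image.subject_id,
                                        "manual_correction": True})
    if not contour.is_simple():
        raise InvalidContourError("manually supplied contour self-intersects")
    return contour


# -- contour CSV round-trip (manual-correction interchange format) --------

def write_contour_csv(contour: ContourPolyline, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_mm", "y_mm"])
        for x, y in contour.vertices:
            writer.writerow([repr(float(x)), repr(float(y))])


def read_contour_csv(path, source: str = "manual") -> ContourPolyline:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header[:2]] != ["x_mm", "y_mm"]:
            raise InvalidParameterError(f"{path}: expected header x_mm,y_mm")
        for row in reader:
            if row:
                rows.append((float(row[0]), float(row[1])))
    return ContourPolyline(np.array(rows), closed=True, source=source)
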