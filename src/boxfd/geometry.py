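"""Conventional Euclidean measures of annulus/LVOT contours.

Diameters are Feret-type: d_max is the largest vertex-pair distance and
d_min the smallest width over rotating-calipers directions, both computed on
the convex hull. (Whether the clinical workstation uses Feret or centroid-ray
diameters is undocumented; Feret is rotation-invariant and deterministic, and
the choice is recorded in the output metadata.)

Eccentricity is 100 * (d_max - d_min) / d_max; non-tubularity is
(annulus area - LVOT area) / annulus area, negative values passed through.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .contours import ContourPolyline
from .errors import InvalidContourError, InvalidParameterError

__all__ = ["GeometryMeasures", "contour_measures", "non_tubularity"]

DIAMETER_DEFINITION = "feret"  # echoed into result metadata


@dataclass(frozen=True)
class GeometryMeasures:
    area_mm2: float
    perimeter_mm: float
    d_min_mm: float
    d_max_mm: float
    eccentricity_pct: float
    diameter_definition: str = DIAMETER_DEFINITION

    def __post_init__(self):
        if self.d_min_mm > self.d_max_mm + 1e-12:
            raise InvalidParameterError("d_min must not exceed d_max")


def _feret_diameters(points: np.ndarray) -> tuple[float, float]:
    """(min Feret width, max Feret diameter) of a point set via its hull."""
    hull = ConvexHull(points)
    hp = points[hull.vertices]
    # max: largest pairwise distance among hull vertices
    diff = hp[:, None, :] - hp[None, :, :]
    d_max = float(np.sqrt((diff ** 2).sum(-1)).max())
    # min: rotating calipers — smallest over hull edges of the farthest
    # vertex distance to the edge's supporting line
    e = np.roll(hp, -1, axis=0) - hp
    lengths = np.linalg.norm(e, axis=1)
    keep = lengths > 0
    e, base, lengths = e[keep], hp[keep], lengths[keep]
    normals = np.stack([-e[:, 1], e[:, 0]], axis=1) / lengths[:, None]
    # distances: (n_edges, n_vertices)
    d = np.abs((hp[None, :, :] - base[:, None, :]) @ normals[..., None])[:, :, 0]
    widths = d.max(axis=1)
    d_min = float(widths.min())
    return d_min, d_max


def contour_measures(contour: ContourPolyline) -> GeometryMeasures:
    """Area (shoelace), perimeter, Feret diameters and eccentricity of a simple closed contour."""
    if not contour.closed:
        raise InvalidContourError("geometry measures require a closed contour")
    contour.require_simple()
    area = contour.area()
    perimeter = contour.perimeter()
    d_min, d_max = _feret_diameters(contour.vertices)
    ecc = 100.0 * (d_max - d_min) / d_max
    return GeometryMeasures(area_mm2=area, perimeter_mm=perimeter,
                            d_min_mm=d_min, d_max_mm=d_max,
                            eccentricity_pct=ecc)


def non_tubularity(annulus_area_mm2: float, lvot_area_mm2: float) -> float:
    """(annulus - LVOT) / annulus; negative when the LVOT flares wider."""
    if not annulus_area_mm2 > 0:
        raise InvalidParameterError("annulus area must be positive")
    if lvot_area_mm2 < 0:
        raise InvalidParameterError("LVOT area must be non-negative")
    return (annulus_area_mm2 - lvot_area_mm2) / annulus_area_mm2
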