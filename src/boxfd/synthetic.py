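"""Synthetic contours, slice images and cohorts with known ground truth.

Three contour families serve as fractal-dimension oracles:

* circles / regular polygons (smooth limit, dimension 1),
* Koch snowflake boundaries (similarity dimension ln4/ln3),
* radially perturbed circles r(theta) = R * (1 + a * f_H(theta)) where f_H
  is a zero-mean periodic fractional-noise profile built by Fourier
  synthesis with a power-law amplitude spectrum |c_k| ~ k^(-H-1/2) and
  random phases. Dimension rises as the Hurst parameter H falls or the
  amplitude a grows, so cohort-level FD contrasts can be planted.

The renderer turns a contour into an HU-like 16-bit slice: bright lumen on
darker tissue, optional very bright calcium foci clipped against the lumen
(so they indent the detected border), an optional 1-px compass ring of known
physical diameter, and truncated additive Gaussian noise. Every generator is
a pure function of (parameters, seed).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.draw import circle_perimeter, polygon2mask

from .cohort_stats import PVR_GRADES, SubjectRecord
from .contours import ContourPolyline
from .errors import GenerationFailureError, InvalidParameterError
from .image import RING_INTENSITY, CalibratedImage, write_tiff

__all__ = [
    "ContourSpec", "RenderSpec", "CohortSubject",
    "generate_circle_contour", "generate_koch_contour", "generate_fractal_contour",
    "generate_segment", "render_ct_slice", "generate_cohort", "write_cohort",
]

_MAX_RESAMPLES = 10
KOCH_DIMENSION = np.log(4) / np.log(3)


@dataclass(frozen=True)
class ContourSpec:
    """Parameters of a radially perturbed circle with tunable roughness."""

    base_radius_mm: float = 12.0
    roughness_amplitude: float = 0.0   # fraction of radius
    hurst_exponent: float = 0.5        # in (0, 1]
    n_vertices: int = 512
    seed: int = 0
    #: lowest Fourier harmonic carrying power. Harmonics below it are
    #: suppressed so the amplitude knob tunes border roughness rather than
    #: global ellipticity; 1 restores the unfiltered power law.
    min_harmonic: int = 4

    def __post_init__(self):
        if not self.base_radius_mm > 0:
            raise InvalidParameterError("base_radius_mm must be positive")
        if self.roughness_amplitude < 0:
            raise InvalidParameterError("roughness_amplitude must be non-negative")
        if not 0 < self.hurst_exponent <= 1:
            raise InvalidParameterError("hurst_exponent must lie in (0, 1]")
        if self.n_vertices < 16:
            raise InvalidParameterError("n_vertices must be >= 16")
        if not 1 <= self.min_harmonic <= self.n_vertices // 4:
            raise InvalidParameterError("min_harmonic must lie in [1, n_vertices/4]")


@dataclass(frozen=True)
class RenderSpec:
    """How a contour is rasterized into an HU-like 16-bit slice image."""

    mm_per_pixel: float = 0.1
    image_size_px: tuple[int, int] = (400, 400)  # (rows, cols)
    lumen_intensity: float = 400.0
    tissue_intensity: float = 50.0
    noise_sd: float = 0.0
    calcium_foci: tuple = ()          # ((x_mm, y_mm, radius_mm, intensity), ...)
    compass_diameter_mm: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.mm_per_pixel > 0:
            raise InvalidParameterError("mm_per_pixel must be positive")
        if self.lumen_intensity <= self.tissue_intensity:
            raise InvalidParameterError("lumen_intensity must exceed tissue_intensity")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        if self.compass_diameter_mm is not None and not self.compass_diameter_mm > 0:
            raise InvalidParameterError("compass_diameter_mm must be positive")


def generate_circle_contour(radius_mm: float, n_vertices: int = 360,
                            center_mm: tuple[float, float] = (0.0, 0.0)) -> ContourPolyline:
    """Regular n-gon on a circle; perimeter within 0.5% of 2*pi*r for n >= 256."""
    if not radius_mm > 0:
        raise InvalidParameterError("radius_mm must be positive")
    if n_vertices < 16:
        raise InvalidParameterError("n_vertices must be >= 16")
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    vertices = np.column_stack([radius_mm * np.cos(theta) + center_mm[0],
                                radius_mm * np.sin(theta) + center_mm[1]])
    return ContourPolyline(vertices, closed=True, source="circle")


def generate_segment(length_mm: float, y_mm: float = 0.0,
                     x0_mm: float = 0.0, n_vertices: int = 2) -> ContourPolyline:
    """Open horizontal segment; degenerate 'contour' used only as an FD oracle."""
    if not length_mm > 0:
        raise InvalidParameterError("length_mm must be positive")
    x = np.linspace(x0_mm, x0_mm + length_mm, max(2, n_vertices))
    return ContourPolyline(np.column_stack([x, np.full_like(x, y_mm)]),
                           closed=False, source="segment")


def generate_koch_contour(level: int, side_mm: float = 100.0) -> ContourPolyline:
    """Koch snowflake boundary with 3 * 4^level segments (level 0..7).

    The default side of 100 mm puts the level-5 scaling regime
    (segment length side/3^5 ~ 0.41 mm up to side/3 ~ 33 mm) around the
    standard 0.8-6.75 mm caliber window.
    """
    if not isinstance(level, (int, np.integer)) or level < 0:
        raise InvalidParameterError("level must be a non-negative integer")
    if level > 7:
        raise InvalidParameterError("level > 7 refused (vertex count blows up)")
    if not side_mm > 0:
        raise InvalidParameterError("side_mm must be positive")
    h = side_mm * np.sqrt(3) / 2.0
    # counter-clockwise equilateral triangle in image coords (y down)
    pts = np.array([[0.0, 0.0], [side_mm, 0.0], [side_mm / 2.0, -h]])
    rot = np.array([[np.cos(np.pi / 3), -np.sin(np.pi / 3)],
                    [np.sin(np.pi / 3), np.cos(np.pi / 3)]])
    for _ in range(level):
        p = pts
        q = np.roll(pts, -1, axis=0)
        d = (q - p) / 3.0
        a = p + d
        b = p + 2.0 * d
        tip = a + d @ rot.T
        pts = np.stack([p, a, tip, b], axis=1).reshape(-1, 2)
    return ContourPolyline(pts, closed=True, source=f"koch{level}")


def _fractional_profile(n: int, hurst: float, rng: np.random.Generator,
                        min_harmonic: int = 1) -> np.ndarray:
    """Zero-mean periodic noise with |c_k| ~ k^(-H-1/2), unit sample std."""
    k = np.arange(1, n // 2 + 1, dtype=float)
    amp = k ** (-hurst - 0.5)
    amp[: min_harmonic - 1] = 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(k))
    spectrum = np.zeros(n // 2 + 1, dtype=complex)
    spectrum[1:] = amp * np.exp(1j * phases)
    f = np.fft.irfft(spectrum, n=n)
    sd = f.std()
    if sd == 0:
        return f
    return (f - f.mean()) / sd


def generate_fractal_contour(spec: ContourSpec) -> ContourPolyline:
    """Radially perturbed circle; resamples on self-intersection (max 10 tries)."""
    n = spec.n_vertices
    theta = 2.0 * np.pi * np.arange(n) / n
    rng = np.random.default_rng(spec.seed)
    for attempt in range(_MAX_RESAMPLES):
        f = _fractional_profile(n, spec.hurst_exponent, rng, spec.min_harmonic)
        r = spec.base_radius_mm * (1.0 + spec.roughness_amplitude * f)
        if np.any(r <= 0.05 * spec.base_radius_mm):
            continue
        vertices = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        contour = ContourPolyline(vertices, closed=True, source="fractal",
                                  metadata={"spec": spec, "attempt": attempt})
        if spec.roughness_amplitude == 0 or contour.is_simple():
            return contour
    raise GenerationFailureError(
        f"no simple contour after {_MAX_RESAMPLES} resamples for {spec}")


def render_ct_slice(contour: ContourPolyline, spec: RenderSpec,
                    plane: str = "annulus", phase: str = "diastole",
                    subject_id: str = "") -> CalibratedImage:
    """Rasterize a contour into a calibrated HU-like 16-bit slice.

    The contour's bounding-box centre is translated to the image centre
    before rasterizing (calcium foci, given in contour coordinates, move
    with it); segmentation grid origin and FD are translation-tolerant, and
    the seed default of image-centre then lands inside the lumen.
    """
    rows, cols = spec.image_size_px
    mmpp = spec.mm_per_pixel
    xmin, ymin, xmax, ymax = contour.bounds()
    cx_img = (cols - 1) / 2.0 * mmpp
    cy_img = (rows - 1) / 2.0 * mmpp
    dx = cx_img - (xmin + xmax) / 2.0
    dy = cy_img - (ymin + ymax) / 2.0
    shifted = contour.vertices + np.array([dx, dy])

    margin = 2.0 * mmpp
    if (shifted[:, 0].min() < margin or shifted[:, 1].min() < margin
            or shifted[:, 0].max() > (cols - 1) * mmpp - margin
            or shifted[:, 1].max() > (rows - 1) * mmpp - margin):
        raise InvalidParameterError(
            "contour does not fit inside the image extent at this scale")

    poly_rc = np.column_stack([shifted[:, 1], shifted[:, 0]]) / mmpp
    lumen_mask = polygon2mask((rows, cols), poly_rc)

    img = np.full((rows, cols), spec.tissue_intensity, dtype=float)
    img[lumen_mask] = spec.lumen_intensity

    rr_grid, cc_grid = np.mgrid[0:rows, 0:cols]
    for focus in spec.calcium_foci:
        fx, fy, fr, fint = focus
        d2 = ((cc_grid * mmpp - (fx + dx)) ** 2
              + (rr_grid * mmpp - (fy + dy)) ** 2)
        disk = d2 <= fr ** 2
        img[disk & lumen_mask] = fint  # clipped against the lumen

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    img = np.clip(np.rint(img), 0, 65535)

    if spec.compass_diameter_mm is not None:
        radius_px = int(round(spec.compass_diameter_mm / 2.0 / mmpp))
        rr, cc = circle_perimeter(rows // 2, cols // 2, radius_px, shape=(rows, cols))
        img[rr, cc] = RING_INTENSITY

    return CalibratedImage(img.astype(np.uint16), mmpp, plane=plane, phase=phase,
                           subject_id=subject_id,
                           metadata={"render_spec": spec, "shift_mm": (dx, dy)})


# -- cohorts ---------------------------------------------------------------

@dataclass
class CohortSubject:
    """One synthetic subject: ground-truth contours, optional images, record."""

    subject_id: str
    group: str
    contours: dict[tuple[str, str], ContourPolyline]
    images: dict[tuple[str, str], CalibratedImage]
    record: SubjectRecord


def _resolve_cell_params(params, cell: tuple[str, str]) -> dict:
    """Group params may be flat or keyed by (plane, phase) for planted cells."""
    if params and all(isinstance(k, tuple) for k in params):
        flat = dict(params.get("default", {}))
        flat.update(params.get(cell, {}))
        return flat
    by_cell = params.get("by_cell", {}) if isinstance(params, dict) else {}
    flat = {k: v for k, v in params.items() if k != "by_cell"}
    flat.update(by_cell.get(cell, {}))
    return flat


def generate_cohort(n_per_group: int, contour_params_by_group: dict,
                    outcome_label_by_group: dict, seed: int = 0,
                    planes: tuple[str, ...] = ("annulus", "lvot"),
                    phases: tuple[str, ...] = ("systole", "diastole"),
                    render: RenderSpec | None = None,
                    missing_phase_rate: float = 0.0,
                    lvot_radius_factor: float = 0.92) -> list[CohortSubject]:
    """Fully seeded synthetic cohort over plane x phase cells.

    ``contour_params_by_group`` maps group name to ContourSpec keyword
    overrides, optionally with a ``"by_cell"`` sub-dict keyed by
    (plane, phase) for planted per-cell contrasts. ``outcome_label_by_group``
    maps group name to a dict with ``pvr_grade`` and optional
    ``composite_endpoint``. With ``render=None`` only ground-truth contours
    are produced (fast statistics-level cohorts); otherwise each cell is
    rasterized with a per-subject noise seed.
    """
    if n_per_group < 1:
        raise InvalidParameterError("n_per_group must be >= 1")
    if len(contour_params_by_group) < 2:
        raise InvalidParameterError("need at least two groups")
    for g in contour_params_by_group:
        if g not in outcome_label_by_group:
            raise InvalidParameterError(f"no outcome label for group {g!r}")

    root = np.random.SeedSequence(seed)
    subjects: list[CohortSubject] = []
    groups = sorted(contour_params_by_group)
    child_seeds = root.spawn(len(groups) * n_per_group)
    idx = 0
    for group in groups:
        params = contour_params_by_group[group]
        outcome = outcome_label_by_group[group]
        for i in range(n_per_group):
            sid = f"{group}{i:04d}"
            sub_rng = np.random.default_rng(child_seeds[idx])
            idx += 1
            contours: dict = {}
            images: dict = {}
            for plane in planes:
                for phase in phases:
                    cell = (plane, phase)
                    if missing_phase_rate > 0 and sub_rng.random() < missing_phase_rate:
                        continue
                    kw = _resolve_cell_params(params, cell)
                    cspec = ContourSpec(**{**kw,
                                           "seed": int(sub_rng.integers(2 ** 31))})
                    if plane == "lvot":
                        cspec = replace(cspec, base_radius_mm=cspec.base_radius_mm
                                        * lvot_radius_factor)
                    if phase == "systole":
                        cspec = replace(cspec, base_radius_mm=cspec.base_radius_mm * 1.05)
                    contour = generate_fractal_contour(cspec)
                    contours[cell] = contour
                    if render is not None:
                        rspec = replace(render, seed=int(sub_rng.integers(2 ** 31)))
                        images[cell] = render_ct_slice(contour, rspec, plane=plane,
                                                       phase=phase, subject_id=sid)
            record = SubjectRecord(
                subject_id=sid,
                pvr_grade=outcome.get("pvr_grade"),
                composite_endpoint=outcome.get("composite_endpoint"))
            subjects.append(CohortSubject(subject_id=sid, group=group,
                                          contours=contours, images=images,
                                          record=record))
    return subjects


def write_cohort(subjects: list[CohortSubject], out_dir) -> Path:
    """Write TIFFs and a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "plane", "phase", "image_path", "group",
                         "pvr_grade", "composite_endpoint", "mm_per_pixel"])
        for sub in subjects:
            for (plane, phase), image in sorted(sub.images.items()):
                name = f"{sub.subject_id}_{plane}_{phase}.tif"
                write_tiff(image, img_dir / name)
                writer.writerow([
                    sub.subject_id, plane, phase, f"images/{name}", sub.group,
                    sub.record.pvr_grade or "",
                    "" if sub.record.composite_endpoint is None
                    else int(sub.record.composite_endpoint),
                    repr(image.mm_per_pixel),
                ])
    return manifest
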