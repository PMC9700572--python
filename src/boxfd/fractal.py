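"""Fixed-grid box-counting fractal dimension of a border contour.

The plane is partitioned into axis-aligned s x s boxes anchored at a single
grid origin per run ("fixed grid": no origin averaging by default). For each
caliber s the number of boxes whose *closed* square intersects the polyline
is counted by exact segment-box clipping, not rasterization; a segment lying
exactly on a shared box edge counts for both adjacent boxes, which removes
tie ambiguity deterministically.

The dimension is the absolute slope of the ordinary-least-squares line of
ln(count) on ln(caliber).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .contours import ContourPolyline
from .errors import DegenerateCaliberError, InsufficientScalesError, InvalidParameterError

__all__ = ["FdConfig", "BoxCountCurve", "FDResult", "default_calibers",
           "box_count", "fit_fd", "compute_fd"]

#: slab-test slack in grid units; absorbs the rounding of (x - origin)/s
_EPS = 1e-9


@dataclass(frozen=True)
class FdConfig:
    """Caliber range/spacing and grid anchoring for an FD run."""

    caliber_min_mm: float = 0.8
    caliber_max_mm: float = 6.75
    n_calibers: int = 10
    spacing: str = "log"            # "log" or "linear"
    grid_origin: tuple[float, float] = (0.0, 0.0)
    origin_shifts: int = 0          # >0 enables origin-averaging (sensitivity mode)
    rasterized: bool = False        # legacy pixel-sampling counts instead of exact clipping

    def __post_init__(self):
        if not (0 < self.caliber_min_mm < self.caliber_max_mm):
            raise InvalidParameterError("need 0 < caliber_min_mm < caliber_max_mm")
        if self.n_calibers < 3:
            raise InvalidParameterError("n_calibers must be >= 3")
        if self.spacing not in ("log", "linear"):
            raise InvalidParameterError("spacing must be 'log' or 'linear'")

    def calibers(self) -> np.ndarray:
        return default_calibers(self)


def default_calibers(config: FdConfig | None = None) -> np.ndarray:
    """The caliber ladder for a config (default: 10 log-spaced in [0.8, 6.75] mm)."""
    cfg = config or FdConfig()
    if cfg.spacing == "log":
        return np.geomspace(cfg.caliber_min_mm, cfg.caliber_max_mm, cfg.n_calibers)
    return np.linspace(cfg.caliber_min_mm, cfg.caliber_max_mm, cfg.n_calibers)


@dataclass(frozen=True)
class BoxCountCurve:
    """(caliber, occupied-box count) pairs for one contour and one grid origin."""

    calibers_mm: np.ndarray
    counts: np.ndarray
    grid_origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        cal = np.asarray(self.calibers_mm, dtype=float)
        cnt = np.asarray(self.counts, dtype=float)
        if cal.shape != cnt.shape or cal.ndim != 1:
            raise InvalidParameterError("calibers and counts must be 1D and aligned")
        if np.any(np.diff(cal) <= 0):
            raise InvalidParameterError("calibers must be strictly increasing")
        if np.any(cnt < 1):
            raise InvalidParameterError("every occupied-box count must be >= 1")
        object.__setattr__(self, "calibers_mm", cal)
        object.__setattr__(self, "counts", cnt)

    def __len__(self) -> int:
        return len(self.calibers_mm)


@dataclass(frozen=True)
class FDResult:
    """ln-ln fit summary; fd is the absolute slope."""

    fd: float
    slope: float
    intercept: float
    r_squared: float
    n_calibers: int
    curve: BoxCountCurve | None = field(default=None, compare=False)
    warnings: tuple[str, ...] = ()


def _count_occupied(p: np.ndarray, q: np.ndarray, caliber: float,
                    origin: tuple[float, float]) -> int:
    """Number of closed grid boxes intersected by any segment (p_i, q_i).

    Works in grid units g = (coord - origin) / caliber so box (i, j) is the
    closed unit square [i, i+1] x [j, j+1]. Candidate boxes per segment are
    the cells of its index bounding box padded by one (the pad catches the
    both-sides rule for segments lying exactly on a grid line); an exact
    closed-interval slab test filters them.
    """
    ox, oy = origin
    gp = (p - (ox, oy)) / caliber
    gq = (q - (ox, oy)) / caliber

    lo = np.minimum(gp, gq)
    hi = np.maximum(gp, gq)
    i_lo = np.floor(lo[:, 0]).astype(np.int64) - 1
    i_hi = np.floor(hi[:, 0]).astype(np.int64) + 1
    j_lo = np.floor(lo[:, 1]).astype(np.int64) - 1
    j_hi = np.floor(hi[:, 1]).astype(np.int64) + 1
    ni = i_hi - i_lo + 1
    nj = j_hi - j_lo + 1
    n_cand = ni * nj

    total = int(n_cand.sum())
    seg = np.repeat(np.arange(len(p)), n_cand)
    # local candidate index 0..n_cand[seg]-1 without a Python loop
    starts = np.concatenate(([0], np.cumsum(n_cand)[:-1]))
    local = np.arange(total) - np.repeat(starts, n_cand)
    bi = i_lo[seg] + local // nj[seg]
    bj = j_lo[seg] + local % nj[seg]

    # closed-interval slab clip of segment t in [0,1] against [bi,bi+1]x[bj,bj+1]
    ax, ay = gp[seg, 0], gp[seg, 1]
    dx = gq[seg, 0] - ax
    dy = gq[seg, 1] - ay
    tmin = np.zeros(total)
    tmax = np.ones(total)
    ok = np.ones(total, dtype=bool)
    for a, d, b in ((ax, dx, bi), (ay, dy, bj)):
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (b - a) / d
            t2 = (b + 1 - a) / d
        para = d == 0
        inside = (a >= b - _EPS) & (a <= b + 1 + _EPS)
        ok &= ~para | inside
        t_lo = np.minimum(t1, t2)
        t_hi = np.maximum(t1, t2)
        t_lo = np.where(para, 0.0, t_lo)
        t_hi = np.where(para, 1.0, t_hi)
        tmin = np.maximum(tmin, t_lo)
        tmax = np.minimum(tmax, t_hi)
    ok &= tmin <= tmax + _EPS

    cells = np.stack([bi[ok], bj[ok]], axis=1)
    if len(cells) == 0:
        return 0
    return len(np.unique(cells, axis=0))


def _count_rasterized(p: np.ndarray, q: np.ndarray, caliber: float,
                      origin: tuple[float, float]) -> int:
    """Legacy variant: bin dense sample points along the polyline into cells."""
    lengths = np.linalg.norm(q - p, axis=1)
    n_steps = np.maximum(1, np.ceil(lengths / (caliber / 8.0)).astype(int))
    pts = [np.linspace(0, 1, n + 1)[:, None] * (qi - pi) + pi
           for pi, qi, n in zip(p, q, n_steps)]
    pts = np.concatenate(pts, axis=0)
    cells = np.floor((pts - np.asarray(origin)) / caliber).astype(np.int64)
    return len(np.unique(cells, axis=0))


def box_count(contour: ContourPolyline, calibers_mm,
              grid_origin: tuple[float, float] = (0.0, 0.0),
              rasterized: bool = False) -> BoxCountCurve:
    """Count occupied boxes at each caliber with one fixed grid origin."""
    calibers = np.asarray(calibers_mm, dtype=float)
    if calibers.ndim != 1 or len(calibers) == 0:
        raise InvalidParameterError("calibers_mm must be a non-empty 1D sequence")
    if np.any(calibers <= 0):
        raise InvalidParameterError("calibers must be positive")
    if np.any(np.diff(calibers) <= 0):
        raise InvalidParameterError("calibers must be strictly increasing")
    xmin, ymin, xmax, ymax = contour.bounds()
    diag = float(np.hypot(xmax - xmin, ymax - ymin))
    if calibers[-1] > diag:
        raise DegenerateCaliberError(
            f"caliber {calibers[-1]:g} mm exceeds contour bounding-box diagonal {diag:g} mm")
    p, q = contour.segments()
    counter = _count_rasterized if rasterized else _count_occupied
    counts = np.array([counter(p, q, float(s), grid_origin) for s in calibers],
                      dtype=float)
    return BoxCountCurve(calibers, counts, grid_origin=tuple(grid_origin))


def fit_fd(curve: BoxCountCurve) -> FDResult:
    """OLS of ln(count) on ln(caliber); fd = |slope|."""
    if len(curve) < 3:
        raise InsufficientScalesError(
            f"need >= 3 calibers to fit a slope, got {len(curve)}")
    x = np.log(curve.calibers_mm)
    y = np.log(curve.counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    fd = abs(float(slope))
    warns = []
    if ss_tot == 0:
        warns.append("all box counts equal; slope 0 is not a valid curve dimension")
    if not 1.0 <= fd <= 2.0:
        warns.append(f"fd {fd:.4f} outside [1, 2] expected for closed planar curves")
    return FDResult(fd=fd, slope=float(slope), intercept=float(intercept),
                    r_squared=r_squared, n_calibers=len(curve), curve=curve,
                    warnings=tuple(warns))


def compute_fd(contour: ContourPolyline, config: FdConfig | None = None) -> FDResult:
    """box_count + fit_fd under a config; deterministic; keeps the curve for audit.

    With ``origin_shifts = k > 0``, counts are averaged over k diagonal grid
    shifts (sensitivity mode); the default k = 0 is the single fixed grid.
    """
    cfg = config or FdConfig()
    calibers = cfg.calibers()
    if cfg.origin_shifts > 0:
        ox, oy = cfg.grid_origin
        all_counts = []
        for i in range(cfg.origin_shifts):
            frac = i / cfg.origin_shifts
            shifted = box_count(contour, calibers,
                                grid_origin=(ox + frac * calibers[0], oy + frac * calibers[0]),
                                rasterized=cfg.rasterized)
            all_counts.append(shifted.counts)
        counts = np.mean(all_counts, axis=0)
        curve = BoxCountCurve(calibers, counts, grid_origin=cfg.grid_origin)
    else:
        curve = box_count(contour, calibers, grid_origin=cfg.grid_origin,
                          rasterized=cfg.rasterized)
    result = fit_fd(curve)
    for w in result.warnings:
        warnings.warn(w, stacklevel=2)
    return result
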