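"""Cohort-level inference: group comparison of FD by outcome, ROC with
Youden cutoff, correlation against conventional measures, and
automatic-vs-manual agreement.

Summary style is median (IQR); groups are compared by Mann-Whitney U
(exact permutation p for small tie-free samples, otherwise the normal
approximation with tie and continuity corrections). The AUC confidence
interval uses the Hanley-McNeil standard error. Agreement is Cronbach's
alpha plus the two-way random-effects, absolute-agreement, single-measures
ICC — ICC(A,1) in McGraw-Wong terms — with an F-based 95% CI. Missing
plane/phase measurements are excluded listwise per contrast, never imputed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InsufficientDataError, InvalidParameterError
from .fractal import FDResult
from .geometry import GeometryMeasures

__all__ = [
    "PVR_GRADES", "SubjectRecord", "RocResult", "AgreementResult",
    "mann_whitney_u", "pearson_correlation", "roc_analysis", "agreement",
    "compare_cohort", "pvr_positive",
]

PVR_GRADES = ("none", "trace", "mild", "moderate", "severe")
#: grades counted as outcome-positive: the mild-or-greater dichotomy
_PVR_POSITIVE = frozenset({"mild", "moderate", "severe"})

PLANE_PHASE_CELLS = (("annulus", "diastole"), ("annulus", "systole"),
                     ("lvot", "diastole"), ("lvot", "systole"))


def pvr_positive(grade: str) -> bool:
    """True for mild/moderate/severe; False for none/trace."""
    if grade not in PVR_GRADES:
        raise InvalidParameterError(f"unknown PVR grade {grade!r}")
    return grade in _PVR_POSITIVE


@dataclass
class SubjectRecord:
    """One subject's measurements and outcomes; entries may be absent."""

    subject_id: str
    fd_by_plane_phase: dict[tuple[str, str], FDResult] = field(default_factory=dict)
    geometry: dict[tuple[str, str], GeometryMeasures] = field(default_factory=dict)
    pvr_grade: str | None = None
    composite_endpoint: bool | None = None

    def __post_init__(self):
        if self.pvr_grade is not None and self.pvr_grade not in PVR_GRADES:
            raise InvalidParameterError(f"unknown PVR grade {self.pvr_grade!r}")


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class AgreementResult:
    cronbach_alpha: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    n: int


def _clean(values, name) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise InvalidParameterError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{name} contains non-finite values")
    return arr


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U; returns (U of group_a, p).

    Exact permutation null when n_a + n_b <= 20 with no ties, otherwise the
    normal approximation with tie correction and continuity correction.
    """
    a = _clean(group_a, "group_a")
    b = _clean(group_b, "group_b")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment r with two-tailed p from the t transform (n - 2 df)."""
    xa = _clean(x, "x")
    ya = _clean(y, "y")
    if len(xa) != len(ya):
        raise InvalidParameterError("x and y must have equal length")
    if len(xa) < 3:
        raise InvalidParameterError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(p)


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the concordance statistic with ties counted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
           + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def roc_analysis(scores, labels) -> RocResult:
    """Empirical ROC: AUC (ties 1/2), Hanley-McNeil 95% CI, Youden cutoff.

    Convention: higher score predicts the positive label; a subject is called
    positive when score >= cutoff. Youden ties break toward the smallest
    cutoff.
    """
    s = _clean(scores, "scores")
    lab = np.asarray(labels).ravel()
    if len(s) != len(lab):
        raise InvalidParameterError("scores and labels must have equal length")
    lab = lab.astype(int)
    if not set(np.unique(lab)) <= {0, 1}:
        raise InvalidParameterError("labels must be binary 0/1")
    n1 = int((lab == 1).sum())
    n0 = int((lab == 0).sum())
    if n1 == 0 or n0 == 0:
        raise InvalidParameterError("both label classes must be present")

    auc = _auc_mann_whitney(s, lab)
    se = _hanley_mcneil_se(auc, n1, n0)
    ci_low = max(0.0, auc - 1.959963984540054 * se)
    ci_high = min(1.0, auc + 1.959963984540054 * se)

    cutoffs = np.unique(s)
    called_pos = s[None, :] >= cutoffs[:, None]
    sens = (called_pos & (lab == 1)).sum(axis=1) / n1
    spec = (~called_pos & (lab == 0)).sum(axis=1) / n0
    youden = sens + spec - 1.0
    best = int(np.flatnonzero(youden == youden.max())[0])  # smallest cutoff wins ties
    return RocResult(auc=auc, ci_low=ci_low, ci_high=ci_high,
                     cutoff=float(cutoffs[best]),
                     sensitivity=float(sens[best]), specificity=float(spec[best]),
                     n_positive=n1, n_negative=n0)


def agreement(auto, manual, ci_level: float = 0.95) -> AgreementResult:
    """Cronbach's alpha (2 raters) and ICC(A,1) with F-based CI."""
    a = _clean(auto, "auto")
    m = _clean(manual, "manual")
    if len(a) != len(m):
        raise InvalidParameterError("auto and manual must be paired (equal length)")
    n = len(a)
    if n < 3:
        raise InvalidParameterError("need at least 3 paired measurements")

    var_sum = np.var(a + m, ddof=1)
    if var_sum == 0:
        alpha_c = 1.0 if np.var(a, ddof=1) == 0 else 0.0
    else:
        alpha_c = 2.0 * (1.0 - (np.var(a, ddof=1) + np.var(m, ddof=1)) / var_sum)

    # two-way ANOVA mean squares, k = 2 raters
    k = 2
    data = np.stack([a, m], axis=1)
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    icc = 0.0 if denom == 0 else float((msr - mse) / denom)

    # McGraw-Wong CI for ICC(A,1)
    if mse == 0 and msc == 0:
        lo = hi = icc
    else:
        alpha_tail = (1.0 - ci_level) / 2.0
        fj = msc / mse if mse > 0 else np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
            vd = ((n - 1) * k ** 2 * icc ** 2 * fj ** 2
                  + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
            v = vn / vd if np.isfinite(fj) else float(n - 1)
        f1 = sps.f.ppf(1 - alpha_tail, n - 1, v)
        f2 = sps.f.ppf(1 - alpha_tail, v, n - 1)
        lo_den = f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        hi_den = k * msc + (k * n - k - n) * mse + n * f2 * msr
        lo = float(n * (msr - f1 * mse) / lo_den) if lo_den != 0 else icc
        hi = float(n * (f2 * msr - mse) / hi_den) if hi_den != 0 else icc
    return AgreementResult(cronbach_alpha=float(alpha_c), icc=icc,
                           icc_ci_low=min(lo, icc), icc_ci_high=max(hi, icc), n=n)


def _group_of(record: SubjectRecord, grouping: str) -> bool | None:
    """Outcome-positive flag for a record under the grouping rule; None if unknown."""
    if grouping == "pvr":
        if record.pvr_grade is None:
            return None
        return pvr_positive(record.pvr_grade)
    if grouping == "composite":
        return record.composite_endpoint
    raise InvalidParameterError(f"unknown grouping rule {grouping!r}")


def _median_iqr(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "n": int(len(values))}


def compare_cohort(records: Sequence[SubjectRecord], grouping: str = "pvr",
                   target: tuple[str, str] = ("annulus", "diastole"),
                   holm: bool = False) -> dict:
    """Group comparison of FD per plane x phase cell plus ROC on the target cell.

    Subjects missing a cell's measurement (or the outcome) are excluded
    listwise per contrast. Raises InsufficientDataError when the target cell
    has fewer than 2 subjects in either group.
    """
    cells: dict = {}
    tested = []
    for cell in PLANE_PHASE_CELLS:
        neg, pos = [], []
        for rec in records:
            flag = _group_of(rec, grouping)
            fd = rec.fd_by_plane_phase.get(cell)
            if flag is None or fd is None:
                continue
            (pos if flag else neg).append(fd.fd)
        entry: dict = {"plane": cell[0], "phase": cell[1],
                       "n_negative": len(neg), "n_positive": len(pos)}
        if len(neg) >= 2 and len(pos) >= 2:
            u, p = mann_whitney_u(neg, pos)
            entry.update(negative=_median_iqr(np.array(neg)),
                         positive=_median_iqr(np.array(pos)),
                         mann_whitney_u=u, p_value=p)
            tested.append(cell)
        else:
            entry["skipped"] = "fewer than 2 subjects per group"
            if cell == tuple(target):
                raise InsufficientDataError(
                    f"target contrast {cell} has fewer than 2 subjects per group")
        cells[f"{cell[0]}_{cell[1]}"] = entry

    if holm and tested:
        ps = np.array([cells[f"{c[0]}_{c[1]}"]["p_value"] for c in tested])
        order = np.argsort(ps)
        adj = np.empty_like(ps)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(ps) - rank) * ps[idx])
            adj[idx] = min(1.0, running)
        for c, p_adj in zip(tested, adj):
            cells[f"{c[0]}_{c[1]}"]["p_value_holm"] = float(p_adj)

    # ROC on the primary contrast
    scores, labels = [], []
    for rec in records:
        flag = _group_of(rec, grouping)
        fd = rec.fd_by_plane_phase.get(tuple(target))
        if flag is None or fd is None:
            continue
        scores.append(fd.fd)
        labels.append(int(flag))
    roc = roc_analysis(scores, labels)
    return {"grouping": grouping, "target": list(target), "cells": cells,
            "roc": roc, "n_subjects": len(records)}
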