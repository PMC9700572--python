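"""Cohort-level inference-recovery simulations.

These drive the synthetic generator -> fractal dimension -> cohort
statistics chain many times to measure operating characteristics of the
whole pipeline: type-I error under a roughness-equal null and power/AUC
under a planted roughness contrast. Contours are evaluated directly
(render=None); the image round trip is validated separately and would only
add identical noise to both groups.
"""
from __future__ import annotations

import numpy as np

from .cohort_stats import compare_cohort
from .fractal import FdConfig, compute_fd
from .synthetic import generate_cohort

__all__ = ["cohort_fd_contrast", "simulate_null_type1", "simulate_planted"]

#: fast-but-faithful settings for Monte-Carlo loops: fewer vertices and
#: calibers than the per-image default, same method throughout
FAST_FD = FdConfig(n_calibers=6)
FAST_CONTOUR = {"base_radius_mm": 12.0, "hurst_exponent": 0.4, "n_vertices": 128}

TARGET = ("annulus", "diastole")


def cohort_fd_contrast(n_per_group: int, params_a: dict, params_b: dict,
                       seed: int, fd_config: FdConfig = FAST_FD) -> dict:
    """Generate one two-group cohort, compute FD per subject, compare groups.

    Returns the target-cell Mann-Whitney p, the ROC result and the group
    medians. Only the target plane/phase cell is generated.
    """
    subjects = generate_cohort(
        n_per_group=n_per_group,
        contour_params_by_group={"A": params_a, "B": params_b},
        outcome_label_by_group={"A": {"pvr_grade": "none"},
                                "B": {"pvr_grade": "mild"}},
        seed=seed, planes=(TARGET[0],), phases=(TARGET[1],))
    records = []
    for sub in subjects:
        sub.record.fd_by_plane_phase[TARGET] = compute_fd(sub.contours[TARGET],
                                                          fd_config)
        records.append(sub.record)
    report = compare_cohort(records, grouping="pvr", target=TARGET)
    cell = report["cells"]["annulus_diastole"]
    return {"p_value": cell["p_value"], "roc": report["roc"],
            "median_a": cell["negative"]["median"],
            "median_b": cell["positive"]["median"]}


def simulate_null_type1(n_cohorts: int, n_per_group: int, seed: int,
                        alpha: float = 0.05,
                        roughness_amplitude: float = 0.04) -> dict:
    """Rejection rate of the target contrast across roughness-equal cohorts."""
    params = {**FAST_CONTOUR, "roughness_amplitude": roughness_amplitude}
    root = np.random.SeedSequence(seed)
    rejections = 0
    for i, child in enumerate(root.spawn(n_cohorts)):
        cohort_seed = int(np.random.default_rng(child).integers(2 ** 31))
        res = cohort_fd_contrast(n_per_group, params, params, cohort_seed)
        if res["p_value"] < alpha:
            rejections += 1
    return {"type1_rate": rejections / n_cohorts, "n_cohorts": n_cohorts,
            "n_per_group": n_per_group, "alpha": alpha}


def simulate_planted(n_reps: int, n_per_group: int, seed: int,
                     roughness_a: float = 0.03, roughness_b: float = 0.039,
                     alpha: float = 0.05, auc_floor: float = 0.65) -> dict:
    """Planted roughness contrast: how often is it detected?"""
    params_a = {**FAST_CONTOUR, "roughness_amplitude": roughness_a}
    params_b = {**FAST_CONTOUR, "roughness_amplitude": roughness_b}
    root = np.random.SeedSequence(seed + 1)
    significant = auc_hits = 0
    gaps = []
    aucs = []
    for child in root.spawn(n_reps):
        cohort_seed = int(np.random.default_rng(child).integers(2 ** 31))
        res = cohort_fd_contrast(n_per_group, params_a, params_b, cohort_seed)
        if res["p_value"] < alpha:
            significant += 1
        if res["roc"].auc > auc_floor:
            auc_hits += 1
        gaps.append(res["median_b"] - res["median_a"])
        aucs.append(res["roc"].auc)
    return {"power": significant / n_reps, "auc_success_rate": auc_hits / n_reps,
            "median_fd_gap": float(np.median(gaps)),
            "median_auc": float(np.median(aucs)),
            "n_reps": n_reps, "n_per_group": n_per_group}
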