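"""Ground-truth evaluation helpers for the synthetic suite."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["match_points", "detection_metrics"]


def match_points(
    detected: np.ndarray,
    truth: np.ndarray,
    radius: float,
) -> list[tuple[int, int]]:
    """One-to-one matching of detected points to ground-truth points.

    Optimal (Hungarian) assignment on Euclidean distance; pairs farther
    apart than ``radius`` are not matched. Points are ``(n, 2)`` arrays of
    ``(x, y)``. Returns the list of matched ``(detected_idx, truth_idx)``.
    """
    detected = np.atleast_2d(np.asarray(detected, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if detected.size == 0 or truth.size == 0:
        return []
    d = cdist(detected, truth)
    big = radius * 1e6 + 1.0
    cost = np.where(d <= radius, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if d[i, j] <= radius]


def detection_metrics(
    detected: np.ndarray,
    truth: np.ndarray,
    radius: float = 2.0,
) -> dict:
    """Recall, precision, and mean localization error of detected centroids."""
    pairs = match_points(detected, truth, radius)
    n_match = len(pairs)
    recall = n_match / len(truth) if len(truth) else float("nan")
    precision = n_match / len(detected) if len(detected) else float("nan")
    if n_match:
        det = np.atleast_2d(detected)
        tru = np.atleast_2d(truth)
        errs = [float(np.linalg.norm(det[i] - tru[j])) for i, j in pairs]
        mean_err = float(np.mean(errs))
        max_err = float(np.max(errs))
    else:
        mean_err = max_err = float("nan")
    return {
        "n_true": len(truth),
        "n_detected": len(detected),
        "n_matched": n_match,
        "recall": recall,
        "precision": precision,
        "mean_localization_error": mean_err,
        "max_localization_error": max_err,
    }
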