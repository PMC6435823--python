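"""Optical quantal analysis: event detection, AZ assignment, Pr estimation.

Stimulus-locked postsynaptic Ca2+ events are detected in baseline-subtracted
movies (a peak counts only if it persists and decays over subsequent
frames), assigned to the nearest punctum centroid by Euclidean distance,
and converted to a per-AZ release probability estimate
``Pr = distinct-stimulus event count / n_stimuli``. Per-NMJ Pearson
correlations between punctum intensity and Pr quantify how predictive
channel abundance is of release.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max
from skimage.filters import gaussian as _gaussian_filter, unsharp_mask

from .puncta import PunctaTable
from .synthetic import EventStream, Movie

__all__ = [
    "ReleaseTable",
    "CorrelationResult",
    "detect_events",
    "assign_events",
    "estimate_pr",
    "correlate_intensity_pr",
    "binomial_ci",
    "preset_live_tagrfp",
]


@dataclass(frozen=True)
class ReleaseTable:
    """Per-punctum release counts and Pr estimates over n stimuli.

    ``table`` columns: ``punctum_id, event_count, n_stimuli, pr_estimate``
    where ``event_count`` counts *distinct stimuli* with at least one
    assigned event (release is per-stimulus binary).
    """

    table: pd.DataFrame
    n_stimuli: int
    unassigned_event_count: int = 0

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class CorrelationResult:
    """Per-NMJ and pooled intensity-Pr correlation."""

    per_nmj: pd.DataFrame  # columns: nmj, n_az, r, p
    average_r: float
    excluded: list = dc_field(default_factory=list)  # (nmj, reason)


def preset_live_tagrfp(image) -> np.ndarray:
    """Mask-channel preprocessing preset for live punctum images:
    Gaussian filter (sigma 2) followed by an unsharp mask (radius 3,
    weight 0.8) to sharpen closely spaced puncta before thresholding."""
    arr = np.asarray(image, dtype=float)
    smooth = _gaussian_filter(arr, sigma=2.0, preserve_range=True)
    return unsharp_mask(smooth, radius=3.0, amount=0.8, preserve_range=True)


def detect_events(
    movie: Movie,
    baseline_frames: np.ndarray | None = None,
    threshold: float | None = None,
    persistence: int = 2,
    match_radius: float = 3.0,
    decay_slack: float = 0.25,
    floor_frac: float = 0.05,
) -> EventStream:
    """Detect stimulus-locked events in a movie.

    The baseline image (mean of ``baseline_frames``; default every frame
    before the first stimulus) is subtracted from all frames. In each
    stimulus frame, local maxima above ``threshold`` become events only if
    a maximum persists within ``match_radius`` px for at least
    ``persistence`` subsequent frames with non-increasing amplitude
    (tolerance ``decay_slack`` relative to the previous frame) that stays
    above ``floor_frac`` of the initial amplitude. Event coordinates are the
    thresholded-maximum pixel (no sub-pixel fit).
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    frames = movie.frames
    stim = np.asarray(movie.stim_frames)
    if stim.size and stim[-1] >= len(frames):
        raise ValueError("stim_frames beyond movie length")
    if baseline_frames is None:
        first = stim[0] if stim.size else len(frames)
        baseline_frames = np.arange(min(first, 10))
    baseline_frames = np.asarray(baseline_frames)
    if baseline_frames.size == 0:
        raise ValueError("baseline_frames must be nonempty")
    if np.intersect1d(baseline_frames, stim).size:
        raise ValueError("baseline_frames must be disjoint from stim_frames")
    baseline = frames[baseline_frames].mean(axis=0)
    dff = frames - baseline[None]
    if threshold is None:
        threshold = 5.0 * float(dff[baseline_frames].std())

    rows = []
    r_int = max(int(np.ceil(match_radius)), 1)
    n_frames = len(frames)
    for s_idx, f0 in enumerate(stim):
        peaks = peak_local_max(
            dff[f0], threshold_abs=threshold, min_distance=r_int, exclude_border=False
        )
        for py, px in peaks:
            amp0 = dff[f0, py, px]
            prev = amp0
            ok = True
            for j in range(1, persistence + 1):
                fj = f0 + j
                if fj >= n_frames:
                    ok = False
                    break
                y0, y1 = max(py - r_int, 0), py + r_int + 1
                x0, x1 = max(px - r_int, 0), px + r_int + 1
                amp = dff[fj, y0:y1, x0:x1].max()
                if amp > prev * (1.0 + decay_slack) or amp < floor_frac * amp0:
                    ok = False
                    break
                prev = amp
            if ok:
                rows.append((int(s_idx), int(px), int(py)))
    df = pd.DataFrame(rows, columns=["stimulus_index", "x", "y"])
    return EventStream(events=df, n_stimuli=max(len(stim), 1))


def assign_events(
    events: EventStream | pd.DataFrame,
    puncta: PunctaTable | pd.DataFrame,
    max_radius: float | None = None,
) -> pd.DataFrame:
    """Assign each event to the punctum with minimal Euclidean centroid distance.

    Ties break to the lowest ``punctum_id``. If ``max_radius`` is set,
    events farther than it from every centroid are flagged unassigned
    (``punctum_id = -1``). Returns a DataFrame with columns
    ``stimulus_index, x, y, punctum_id, distance``.
    """
    ev = events.events if isinstance(events, EventStream) else events
    pt = puncta.table if isinstance(puncta, PunctaTable) else puncta
    if len(pt) == 0:
        raise ValueError("puncta table is empty")
    pt = pt.sort_values("punctum_id", ignore_index=True)
    out = ev[["stimulus_index", "x", "y"]].copy()
    if len(ev) == 0:
        out["punctum_id"] = pd.Series(dtype=int)
        out["distance"] = pd.Series(dtype=float)
        return out
    d = cdist(ev[["x", "y"]].to_numpy(float), pt[["x", "y"]].to_numpy(float))
    idx = d.argmin(axis=1)  # argmin returns the first (lowest id) on ties
    dist = d[np.arange(len(ev)), idx]
    pid = pt["punctum_id"].to_numpy()[idx]
    if max_radius is not None:
        unassigned = dist > max_radius
        pid = np.where(unassigned, -1, pid)
    out["punctum_id"] = pid.astype(int)
    out["distance"] = dist
    return out


def estimate_pr(
    assignments: pd.DataFrame,
    n_stimuli: int,
    punctum_ids: np.ndarray | PunctaTable | None = None,
) -> ReleaseTable:
    """Estimate per-punctum release probability from assigned events.

    Duplicate events for one punctum within one stimulus collapse to a
    single release, so ``pr_estimate`` lies in [0, 1]. ``punctum_ids``
    (or a PunctaTable) fixes the output rows so zero-count puncta appear.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    if isinstance(punctum_ids, PunctaTable):
        punctum_ids = punctum_ids.table["punctum_id"].to_numpy()
    assigned = assignments[assignments["punctum_id"] >= 0]
    n_unassigned = int(len(assignments) - len(assigned))
    distinct = assigned[["punctum_id", "stimulus_index"]].drop_duplicates()
    counts = distinct.groupby("punctum_id").size()
    if punctum_ids is None:
        punctum_ids = counts.index.to_numpy()
    counts = counts.reindex(np.asarray(punctum_ids), fill_value=0)
    df = pd.DataFrame(
        {
            "punctum_id": counts.index.to_numpy(int),
            "event_count": counts.to_numpy(int),
            "n_stimuli": n_stimuli,
            "pr_estimate": counts.to_numpy(float) / n_stimuli,
        }
    )
    return ReleaseTable(table=df, n_stimuli=n_stimuli, unassigned_event_count=n_unassigned)


def binomial_ci(
    count: np.ndarray | int,
    n: int,
    confidence: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Clopper-Pearson confidence interval for a binomial proportion."""
    k = np.atleast_1d(np.asarray(count, dtype=float))
    alpha = 1.0 - confidence
    lo = np.where(k == 0, 0.0, stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = np.where(k == n, 1.0, stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def correlate_intensity_pr(
    nmj_tables,
    intensity_col: str = "sum_intensity",
) -> CorrelationResult:
    """Per-NMJ Pearson correlation between punctum intensity and Pr.

    ``nmj_tables`` is a mapping of NMJ name -> ``(PunctaTable, ReleaseTable)``
    (or pre-merged DataFrames with ``intensity_col`` and ``pr_estimate``).
    NMJs with fewer than 3 AZs or zero variance in either variable are
    excluded from the unweighted average r and reported in ``excluded``.
    """
    if not isinstance(nmj_tables, dict):
        nmj_tables = {i: t for i, t in enumerate(nmj_tables)}
    rows = []
    excluded = []
    for name, item in nmj_tables.items():
        if isinstance(item, pd.DataFrame):
            merged = item
        else:
            puncta, release = item
            pt = puncta.table if isinstance(puncta, PunctaTable) else puncta
            rt = release.table if isinstance(release, ReleaseTable) else release
            merged = pt.merge(rt, on="punctum_id", how="inner")
        x = merged[intensity_col].to_numpy(float)
        y = merged["pr_estimate"].to_numpy(float)
        if len(merged) < 3:
            excluded.append((name, "fewer than 3 AZs"))
            continue
        if np.std(x) == 0 or np.std(y) == 0:
            excluded.append((name, "zero variance"))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"nmj": name, "n_az": len(merged), "r": r, "p": p})
    per_nmj = pd.DataFrame(rows, columns=["nmj", "n_az", "r", "p"])
    avg = float(per_nmj["r"].mean()) if len(per_nmj) else float("nan")
    return CorrelationResult(per_nmj=per_nmj, average_r=avg, excluded=excluded)
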