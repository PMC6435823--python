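"""Ratiometric presynaptic Ca2+ transient analysis.

The ratio R(t) of the Ca2+-sensitive channel to a co-loaded insensitive
normalizer removes pathlength and loading differences; stimulus-aligned
sweeps are averaged, the averaged single-AP transient yields a peak
amplitude (delta R) and an exponential decay time constant (tau), and the
train segment yields a plateau amplitude. Preparations with outlying
resting ratios are excluded by a 3x median-absolute-deviation rule, and a
transient passes QC only if its decay tau is below 250 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import TransientRecording

__all__ = [
    "TransientSummary",
    "ratio_trace",
    "average_single_ap_sweeps",
    "peak_and_tau",
    "train_plateau",
    "mad_outlier_filter",
    "qc_transient",
    "analyze_transient",
]

#: decay-time gate: transients must recover with tau strictly below this (s)
TAU_LIMIT = 0.250


@dataclass(frozen=True)
class TransientSummary:
    """Summary statistics of one transient recording."""

    resting_R: float
    single_ap_delta_R: float
    tau: float  # s
    train_delta_R: float
    qc_pass: bool


def ratio_trace(recording: TransientRecording) -> np.ndarray:
    """Elementwise fluorescence ratio R(t) = rhod / af647."""
    if np.any(recording.af647 <= 0):
        raise ValueError("af647 must be > 0 everywhere")
    return recording.rhod / recording.af647


def average_single_ap_sweeps(
    r_trace: np.ndarray,
    time: np.ndarray,
    stimulus_times: np.ndarray,
    window: tuple[float, float] = (-0.05, 0.5),
    train_window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average stimulus-aligned windows of the ratio trace pointwise.

    ``window`` is (pre, post) seconds around each stimulus. Sweeps whose
    window overlaps ``train_window`` are excluded with a warning. Returns
    ``(t_rel, averaged_trace)`` with t_rel = 0 at the stimulus.
    """
    stimulus_times = np.asarray(stimulus_times, dtype=float)
    if stimulus_times.size == 0:
        raise ValueError("at least one stimulus is required")
    dt = float(np.median(np.diff(time)))
    i_pre = int(round(-window[0] / dt))
    i_post = int(round(window[1] / dt))
    sweeps = []
    excluded = 0
    for ts in stimulus_times:
        if train_window is not None and ts + window[1] > train_window[0] and ts + window[0] < train_window[1]:
            excluded += 1
            continue
        i0 = int(round((ts - time[0]) / dt))
        lo, hi = i0 - i_pre, i0 + i_post + 1
        if lo < 0 or hi > len(r_trace):
            raise ValueError("sweep window extends outside the recording")
        sweeps.append(r_trace[lo:hi])
    if excluded:
        warnings.warn(f"excluded {excluded} sweep(s) overlapping the train window")
    if not sweeps:
        raise ValueError("no usable sweeps after exclusions")
    avg = np.mean(sweeps, axis=0)
    t_rel = (np.arange(len(avg)) - i_pre) * dt
    return t_rel, avg


def peak_and_tau(
    t: np.ndarray,
    trace: np.ndarray,
    baseline_window: tuple[float, float] = (-0.05, 0.0),
) -> dict:
    """Peak amplitude and decay time constant of an averaged transient.

    delta_R = max - baseline mean, with baseline taken over
    ``baseline_window`` (which must precede the stimulus at t = 0). The
    decay is fit from the peak onward as ``A*exp(-t/tau) + B`` by nonlinear
    least squares, tau initialized at the time to decay to 1/e of the peak.
    Raises on non-convergence or tau <= 0.
    """
    t = np.asarray(t, dtype=float)
    trace = np.asarray(trace, dtype=float)
    bmask = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not np.any(bmask):
        raise ValueError("empty baseline window")
    baseline = float(trace[bmask].mean())
    i_peak = int(np.argmax(trace))
    if t[i_peak] < 0:
        raise ValueError("peak precedes the stimulus")
    delta = float(trace[i_peak] - baseline)

    td = t[i_peak:] - t[i_peak]
    yd = trace[i_peak:]
    # initialize tau at the time-to-1/e crossing
    target = baseline + delta / np.e
    below = np.nonzero(yd <= target)[0]
    tau0 = float(td[below[0]]) if below.size else float(td[-1] / 3.0)
    tau0 = max(tau0, float(td[1]) if len(td) > 1 else 1e-3)

    def model(tt, a, tau, b):
        return a * np.exp(-tt / tau) + b

    try:
        popt, _ = curve_fit(
            model, td, yd, p0=[delta, tau0, baseline], maxfev=10000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"tau fit did not converge: {exc}") from exc
    tau = float(popt[1])
    if tau <= 0:
        raise RuntimeError("tau fit returned a nonpositive time constant")
    return {"delta_R": delta, "tau": tau, "baseline": baseline}


def train_plateau(
    r_trace: np.ndarray,
    time: np.ndarray,
    train_window: tuple[float, float],
    baseline: float,
    fraction: float = 0.5,
) -> float:
    """Plateau amplitude: mean R over the final ``fraction`` of the train
    window, minus baseline."""
    t0, t1 = train_window
    if t0 < time[0] or t1 > time[-1] + 1e-9:
        raise ValueError("train window outside the recording")
    start = t1 - fraction * (t1 - t0)
    mask = (time >= start) & (time < t1)
    if not np.any(mask):
        raise ValueError("train window contains no samples")
    return float(np.mean(r_trace[mask]) - baseline)


def mad_outlier_filter(
    values: np.ndarray,
    k: float = 3.0,
    scaled: bool = False,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Median-absolute-deviation outlier exclusion.

    ``MAD = median(|x - median(x)|)`` (unscaled by default — the literal
    rule; ``scaled=True`` applies the 1.4826 normal-consistency factor).
    Values within ``[median - k*MAD, median + k*MAD]`` (inclusive) are
    kept. A zero MAD keeps only values equal to the median and warns.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("MAD filter requires at least 3 values")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if scaled:
        mad *= 1.4826
    if mad == 0:
        warnings.warn("MAD is zero; keeping only values equal to the median")
    lo, hi = med - k * mad, med + k * mad
    keep = (x >= lo) & (x <= hi)
    return keep, (lo, hi)


def qc_transient(summary: TransientSummary, tau_limit: float = TAU_LIMIT) -> bool:
    """Pass iff the decay tau is strictly below the limit (default 250 ms)."""
    return bool(np.isfinite(summary.tau) and summary.tau < tau_limit)


def analyze_transient(
    recording: TransientRecording,
    sweep_window: tuple[float, float] = (-0.05, 0.5),
    baseline_window: tuple[float, float] = (-0.05, 0.0),
    plateau_fraction: float = 0.5,
    tau_limit: float = TAU_LIMIT,
) -> TransientSummary:
    """Full single-recording analysis: ratio -> sweep average -> peak/tau ->
    train plateau -> QC."""
    r = ratio_trace(recording)
    train_win = None
    if recording.train is not None:
        train_win = (
            recording.train["start"],
            recording.train["start"] + recording.train["duration"],
        )
    t_rel, avg = average_single_ap_sweeps(
        r, recording.time, recording.stimulus_times, sweep_window, train_win
    )
    fit = peak_and_tau(t_rel, avg, baseline_window)
    resting = fit["baseline"]
    train_dr = float("nan")
    if train_win is not None:
        train_dr = train_plateau(r, recording.time, train_win, resting, plateau_fraction)
    summary = TransientSummary(
        resting_R=resting,
        single_ap_delta_R=fit["delta_R"],
        tau=fit["tau"],
        train_delta_R=train_dr,
        qc_pass=False,
    )
    return TransientSummary(
        resting_R=summary.resting_R,
        single_ap_delta_R=summary.single_ap_delta_R,
        tau=summary.tau,
        train_delta_R=summary.train_delta_R,
        qc_pass=qc_transient(summary, tau_limit),
    )
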