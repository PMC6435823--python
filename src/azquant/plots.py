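"""Minimal figure helpers for reports (cumulative distributions, scaling fits)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .plasticity import ScalingFit, ecdf

__all__ = ["plot_cumulative_distributions", "plot_scaling_fit"]


def plot_cumulative_distributions(groups: dict, path, xlabel: str = "intensity (a.u.)"):
    """Cumulative probability curves of per-AZ intensities per group."""
    fig, ax = plt.subplots(figsize=(4, 3))
    for name, values in groups.items():
        df = ecdf(np.asarray(values, float))
        ax.step(df["value"], df["cumulative_prob"], where="post", label=str(name))
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative probability")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scaling_fit(table, fit: ScalingFit, path):
    """Baseline vs after scatter with unity, additive, multiplicative, and free lines."""
    x = table["baseline"].to_numpy(float)
    ycol = "after_corrected" if "after_corrected" in table.columns else "after_raw"
    y = table[ycol].to_numpy(float)
    xs = np.linspace(0, x.max() * 1.05, 100)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=8, alpha=0.4, color="0.3")
    ax.plot(xs, xs, "k--", lw=1, label="unity")
    ax.plot(xs, xs + fit.additive_c, color="green", lw=1.2, label=f"additive c={fit.additive_c:.1f}")
    ax.plot(xs, fit.multiplicative_m * xs, color="orange", lw=1.2,
            label=f"multiplicative m={fit.multiplicative_m:.2f}")
    ax.plot(xs, fit.free_slope * xs + fit.free_intercept, color="tab:blue", lw=1.2,
            label=f"free fit (R²={fit.r_squared:.2f})")
    ax.set_xlabel("baseline intensity (a.u.)")
    ax.set_ylabel("post-treatment intensity (a.u.)")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
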