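"""Quantal analysis of intracellular NMJ recordings.

Quantal content is the ratio of mean evoked (EJP) to mean miniature (mEJP)
amplitude, computed per recording and then averaged across NMJs of a group
(mean of ratios, not ratio of group means). Recordings pass quality control
only with a resting potential between -60 and -80 mV, input resistance of
at least 5 MOhm, at least 100 analyzed mEJPs, and at least 20 EJPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import unpaired_test
from .synthetic import EphysRecording

__all__ = ["QuantalResult", "recording_qc", "quantal_content", "group_summary"]


@dataclass(frozen=True)
class QuantalResult:
    mean_mejp: float  # mV
    mean_ejp: float  # mV
    quantal_content: float


def recording_qc(recording: EphysRecording) -> bool:
    """Quality gates: Vrest in [-80, -60] mV, Rin >= 5 MOhm, >= 100 mEJPs,
    >= 20 EJPs."""
    return bool(
        -80.0 <= recording.v_rest <= -60.0
        and recording.r_in >= 5.0
        and len(recording.mejp_amplitudes) >= 100
        and len(recording.ejp_amplitudes) >= 20
    )


def quantal_content(recording: EphysRecording, check_qc: bool = True) -> QuantalResult:
    """Per-recording quantal content = mean EJP / mean mEJP."""
    if check_qc and not recording_qc(recording):
        raise ValueError("recording fails quality control")
    mean_mejp = float(np.mean(recording.mejp_amplitudes))
    if mean_mejp == 0:
        raise ValueError("mean mEJP amplitude is zero")
    mean_ejp = float(np.mean(recording.ejp_amplitudes))
    return QuantalResult(
        mean_mejp=mean_mejp, mean_ejp=mean_ejp, quantal_content=mean_ejp / mean_mejp
    )


def group_summary(
    groups: Mapping[str, Sequence],
    control: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group-level quantal-content summary, normalized to a control group.

    ``groups`` maps a group name to a sequence of :class:`EphysRecording`,
    :class:`QuantalResult`, or plain quantal-content numbers. The group
    statistic is the mean of per-recording ratios; ``percent_of_control``
    scales it by the control group's mean. Pairwise tests against control
    use the normality/variance-gated Student / Welch / Mann-Whitney choice.
    """
    if control not in groups:
        raise ValueError(f"unknown control group: {control!r}")

    def _values(items) -> np.ndarray:
        out = []
        for it in items:
            if isinstance(it, EphysRecording):
                out.append(quantal_content(it).quantal_content)
            elif isinstance(it, QuantalResult):
                out.append(it.quantal_content)
            else:
                out.append(float(it))
        return np.asarray(out, dtype=float)

    values = {name: _values(items) for name, items in groups.items()}
    cmean = values[control].mean()
    rows = []
    for name, v in values.items():
        row = {
            "group": name,
            "n": len(v),
            "mean_qc": float(v.mean()),
            "sem_qc": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan"),
            "percent_of_control": float(100.0 * v.mean() / cmean),
        }
        if name == control:
            row.update({"test_name": "", "p": float("nan")})
        else:
            test, _stat, p = unpaired_test(v, values[control], alpha)
            row.update({"test_name": test, "p": p})
        rows.append(row)
    return pd.DataFrame(rows)
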