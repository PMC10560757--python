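"""Per-neuron tuning and response-quality metrics.

Implements the standard selectivity and quality indices for visual-cortex
calcium data:

* ``OSI = (R_prefer - R_orthog) / (R_prefer + R_orthog)`` — contrast ratio of
  the trial-mean response at the preferred direction against the mean of the
  responses at the two orthogonal directions (same temporal frequency).
* ``DSI = (R_prefer - R_opposite) / (R_prefer + R_opposite)`` — same ratio
  against the opposite direction of motion.
* ``Reliability = 2/(T^2 - T) * sum_{i<j} rho(f_i, f_j)`` — mean pairwise
  Pearson correlation between the single-trial df/f traces of the preferred
  condition; requires time-resolved traces.
* ``SNR = (sum_i R_i^2 - n * V) / (n * V)`` — squared trial-mean responses
  against the estimated variance of the trial mean, where
  ``V = mean_i( unbiased within-stimulus variance / repeats )``.  Under this
  estimator a pure-noise neuron has SNR ~ 0 in expectation, so positive SNR
  means the neuron responds above its noise baseline.

Degenerate cases use explicit sentinels: a zero denominator in OSI/DSI gives
NaN; zero noise with nonzero signal gives +inf SNR; Pearson correlations of
zero-variance vectors are 0 by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataio import TraceRecording, TrialResponseTensor
from .stimuli import StimulusSet

__all__ = [
    "pearson_corr",
    "preferred_condition",
    "osi",
    "dsi",
    "reliability",
    "snr",
    "orthogonal_and_opposite",
    "neuron_properties",
]


def pearson_corr(r1: Sequence[float], r2: Sequence[float]) -> float:
    """Pearson correlation with the zero-variance -> 0 convention."""
    x = np.asarray(r1, dtype=float)
    y = np.asarray(r2, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float((xc @ yc) / (sx * sy))


def preferred_condition(t: TrialResponseTensor, neuron_index: int) -> int:
    """Condition id with the maximal trial-mean response; ties -> lowest id."""
    means = t.responses[neuron_index].mean(axis=1)
    if means.size == 0:
        raise ValueError("no conditions")
    best = means.max()
    ids = np.asarray(t.stimuli.condition_ids)
    candidates = ids[np.isclose(means, best, rtol=0.0, atol=0.0)]
    return int(candidates.min())


def osi(r_prefer: float, r_orthog: float) -> float:
    """Orientation selectivity index; NaN when the denominator is zero."""
    denom = r_prefer + r_orthog
    if denom == 0.0:
        return math.nan
    return (r_prefer - r_orthog) / denom


def dsi(r_prefer: float, r_opposite: float) -> float:
    """Direction selectivity index; NaN when the denominator is zero."""
    denom = r_prefer + r_opposite
    if denom == 0.0:
        return math.nan
    return (r_prefer - r_opposite) / denom


def reliability(trial_traces: Sequence[Sequence[float]]) -> float:
    """Mean pairwise Pearson correlation of single-trial df/f traces.

    Zero-variance trials contribute rho = 0 to every pair they are in.
    """
    traces = [np.asarray(f, dtype=float) for f in trial_traces]
    T = len(traces)
    if T < 2:
        raise ValueError("reliability needs at least 2 trials")
    total = 0.0
    for i in range(T):
        for j in range(i + 1, T):
            total += pearson_corr(traces[i], traces[j])
    return 2.0 * total / (T * T - T)


def snr(responses: np.ndarray) -> float:
    """Stimulus SNR of one neuron from its (condition, repeat) amplitudes.

    ``V`` is the unbiased within-stimulus variance averaged over stimuli and
    divided by the per-stimulus repeat count — the estimated variance of a
    trial-mean response.  Returns +inf when V = 0 with nonzero signal and NaN
    when both are zero.
    """
    resp = np.asarray(responses, dtype=float)
    if resp.ndim != 2:
        raise ValueError("responses must be (condition, repeat)")
    n, reps = resp.shape
    if reps < 2:
        raise ValueError("snr needs at least 2 repeats per condition")
    trial_means = resp.mean(axis=1)
    within_var = resp.var(axis=1, ddof=1)
    v = float(np.mean(within_var / reps))
    signal = float(np.sum(trial_means**2))
    if v == 0.0:
        return math.nan if signal == 0.0 else math.inf
    return (signal - n * v) / (n * v)


def orthogonal_and_opposite(
    stimuli: StimulusSet, preferred: int
) -> tuple[list[int], int]:
    """Condition ids of the orthogonal (+/-90 deg) and opposite (+180 deg)
    directions at the preferred condition's temporal frequency.

    Returns ``(orthogonal_ids, opposite_id)``; the orthogonal list has one
    entry when only one of the two +/-90 deg directions exists on the grid.
    """
    if stimuli.task_kind != "grating":
        raise ValueError("orientation geometry requires a grating task")
    cond = next(c for c in stimuli.conditions if c.condition_id == preferred)
    theta = cond.direction_deg
    tf = cond.temporal_frequency_hz
    opposite = stimuli.find_grating((theta + 180.0) % 360.0, tf)
    orthogonal = []
    for delta in (90.0, -90.0):
        try:
            cid = stimuli.find_grating((theta + delta) % 360.0, tf)
        except KeyError:
            continue
        if cid not in orthogonal:
            orthogonal.append(cid)
    if not orthogonal:
        raise KeyError("no orthogonal direction on the condition grid")
    return orthogonal, opposite


@dataclass(frozen=True)
class TuningSummary:
    """Responses entering the selectivity indices for one neuron."""

    preferred: int
    r_prefer: float
    r_orthog: Optional[float]
    r_opposite: Optional[float]


def _tuning_summary(t: TrialResponseTensor, neuron_index: int) -> TuningSummary:
    means = t.responses[neuron_index].mean(axis=1)
    pos = {cid: i for i, cid in enumerate(t.stimuli.condition_ids)}
    preferred = preferred_condition(t, neuron_index)
    r_prefer = float(means[pos[preferred]])
    if t.stimuli.task_kind != "grating":
        return TuningSummary(preferred, r_prefer, None, None)
    orth_ids, opp_id = orthogonal_and_opposite(t.stimuli, preferred)
    r_orth = float(np.mean([means[pos[c]] for c in orth_ids]))
    r_opp = float(means[pos[opp_id]])
    return TuningSummary(preferred, r_prefer, r_orth, r_opp)


def neuron_properties(
    t: TrialResponseTensor, traces: Optional[TraceRecording] = None
) -> pd.DataFrame:
    """Per-neuron property table: preferred condition, OSI, DSI, SNR,
    reliability.

    OSI/DSI are computed for grating tasks only (NaN otherwise); reliability
    needs the time-resolved ``traces`` of the same session (NaN otherwise).
    Rows align with the tensor's neuron table.
    """
    rows = []
    for i in range(t.n_neurons):
        summary = _tuning_summary(t, i)
        row = {
            "neuron_id": int(t.neurons["neuron_id"].iloc[i]),
            "depth_um": float(t.neurons["depth_um"].iloc[i]),
            "layer_label": t.neurons["layer_label"].iloc[i],
            "preferred_condition": summary.preferred,
            "osi": math.nan,
            "dsi": math.nan,
            "snr": snr(t.responses[i]),
            "reliability": math.nan,
        }
        if summary.r_orthog is not None:
            row["osi"] = osi(summary.r_prefer, summary.r_orthog)
            row["dsi"] = dsi(summary.r_prefer, summary.r_opposite)
        if traces is not None:
            row["reliability"] = reliability(
                traces.trial_traces(i, summary.preferred)
            )
        rows.append(row)
    return pd.DataFrame(rows)
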