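"""Synthetic laminar populations with the statistics the decoding analysis assumes.

Neurons are generated per cortical-layer (or imaging-depth) profile.  For
grating tasks each neuron carries a von Mises-style tuning curve over drift
direction::

    mu_i(theta) = baseline + gain * [ (1 - m) * exp(kappa * (cos 2(theta - theta_i) - 1))
                                      + m * exp(kappa * (cos (theta - theta_i) - 1)) ]

where ``theta_i`` is the neuron's preferred direction (uniform over the
circle), ``kappa`` the tuning concentration and ``m`` the direction mix
(m=0: purely orientation tuned, responding equally to opposite directions;
m=1: purely direction tuned).  For image tasks the mean response to each
image is ``baseline + gain * w`` with sparse nonnegative weights drawn once
per neuron.  Single-trial amplitudes are the tuned mean plus Gaussian noise
with per-layer standard deviation — trial-to-trial variability is the one
noise knob, and reliability/SNR are measured outputs, not inputs.

With ``emit_traces`` the generator renders each trial as amplitude times a
fixed on-window response kernel (unit mean, so trial-window averaging
recovers the amplitude exactly) plus white trace noise, at 30 Hz by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dataio import TraceRecording, TrialResponseTensor
from .stimuli import StimulusSet, make_stimulus_set

__all__ = [
    "LayerProfile",
    "generate_population",
    "simulate_depth_series",
    "DEFAULT_DEPTHS_UM",
    "REPRESENTATIVE_DEPTHS",
]

# Representative imaging depth per layer, used when a profile is specified by
# layer label only (middle of each layer's depth range).
REPRESENTATIVE_DEPTHS = {"L2/3": 175.0, "L4": 300.0, "L5": 435.0, "L6": 550.0}

# 11 imaging planes, 70-420 um at 35 um steps, for depth-series simulations.
DEFAULT_DEPTHS_UM = tuple(70.0 + 35.0 * i for i in range(11))


@dataclass(frozen=True)
class LayerProfile:
    """Generative parameters of one layer's (or depth's) neuron population.

    Defaults describe weakly tuned single neurons typical of single-trial
    df/f data: response gain 0.3 df/f on top of a 0.05 df/f baseline, trial
    noise several-fold larger than the tuned signal (noise_sd 1.0), moderate
    tuning concentration (kappa 1.5) and an even orientation/direction mix.
    """

    n_neurons: int
    layer_label: Optional[str] = None
    depth_um: Optional[float] = None
    gain: float = 0.3
    tuning_kappa: float = 1.5
    direction_mix: float = 0.5
    noise_sd: float = 1.0
    baseline: float = 0.05
    area_label: str = "VISp"
    image_sparsity: float = 0.2

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.gain < 0:
            raise ValueError("gain must be nonnegative")
        if self.tuning_kappa < 0:
            raise ValueError("tuning_kappa must be nonnegative")
        if not 0.0 <= self.direction_mix <= 1.0:
            raise ValueError("direction_mix must lie in [0, 1]")
        if not 0.0 < self.image_sparsity <= 1.0:
            raise ValueError("image_sparsity must lie in (0, 1]")
        if self.layer_label is None and self.depth_um is None:
            raise ValueError("profile needs a layer_label or a depth_um")
        if self.depth_um is not None and self.depth_um < 0:
            raise ValueError("depth_um must be nonnegative")

    @property
    def resolved_depth_um(self) -> float:
        if self.depth_um is not None:
            return float(self.depth_um)
        return REPRESENTATIVE_DEPTHS[self.layer_label]


def _tuning_means(
    profile: LayerProfile, preferred_deg: np.ndarray, stimuli: StimulusSet
) -> np.ndarray:
    """(neuron, condition) mean amplitudes for a grating stimulus set."""
    dirs = np.array(
        [c.direction_deg for c in stimuli.conditions], dtype=float
    )
    delta = np.deg2rad(dirs[None, :] - preferred_deg[:, None])
    k = profile.tuning_kappa
    m = profile.direction_mix
    orient = np.exp(k * (np.cos(2.0 * delta) - 1.0))
    direct = np.exp(k * (np.cos(delta) - 1.0))
    return profile.baseline + profile.gain * ((1.0 - m) * orient + m * direct)


def _image_means(
    profile: LayerProfile, rng: np.random.Generator, stimuli: StimulusSet
) -> np.ndarray:
    """Sparse nonnegative per-image weights: Bernoulli(sparsity) x Exp(1)."""
    shape = (profile.n_neurons, stimuli.n_conditions)
    active = rng.random(shape) < profile.image_sparsity
    weights = rng.exponential(scale=1.0, size=shape) * active
    return profile.baseline + profile.gain * weights


def _generate_amplitudes(
    profiles: Sequence[LayerProfile],
    stimuli: StimulusSet,
    seed: int,
    snap_preferred: bool,
) -> tuple[np.ndarray, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    blocks = []
    meta_rows = []
    neuron_id = 0
    grid = None
    if stimuli.task_kind == "grating":
        grid = np.asarray(stimuli.directions(), dtype=float)
    for profile in profiles:
        if stimuli.task_kind == "grating":
            preferred = rng.uniform(0.0, 360.0, size=profile.n_neurons)
            if snap_preferred:
                # snap each preferred direction to the nearest grid direction
                d = np.abs(((grid[None, :] - preferred[:, None]) + 180.0) % 360.0 - 180.0)
                preferred = grid[np.argmin(d, axis=1)]
            means = _tuning_means(profile, preferred, stimuli)
        else:
            means = _image_means(profile, rng, stimuli)
        noise = rng.normal(
            0.0, profile.noise_sd, size=(profile.n_neurons, stimuli.n_conditions, stimuli.n_repeats)
        )
        blocks.append(means[:, :, None] + noise)
        for j in range(profile.n_neurons):
            meta_rows.append(
                {
                    "neuron_id": neuron_id,
                    "depth_um": profile.resolved_depth_um,
                    "layer_label": profile.layer_label,
                    "area_label": profile.area_label,
                }
            )
            neuron_id += 1
    responses = np.concatenate(blocks, axis=0)
    return responses, pd.DataFrame(meta_rows)


def _response_kernel(n_samples: int) -> np.ndarray:
    """Fixed rise-and-decay trial kernel, normalized to unit mean."""
    t = np.arange(n_samples, dtype=float)
    shape = (1.0 - np.exp(-t / max(1.0, 0.1 * n_samples))) * np.exp(
        -t / max(1.0, 0.6 * n_samples)
    )
    mean = shape.mean()
    if mean <= 0:
        return np.ones(n_samples)
    return shape / mean


def generate_population(
    profiles: Sequence[LayerProfile],
    stimuli: StimulusSet,
    seed: int,
    emit_traces: bool = False,
    trial_duration_s: float = 1.0,
    sampling_hz: float = 30.0,
    trace_noise_sd: float = 0.05,
    snap_preferred: bool = False,
) -> Union[TrialResponseTensor, TraceRecording]:
    """Simulate one multi-layer population for a stimulus session.

    The same seed produces bit-identical trial amplitudes whether or not
    traces are emitted: the trace path renders the already-drawn amplitudes
    with the unit-mean kernel and adds white noise from an independent
    stream, so ``trial_average`` on the traces recovers the amplitude tensor
    up to the trace-noise term (exactly, when ``trace_noise_sd`` is 0).

    Parameters
    ----------
    snap_preferred
        Snap each neuron's preferred direction onto the stimulus direction
        grid (grating tasks).  Useful for closed-form checks of tuning
        metrics; off by default so preferred directions are continuous.
    """
    if not profiles:
        raise ValueError("need at least one layer profile")
    if trial_duration_s <= 0:
        raise ValueError("trial_duration_s must be positive")
    if sampling_hz <= 0:
        raise ValueError("sampling_hz must be positive")

    responses, neurons = _generate_amplitudes(profiles, stimuli, seed, snap_preferred)
    tensor = TrialResponseTensor(
        responses=responses, stimuli=stimuli, neurons=neurons, normalized=False
    )
    if not emit_traces:
        return tensor

    n_samples = int(round(trial_duration_s * sampling_hz))
    if n_samples < 2:
        raise ValueError("trial window must span at least 2 samples")
    kernel = _response_kernel(n_samples)

    n, c, r = tensor.responses.shape
    # Randomized presentation order, shared across neurons (one scan).
    order_rng = np.random.default_rng([seed, 3])
    trials = [(ci, ri) for ci in range(c) for ri in range(r)]
    order = order_rng.permutation(len(trials))
    trace_rng = np.random.default_rng([seed, 7])

    total = n_samples * len(trials)
    dff = trace_rng.normal(0.0, trace_noise_sd, size=(n, total)) if trace_noise_sd > 0 else np.zeros((n, total))
    epoch_rows = []
    cond_ids = tensor.stimuli.condition_ids
    for slot, idx in enumerate(order):
        ci, ri = trials[idx]
        start = slot * n_samples
        end = start + n_samples
        dff[:, start:end] += tensor.responses[:, ci, ri][:, None] * kernel[None, :]
        epoch_rows.append(
            {
                "condition_id": cond_ids[ci],
                "repeat_idx": ri,
                "start": start,
                "end": end,
            }
        )
    return TraceRecording(
        dff=dff,
        sampling_hz=sampling_hz,
        epochs=pd.DataFrame(epoch_rows),
        neurons=neurons,
        stimuli=stimuli,
    )


def simulate_depth_series(
    base_profile: LayerProfile,
    stimuli: StimulusSet,
    seed: int,
    depths_um: Optional[Sequence[float]] = None,
    snr_curve: Optional[Union[Mapping[float, float], Callable[[float], float]]] = None,
) -> list[TrialResponseTensor]:
    """One population per imaging depth, sharing all parameters but noise_sd.

    ``snr_curve`` maps depth (um) to the trial noise standard deviation at
    that depth (dict or callable); depths absent from a dict keep the base
    profile's noise_sd.  Default depths are the 11 planes 70-420 um.
    """
    depths = list(DEFAULT_DEPTHS_UM if depths_um is None else depths_um)
    if len(set(depths)) != len(depths):
        raise ValueError("duplicate depths")
    if sorted(depths) != depths:
        raise ValueError("depths must be sorted ascending")

    def noise_at(depth: float) -> float:
        if snr_curve is None:
            return base_profile.noise_sd
        if callable(snr_curve):
            return float(snr_curve(depth))
        return float(snr_curve.get(depth, base_profile.noise_sd))

    out = []
    for i, depth in enumerate(depths):
        profile = replace(
            base_profile,
            depth_um=float(depth),
            layer_label=None,
            noise_sd=noise_at(depth),
        )
        # independent but reproducible per-depth seed, kept below 2**31
        depth_seed = (seed + 7919 * (i + 1)) % (2**31 - 1)
        tensor = generate_population([profile], stimuli, seed=depth_seed)
        out.append(tensor)
    return out
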