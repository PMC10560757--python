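"""Containers, preprocessing and file formats for trial-structured df/f data.

Two in-memory containers carry the pipeline:

* :class:`TraceRecording` — continuous per-neuron df/f time series at a fixed
  sampling rate plus an epoch table mapping each stimulus presentation to a
  half-open window of timepoints.
* :class:`TrialResponseTensor` — one scalar response amplitude per
  (neuron, condition, repeat), with a neuron metadata table (depth, layer,
  area) and the paired stimulus condition table.

Preprocessing follows the standard two-photon decoding recipe: the df/f trace
within each trial window is averaged to a single amplitude per presentation,
then amplitudes are z-scored across trials within each neuron ("normalized
across neurons") so no neuron dominates the population vector by virtue of
its raw fluorescence scale.  A simplified spontaneous-activity correction
(per-neuron mean subtraction) is provided for depth-profile data.

On disk a tensor is a long-form CSV with a JSON sidecar for the condition
table; traces live in an HDF5 container with datasets /dff, /epochs, /neurons.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .stimuli import StimulusSet

__all__ = [
    "TraceRecording",
    "TrialResponseTensor",
    "trial_average",
    "normalize_across_neurons",
    "subtract_spontaneous",
    "read_tensor",
    "write_tensor",
    "read_traces",
    "write_traces",
]

NEURON_COLUMNS = ["neuron_id", "depth_um", "layer_label", "area_label"]
TENSOR_COLUMNS = NEURON_COLUMNS + ["condition_id", "repeat_idx", "response"]


def _check_neuron_table(neurons: pd.DataFrame) -> pd.DataFrame:
    neurons = neurons.copy().reset_index(drop=True)
    for col in ("layer_label", "area_label"):
        if col not in neurons:
            neurons[col] = None
    missing = [c for c in ("neuron_id", "depth_um") if c not in neurons]
    if missing:
        raise ValueError(f"neuron table missing columns: {missing}")
    if neurons["neuron_id"].duplicated().any():
        raise ValueError("duplicate neuron_id in neuron table")
    return neurons[NEURON_COLUMNS]


@dataclass
class TraceRecording:
    """Continuous df/f traces with a stimulus epoch table.

    Attributes
    ----------
    dff : (n_neurons, n_timepoints) float array, df/f units.
    sampling_hz : sampling rate of ``dff``.
    epochs : DataFrame with columns (condition_id, repeat_idx, start, end);
        windows are half-open 0-based ``[start, end)`` timepoint ranges.
    neurons : DataFrame with columns (neuron_id, depth_um, layer_label,
        area_label).
    stimuli : the paired condition table.
    """

    dff: np.ndarray
    sampling_hz: float
    epochs: pd.DataFrame
    neurons: pd.DataFrame
    stimuli: StimulusSet

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be 2-D (neuron, timepoint)")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        self.neurons = _check_neuron_table(self.neurons)
        if len(self.neurons) != self.dff.shape[0]:
            raise ValueError("neuron table length does not match dff rows")
        ep = self.epochs.reset_index(drop=True)
        required = {"condition_id", "repeat_idx", "start", "end"}
        if not required.issubset(ep.columns):
            raise ValueError(f"epoch table must have columns {sorted(required)}")
        if (ep["end"] <= ep["start"]).any():
            raise ValueError("empty or inverted epoch window")
        if (ep["start"] < 0).any() or (ep["end"] > self.dff.shape[1]).any():
            raise ValueError("epoch window beyond trace length")
        order = np.argsort(ep["start"].to_numpy(), kind="stable")
        starts = ep["start"].to_numpy()[order]
        ends = ep["end"].to_numpy()[order]
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("overlapping epoch windows")
        known = set(self.stimuli.condition_ids)
        if not set(ep["condition_id"]).issubset(known):
            raise ValueError("epoch condition_id not present in stimulus set")
        self.epochs = ep

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.dff.shape[1]

    def trial_traces(self, neuron_index: int, condition_id: int) -> list[np.ndarray]:
        """The df/f trace of every repeat of one condition for one neuron."""
        ep = self.epochs[self.epochs["condition_id"] == condition_id]
        ep = ep.sort_values("repeat_idx")
        return [
            self.dff[neuron_index, int(r.start): int(r.end)].copy()
            for r in ep.itertuples()
        ]


@dataclass
class TrialResponseTensor:
    """Scalar response per (neuron, condition, repeat) with metadata.

    ``responses[n, c, r]`` is the trial-averaged df/f amplitude of neuron *n*
    to the *r*-th repeat of the condition at table position *c* (positions
    follow ``stimuli.conditions`` order).
    """

    responses: np.ndarray
    stimuli: StimulusSet
    neurons: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 3:
            raise ValueError("responses must be 3-D (neuron, condition, repeat)")
        if np.isnan(self.responses).any():
            raise ValueError("responses contain missing values")
        if self.responses.shape[1] != self.stimuli.n_conditions:
            raise ValueError("condition axis does not match stimulus set")
        self.neurons = _check_neuron_table(self.neurons)
        if len(self.neurons) != self.responses.shape[0]:
            raise ValueError("neuron table length does not match responses")

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.responses.shape[1]

    @property
    def n_repeats(self) -> int:
        return self.responses.shape[2]

    def condition_index(self, condition_id: int) -> int:
        for i, c in enumerate(self.stimuli.conditions):
            if c.condition_id == condition_id:
                return i
        raise KeyError(f"condition_id {condition_id} not in stimulus set")

    def trial_means(self) -> np.ndarray:
        """(neuron, condition) matrix of across-repeat means."""
        return self.responses.mean(axis=2)

    def as_samples(self, neuron_subset: Optional[Sequence[int]] = None):
        """Flatten to decoder samples: (trials, neurons) X and condition-id y.

        Trials are ordered condition-major then repeat, so row ``c * R + r``
        is repeat *r* of the condition at table position *c*.
        """
        resp = self.responses if neuron_subset is None else self.responses[list(neuron_subset)]
        n, c, r = resp.shape
        X = resp.reshape(n, c * r).T
        y = np.repeat(np.asarray(self.stimuli.condition_ids), r)
        return X, y

    def copy(self) -> "TrialResponseTensor":
        return TrialResponseTensor(
            responses=self.responses.copy(),
            stimuli=self.stimuli,
            neurons=self.neurons.copy(),
            normalized=self.normalized,
        )


def trial_average(rec: TraceRecording) -> TrialResponseTensor:
    """Average each trial's df/f window to one amplitude per presentation.

    Windows are half-open ``[start, end)``.  Every (condition, repeat) pair in
    the epoch table must be present exactly once; repeat indices must form
    0..R-1 for every condition with a common R.
    """
    if rec.epochs.empty:
        raise ValueError("epoch table is empty")
    cond_ids = rec.stimuli.condition_ids
    cond_pos = {cid: i for i, cid in enumerate(cond_ids)}
    reps = rec.epochs.groupby("condition_id")["repeat_idx"].nunique()
    n_rep = int(reps.max())
    if (reps != n_rep).any() or len(reps) != len(cond_ids):
        raise ValueError("every condition must have the same number of repeats")
    out = np.full((rec.n_neurons, len(cond_ids), n_rep), np.nan)
    for row in rec.epochs.itertuples():
        c = cond_pos[int(row.condition_id)]
        r = int(row.repeat_idx)
        window = rec.dff[:, int(row.start): int(row.end)]
        out[:, c, r] = window.mean(axis=1)
    if np.isnan(out).any():
        raise ValueError("epoch table does not cover every (condition, repeat)")
    return TrialResponseTensor(
        responses=out, stimuli=rec.stimuli, neurons=rec.neurons, normalized=False
    )


def normalize_across_neurons(t: TrialResponseTensor) -> TrialResponseTensor:
    """Z-score each neuron over all its (condition, repeat) amplitudes.

    Uses the sample standard deviation (ddof=1).  Neurons with zero variance
    map to all-zeros.  Normalizing an already-normalized tensor is rejected
    rather than silently reapplied.
    """
    if t.normalized:
        raise ValueError("tensor is already normalized")
    n, c, r = t.responses.shape
    if c * r < 2:
        raise ValueError("need at least 2 amplitudes per neuron to normalize")
    flat = t.responses.reshape(n, c * r)
    mean = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (flat - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return TrialResponseTensor(
        responses=out.reshape(n, c, r),
        stimuli=t.stimuli,
        neurons=t.neurons.copy(),
        normalized=True,
    )


def subtract_spontaneous(
    t: TrialResponseTensor, spont_mean: Union[Sequence[float], np.ndarray]
) -> TrialResponseTensor:
    """Subtract a per-neuron spontaneous-activity mean from every amplitude."""
    spont = np.asarray(spont_mean, dtype=float)
    if spont.shape != (t.n_neurons,):
        raise ValueError(
            f"spont_mean length {spont.shape} does not match {t.n_neurons} neurons"
        )
    return TrialResponseTensor(
        responses=t.responses - spont[:, None, None],
        stimuli=t.stimuli,
        neurons=t.neurons.copy(),
        normalized=t.normalized,
    )


# ---------------------------------------------------------------------------
# File formats


def _sidecar_path(path: Union[str, Path]) -> Path:
    return Path(path).with_suffix(".conditions.json")


def write_tensor(t: TrialResponseTensor, path: Union[str, Path]) -> None:
    """Write a tensor as long-form CSV plus a JSON condition-table sidecar."""
    path = Path(path)
    n, c, r = t.responses.shape
    cond_ids = np.asarray(t.stimuli.condition_ids)
    rows = {
        "neuron_id": np.repeat(t.neurons["neuron_id"].to_numpy(), c * r),
        "depth_um": np.repeat(t.neurons["depth_um"].to_numpy(), c * r),
        "layer_label": np.repeat(t.neurons["layer_label"].to_numpy(), c * r),
        "area_label": np.repeat(t.neurons["area_label"].to_numpy(), c * r),
        "condition_id": np.tile(np.repeat(cond_ids, r), n),
        "repeat_idx": np.tile(np.arange(r), n * c),
        "response": t.responses.reshape(-1),
    }
    pd.DataFrame(rows).to_csv(path, index=False)
    sidecar = {"stimuli": t.stimuli.to_dict(), "normalized": bool(t.normalized)}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_tensor(path: Union[str, Path]) -> TrialResponseTensor:
    """Read a long-form CSV tensor written by :func:`write_tensor`."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tensor CSV missing columns: {missing}")
    if df.duplicated(["neuron_id", "condition_id", "repeat_idx"]).any():
        raise ValueError("duplicated (neuron, condition, repeat) keys")
    sidecar = json.loads(_sidecar_path(path).read_text())
    stimuli = StimulusSet.from_dict(sidecar["stimuli"])
    neurons = (
        df.drop_duplicates("neuron_id")[NEURON_COLUMNS]
        .sort_values("neuron_id")
        .reset_index(drop=True)
    )
    neurons["layer_label"] = neurons["layer_label"].where(neurons["layer_label"].notna(), None)
    neurons["area_label"] = neurons["area_label"].where(neurons["area_label"].notna(), None)
    cond_pos = {cid: i for i, cid in enumerate(stimuli.condition_ids)}
    neuron_pos = {nid: i for i, nid in enumerate(neurons["neuron_id"])}
    n = len(neuron_pos)
    c = len(cond_pos)
    r = int(df["repeat_idx"].max()) + 1
    out = np.full((n, c, r), np.nan)
    out[
        df["neuron_id"].map(neuron_pos).to_numpy(),
        df["condition_id"].map(cond_pos).to_numpy(),
        df["repeat_idx"].to_numpy(),
    ] = df["response"].to_numpy()
    if np.isnan(out).any():
        raise ValueError("tensor CSV does not cover every (neuron, condition, repeat)")
    return TrialResponseTensor(
        responses=out,
        stimuli=stimuli,
        neurons=neurons,
        normalized=bool(sidecar.get("normalized", False)),
    )


def write_traces(rec: TraceRecording, path: Union[str, Path]) -> None:
    """Write a trace recording to an HDF5 container."""
    str_dtype = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=rec.dff)
        f.create_dataset(
            "epochs",
            data=rec.epochs[["condition_id", "repeat_idx", "start", "end"]].to_numpy(int),
        )
        g = f.create_group("neurons")
        g.create_dataset("neuron_id", data=rec.neurons["neuron_id"].to_numpy(int))
        g.create_dataset("depth_um", data=rec.neurons["depth_um"].to_numpy(float))
        g.create_dataset(
            "layer_label",
            data=[str(x) if x is not None else "" for x in rec.neurons["layer_label"]],
            dtype=str_dtype,
        )
        g.create_dataset(
            "area_label",
            data=[str(x) if x is not None else "" for x in rec.neurons["area_label"]],
            dtype=str_dtype,
        )
        f.attrs["sampling_hz"] = rec.sampling_hz
        f.attrs["stimuli_json"] = json.dumps(rec.stimuli.to_dict())


def read_traces(path: Union[str, Path]) -> TraceRecording:
    """Read a trace recording written by :func:`write_traces`."""
    with h5py.File(path, "r") as f:
        dff = f["dff"][()]
        ep = pd.DataFrame(
            f["epochs"][()], columns=["condition_id", "repeat_idx", "start", "end"]
        )
        g = f["neurons"]
        def _strings(name):
            return [s.decode() if isinstance(s, bytes) else str(s) for s in g[name][()]]
        neurons = pd.DataFrame(
            {
                "neuron_id": g["neuron_id"][()],
                "depth_um": g["depth_um"][()],
                "layer_label": [s or None for s in _strings("layer_label")],
                "area_label": [s or None for s in _strings("area_label")],
            }
        )
        stimuli = StimulusSet.from_dict(json.loads(f.attrs["stimuli_json"]))
        sampling_hz = float(f.attrs["sampling_hz"])
    return TraceRecording(
        dff=dff, sampling_hz=sampling_hz, epochs=ep, neurons=neurons, stimuli=stimuli
    )
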