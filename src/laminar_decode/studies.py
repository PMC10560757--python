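"""Canonical synthetic study designs for the laminar decoding benchmarks.

Each function assembles one complete in-silico experiment — generator
profiles, stimulus protocol and decoding configuration — and returns the
measured outcome.  These are the desk-scale analogues of the real-data
analyses the pipeline was designed around: a 4-layer "L4 advantage"
experiment, an 11-depth series with a mid-depth SNR peak, a chance-floor
control with untuned neurons, and a population-size sweep.  The analysis
drivers, the test suite and the acceptance script all run these same
recipes, so the numbers they report come from one code path.

Default problem sizes are chosen to keep a full replicate set in the tens of
seconds: 8-direction gratings with 40 repeats for the layer experiments and
32 directions with 24 repeats for the depth series, against the papers'
~75-120 repeats at full scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataio import TrialResponseTensor
from .decoding import DECODER_NAMES, DecodingConfig, DecodingResult, decoder_suite, subsampled_decode
from .layer_stats import accuracy_vs_property, compare_layers, depth_profile, RegressionSummary
from .stimuli import make_stimulus_set
from .synthgen import LayerProfile, generate_population, simulate_depth_series
from .tuning import neuron_properties

__all__ = [
    "layer_profiles_l4_advantage",
    "split_by_layer",
    "l4_advantage_experiment",
    "l4_advantage_replicates",
    "depth_noise_curve",
    "depth_snr_experiment",
    "depth_snr_replicates",
    "chance_floor_experiment",
    "size_sweep_experiment",
]

# Laminar noise profile emulating the reported accuracy ordering: L4 (direct
# thalamic input) at half the trial noise, L5 (broadly tuned) the noisiest.
L4_ADVANTAGE_NOISE = {"L2/3": 1.0, "L4": 0.5, "L5": 1.2, "L6": 1.0}


def layer_profiles_l4_advantage(
    n_neurons_per_layer: int = 100,
) -> list[LayerProfile]:
    """Four-layer profile set with L4's trial noise halved."""
    return [
        LayerProfile(n_neurons=n_neurons_per_layer, layer_label=lab, noise_sd=sd)
        for lab, sd in L4_ADVANTAGE_NOISE.items()
    ]


def split_by_layer(t: TrialResponseTensor) -> dict[str, TrialResponseTensor]:
    """One single-layer tensor per layer label, in table order."""
    out = {}
    for label in t.neurons["layer_label"].dropna().unique():
        mask = (t.neurons["layer_label"] == label).to_numpy()
        sub = t.copy()
        sub.responses = sub.responses[mask]
        sub.neurons = sub.neurons[mask].reset_index(drop=True)
        out[label] = sub
    return out


@dataclass
class LayerExperimentOutcome:
    results: dict[str, DecodingResult]
    comparisons: pd.DataFrame

    @property
    def mean_accuracies(self) -> dict[str, float]:
        return {k: v.mean_accuracy for k, v in self.results.items()}

    def l4_beats_every_layer(self, alpha: float = 0.05) -> bool:
        """True when L4 has the top mean accuracy and every L4 pairwise
        comparison is significant at ``alpha``."""
        means = self.mean_accuracies
        if max(means, key=means.get) != "L4":
            return False
        mask = (self.comparisons["layer_a"] == "L4") | (
            self.comparisons["layer_b"] == "L4"
        )
        return bool((self.comparisons.loc[mask, "p_value"] <= alpha).all())


def l4_advantage_experiment(
    seed: int,
    n_neurons_per_layer: int = 100,
    n_directions: int = 8,
    n_repeats: int = 40,
    population_size: int = 64,
    n_selection_repeats: int = 15,
    decoder: str = "nn-corr",
) -> LayerExperimentOutcome:
    """One replicate of the size-matched 4-layer decoding comparison."""
    stim = make_stimulus_set(
        "custom", {"n_directions": n_directions, "n_repeats": n_repeats}
    )
    tensor = generate_population(
        layer_profiles_l4_advantage(n_neurons_per_layer), stim, seed=seed
    )
    config = DecodingConfig(
        decoder=decoder,
        population_size=population_size,
        n_selection_repeats=n_selection_repeats,
        seed=(seed * 37 + 1) % (2**31),
    )
    results = {
        label: subsampled_decode(sub, config)
        for label, sub in split_by_layer(tensor).items()
    }
    comparisons = compare_layers({k: v.accuracies for k, v in results.items()})
    return LayerExperimentOutcome(results=results, comparisons=comparisons)


def l4_advantage_replicates(
    seed: int, n_replicates: int = 20, **kwargs
) -> pd.DataFrame:
    """Replicate the 4-layer experiment; one row per replicate."""
    rows = []
    for rep in range(n_replicates):
        outcome = l4_advantage_experiment(seed + rep, **kwargs)
        row = {f"acc_{k}": v for k, v in outcome.mean_accuracies.items()}
        row["replicate"] = rep
        row["l4_significant_everywhere"] = outcome.l4_beats_every_layer()
        rows.append(row)
    return pd.DataFrame(rows)


def depth_noise_curve(depth_um: float) -> float:
    """Trial noise over depth: lowest mid-cortex (245 um), higher at the
    pial surface and at depth, so stimulus SNR peaks in the middle planes."""
    return 0.6 + 0.9 * abs(depth_um - 245.0) / 175.0


def depth_snr_experiment(
    seed: int,
    n_neurons_per_depth: int = 100,
    n_directions: int = 32,
    n_repeats: int = 24,
    population_size: int = 64,
    n_selection_repeats: int = 5,
    decoder: str = "nn-corr",
) -> tuple[pd.DataFrame, RegressionSummary]:
    """11-depth series: decode per depth, regress accuracy on mean SNR."""
    stim = make_stimulus_set(
        "custom", {"n_directions": n_directions, "n_repeats": n_repeats}
    )
    base = LayerProfile(n_neurons=n_neurons_per_depth, depth_um=70.0)
    series = simulate_depth_series(base, stim, seed=seed, snr_curve=depth_noise_curve)
    config = DecodingConfig(
        decoder=decoder,
        population_size=population_size,
        n_selection_repeats=n_selection_repeats,
        seed=(seed * 13 + 5) % (2**31),
    )
    results, props = {}, {}
    for tensor in series:
        depth = float(tensor.neurons["depth_um"].iloc[0])
        results[depth] = subsampled_decode(tensor, config)
        table = neuron_properties(tensor)
        props[depth] = {
            "snr": float(table["snr"].mean()),
            "osi": float(table["osi"].mean()),
            "dsi": float(table["dsi"].mean()),
            "reliability": float("nan"),
        }
    profile = depth_profile(results, props)
    fit = accuracy_vs_property(
        profile["mean_snr"], profile["mean_accuracy"], predictor="snr"
    )
    return profile, fit


def depth_snr_replicates(seed: int, n_replicates: int = 10, **kwargs) -> pd.DataFrame:
    rows = []
    for rep in range(n_replicates):
        _, fit = depth_snr_experiment(seed + rep, **kwargs)
        rows.append(
            {
                "replicate": rep,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "positive_and_strong": fit.slope > 0 and fit.r_squared >= 0.5,
            }
        )
    return pd.DataFrame(rows)


def chance_floor_experiment(
    seed: int,
    n_directions: int = 32,
    n_repeats: int = 20,
    n_neurons: int = 64,
    decoders: Sequence[str] = DECODER_NAMES,
) -> pd.DataFrame:
    """Untuned (gain 0) population: every decoder should sit at chance.

    Returns per-decoder pooled test-trial counts; each test trial appears
    exactly once across the stratified folds, so ``n_correct`` is a draw
    from Binomial(n_trials, 1/k) under the chance hypothesis.
    """
    stim = make_stimulus_set(
        "custom", {"n_directions": n_directions, "n_repeats": n_repeats}
    )
    profile = LayerProfile(n_neurons=n_neurons, layer_label="L4", gain=0.0)
    tensor = generate_population([profile], stim, seed=seed)
    n_trials = n_directions * n_repeats
    rows = []
    for name in decoders:
        config = DecodingConfig(
            decoder=name,
            population_size=n_neurons,
            n_selection_repeats=1,
            seed=(seed + 101) % (2**31),
        )
        result = subsampled_decode(tensor, config)
        accuracy = result.mean_accuracy
        rows.append(
            {
                "decoder": name,
                "accuracy": accuracy,
                "n_correct": int(round(accuracy * n_trials)),
                "n_trials": n_trials,
                "chance": 1.0 / n_directions,
            }
        )
    return pd.DataFrame(rows)


def size_sweep_experiment(
    seed: int,
    sizes: Sequence[int] = (4, 8, 16, 32, 64, 128, 256),
    n_neurons: int = 300,
    n_directions: int = 8,
    n_repeats: int = 40,
    decoder: str = "nn-corr",
    n_selection_repeats: int = 15,
) -> pd.DataFrame:
    """Mean accuracy versus population size on tuned synthetic data."""
    stim = make_stimulus_set(
        "custom", {"n_directions": n_directions, "n_repeats": n_repeats}
    )
    profile = LayerProfile(n_neurons=n_neurons, layer_label="L4")
    tensor = generate_population([profile], stim, seed=seed)
    config = DecodingConfig(
        decoder=decoder,
        population_size=min(sizes),
        n_selection_repeats=n_selection_repeats,
        seed=(seed + 211) % (2**31),
    )
    return decoder_suite(tensor, list(sizes), [decoder], config)
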