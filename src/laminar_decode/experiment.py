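"""Seeded end-to-end experiments: generator -> preprocessing -> metrics ->
decoding -> layer statistics, from one JSON-serializable configuration.

A single global seed spawns per-stage seeds through a fixed counter scheme
(stage k uses ``seed + 1000 * k``, reduced mod 2^31 - 1), so each stage is
individually reproducible and no two stages share a stream.  A run writes
its tensor, per-neuron property table, per-layer decoding results and
pairwise layer comparisons under the output directory, plus a manifest
recording the configuration, stage seeds and timings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .dataio import write_tensor
from .decoding import DECODER_NAMES, DecodingConfig, subsampled_decode
from .layer_stats import compare_layers
from .stimuli import PRESETS, make_stimulus_set
from .synthgen import LayerProfile, generate_population
from .tuning import neuron_properties

__all__ = ["ExperimentConfig", "validate_config", "run_experiment"]

logger = logging.getLogger("laminar_decode")

_STAGE_OFFSET = 1000
_MOD = 2**31 - 1


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Per-stage seed from the global seed (documented counter scheme)."""
    return (global_seed + _STAGE_OFFSET * stage_index) % _MOD


@dataclass
class ExperimentConfig:
    """Fully serializable description of one synthetic decoding experiment."""

    stimulus: dict = field(
        default_factory=lambda: {"preset": "allen-dg", "overrides": {}}
    )
    layers: list = field(default_factory=list)  # list of LayerProfile kwargs
    decoding: dict = field(default_factory=dict)  # DecodingConfig kwargs
    outdir: str = "results/experiment"
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ExperimentConfig":
        return cls(**json.loads(Path(path).read_text()))

    def build_stimuli(self):
        return make_stimulus_set(
            self.stimulus.get("preset", "custom"), self.stimulus.get("overrides")
        )

    def build_profiles(self) -> list[LayerProfile]:
        return [LayerProfile(**kw) for kw in self.layers]

    def build_decoding(self) -> DecodingConfig:
        kwargs = dict(self.decoding)
        kwargs.setdefault("seed", stage_seed(self.seed, 3))
        return DecodingConfig(**kwargs)


def validate_config(config: ExperimentConfig) -> list[str]:
    """Report every problem that would stop :func:`run_experiment`.

    Returns an empty list iff the configuration is runnable; never raises.
    """
    problems: list[str] = []
    if config.seed < 0:
        problems.append("seed must be nonnegative")
    preset = config.stimulus.get("preset")
    if preset != "custom" and preset not in PRESETS:
        problems.append(f"unknown stimulus preset: {preset!r}")
    stimuli = None
    try:
        stimuli = config.build_stimuli()
    except Exception as exc:  # reported, never raised
        problems.append(f"stimulus: {exc}")
    if not config.layers:
        problems.append("no layer profiles")
    profiles = []
    try:
        profiles = config.build_profiles()
    except Exception as exc:
        problems.append(f"layers: {exc}")
    decoding = None
    try:
        decoding = config.build_decoding()
    except Exception as exc:
        problems.append(f"decoding: {exc}")
    if decoding is not None:
        if decoding.decoder not in DECODER_NAMES:
            problems.append(f"unknown decoder: {decoding.decoder!r}")
        if profiles:
            smallest = min(p.n_neurons for p in profiles)
            if decoding.population_size > smallest:
                problems.append(
                    f"population_size {decoding.population_size} exceeds the "
                    f"smallest layer's {smallest} neurons"
                )
        if stimuli is not None and stimuli.n_repeats < decoding.cv_folds:
            problems.append(
                f"cv_folds {decoding.cv_folds} exceeds the {stimuli.n_repeats} "
                "repeats per condition"
            )
    return problems


def _stage(name: str):
    """Decorator-free stage wrapper: annotate any error with the stage name."""
    class _Ctx:
        def __init__(self):
            self.t0 = None

        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            self.elapsed = time.perf_counter() - self.t0
            logger.info("stage %s: done in %.2fs", name, self.elapsed)
            return False

    return _Ctx()


def run_experiment(config: ExperimentConfig) -> dict:
    """Run generator -> properties -> per-layer decoding -> comparisons.

    Writes tensor.csv (+ sidecar), props.csv, results.csv, comparisons.csv
    and manifest.json under ``config.outdir`` and returns the artifact paths
    and in-memory tables.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    with _stage("simulate") as s:
        stimuli = config.build_stimuli()
        profiles = config.build_profiles()
        tensor = generate_population(
            profiles, stimuli, seed=stage_seed(config.seed, 1)
        )
        write_tensor(tensor, outdir / "tensor.csv")
    timings["simulate"] = s.elapsed

    with _stage("properties") as s:
        props = neuron_properties(tensor)
        props.to_csv(outdir / "props.csv", index=False)
    timings["properties"] = s.elapsed

    with _stage("decode") as s:
        decoding = config.build_decoding()
        layer_results = {}
        rows = []
        for label in tensor.neurons["layer_label"].dropna().unique():
            mask = (tensor.neurons["layer_label"] == label).to_numpy()
            sub = tensor.copy()
            sub.responses = sub.responses[mask]
            sub.neurons = sub.neurons[mask].reset_index(drop=True)
            result = subsampled_decode(sub, decoding)
            layer_results[label] = result
            for i, acc in enumerate(result.accuracies):
                rows.append(
                    {
                        "decoder": decoding.decoder,
                        "task": stimuli.task_kind,
                        "layer": label,
                        "depth_um": result.metadata["depth_um"],
                        "population_size": decoding.population_size,
                        "repeat": i // decoding.cv_folds,
                        "fold": i % decoding.cv_folds,
                        "accuracy": acc,
                    }
                )
        results_df = pd.DataFrame(rows)
        results_df.to_csv(outdir / "results.csv", index=False)
    timings["decode"] = s.elapsed

    with _stage("compare") as s:
        comparisons = compare_layers(
            {k: v.accuracies for k, v in layer_results.items()}
        )
        comparisons.to_csv(outdir / "comparisons.csv", index=False)
    timings["compare"] = s.elapsed

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": {f"stage_{k}": stage_seed(config.seed, k) for k in (1, 2, 3)},
        "timings_s": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return {
        "outdir": str(outdir),
        "tensor": tensor,
        "props": props,
        "results": results_df,
        "layer_results": layer_results,
        "comparisons": comparisons,
        "manifest": manifest,
    }
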