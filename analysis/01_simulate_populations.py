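#!/usr/bin/env python
"""Simulate the baseline laminar populations for the decoding analyses.

Generates (a) a 4-layer grating population with L4's trial noise halved —
the synthetic analogue of the laminar organization under study, where L4
receives direct thalamic input — and (b) a small trace-level session used
downstream for the trace-based reliability metric.  Writes the trial tensor
and the HDF5 traces under results/.
"""

from pathlib import Path

from laminar_decode import generate_population, make_stimulus_set, write_tensor, write_traces
from laminar_decode.studies import layer_profiles_l4_advantage

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)

    # 8-direction grating session, 40 repeats per condition (desk scale),
    # 100 neurons per layer
    stim = make_stimulus_set("custom", {"n_directions": 8, "n_repeats": 40})
    profiles = layer_profiles_l4_advantage(n_neurons_per_layer=100)
    tensor = generate_population(profiles, stim, seed=SEED)
    write_tensor(tensor, OUT / "layers_tensor.csv")
    print(
        f"4-layer population: {tensor.n_neurons} neurons x "
        f"{tensor.n_conditions} conditions x {tensor.n_repeats} repeats "
        f"-> {OUT / 'layers_tensor.csv'}"
    )

    # small 30 Hz trace session for trial-to-trial reliability (20 neurons
    # per layer, 4 directions x 12 repeats, 1 s trials)
    stim_small = make_stimulus_set("custom", {"n_directions": 4, "n_repeats": 12})
    profiles_small = layer_profiles_l4_advantage(n_neurons_per_layer=20)
    rec = generate_population(
        profiles_small, stim_small, seed=SEED + 1, emit_traces=True,
        trial_duration_s=1.0,
    )
    write_traces(rec, OUT / "traces_session.h5")
    print(
        f"trace session: {rec.n_neurons} neurons, {len(rec.epochs)} trials at "
        f"{rec.sampling_hz:.0f} Hz -> {OUT / 'traces_session.h5'}"
    )


if __name__ == "__main__":
    main()
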