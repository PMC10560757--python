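#!/usr/bin/env python
"""Size-matched decoding comparisons across cortical layers.

Three analyses on the 4-layer tensor from 01_simulate_populations.py:

1. per-layer decoding at matched population size (64 neurons, 15 selection
   repeats, 5-fold stratified CV) with pairwise Wilcoxon rank-sum tests —
   the L4-advantage comparison;
2. a decoder bake-off (all six decoders) at size 64 on the L4 population;
3. a population-size sweep {4 ... 256} pooled over layers.

Writes per-fold accuracies, comparison tables and sweep tables to results/.
"""

from pathlib import Path

import pandas as pd

from laminar_decode import DecodingConfig, compare_layers, decoder_suite, read_tensor, subsampled_decode
from laminar_decode.decoding import DECODER_NAMES
from laminar_decode.studies import split_by_layer

SEED = 21
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tensor = read_tensor(OUT / "layers_tensor.csv")
    by_layer = split_by_layer(tensor)

    # 1. layer comparison at matched size
    config = DecodingConfig(decoder="nn-corr", population_size=64, seed=SEED)
    results = {lab: subsampled_decode(sub, config) for lab, sub in by_layer.items()}
    rows = [
        {"layer": lab, "mean_accuracy": r.mean_accuracy, "sem": r.sem_accuracy}
        for lab, r in results.items()
    ]
    pd.DataFrame(rows).to_csv(OUT / "layer_accuracy.csv", index=False)
    comparisons = compare_layers({k: v.accuracies for k, v in results.items()})
    comparisons.to_csv(OUT / "layer_comparisons.csv", index=False)

    print("size-matched (64-neuron) accuracy per layer, nn-corr decoder:")
    for lab, r in results.items():
        print(f"  {lab:5s} {r.mean_accuracy:.3f} +/- {r.sem_accuracy:.3f}")
    print("pairwise rank-sum comparisons:")
    print(
        comparisons[["layer_a", "layer_b", "p_value", "code"]]
        .to_string(index=False, float_format=lambda v: f"{v:.2e}")
    )

    # 2. decoder bake-off on the L4 population
    suite = decoder_suite(by_layer["L4"], [64], list(DECODER_NAMES), config)
    suite.drop(columns=["accuracies"]).to_csv(OUT / "decoder_bakeoff.csv", index=False)
    print("\ndecoder bake-off (L4, 64 neurons):")
    for row in suite.itertuples():
        print(f"  {row.decoder:14s} {row.mean_accuracy:.3f}")

    # 3. size sweep per layer
    sweep_rows = []
    for lab, sub in by_layer.items():
        sweep = decoder_suite(sub, [4, 8, 16, 32, 64], ["nn-corr"], config)
        sweep["layer"] = lab
        sweep_rows.append(sweep.drop(columns=["accuracies"]))
    sweep = pd.concat(sweep_rows, ignore_index=True)
    sweep.to_csv(OUT / "size_sweep.csv", index=False)
    pivot = sweep.pivot(index="population_size", columns="layer", values="mean_accuracy")
    print("\nmean accuracy by population size (nn-corr):")
    print(pivot.round(3).to_string())
    print(f"\ntables -> {OUT / 'layer_accuracy.csv'}, {OUT / 'layer_comparisons.csv'},")
    print(f"          {OUT / 'decoder_bakeoff.csv'}, {OUT / 'size_sweep.csv'}")


if __name__ == "__main__":
    main()
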