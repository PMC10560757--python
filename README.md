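# laminar-decode

Do neuron populations in different cortical layers of mouse visual cortex
carry different amounts of stimulus information? `laminar-decode` is an
analysis pipeline for asking that question of trial-structured two-photon
calcium (df/f) recordings: it computes per-neuron tuning and quality
metrics, decodes stimulus identity from size-matched neuron populations
with a suite of multiclass classifiers, and compares decoding accuracy
across layers and imaging depths with nonparametric statistics. A
synthetic laminar population generator with the same statistical structure
ships with the package, so the whole pipeline runs, and is tested, without
any external download.

## What it computes

Per neuron, from a (neuron × condition × repeat) response tensor:

- **OSI** = (R_prefer − R_orthog)/(R_prefer + R_orthog) and
  **DSI** = (R_prefer − R_opposite)/(R_prefer + R_opposite) — orientation
  and direction selectivity;
- **Reliability** = 2/(T²−T) Σ_{i<j} ρ(f_i, f_j) — mean pairwise Pearson
  correlation of single-trial df/f traces at the preferred condition;
- **SNR** = (Σ_i R_i² − nV)/(nV), with V the estimated variance of a
  trial-mean response — ≈ 0 for a pure-noise neuron, positive for neurons
  responding above their noise baseline.

Per population: stratified 5-fold cross-validated decoding accuracy (the
fraction of correctly labeled test trials) for six decoders — a
correlation-template nearest-neighbor decoder (`nn-corr`), ECOC linear
SVM, k-NN, decision tree, Gaussian naive Bayes, and logistic regression —
with neuron subsets of a fixed size redrawn 15 times to remove selection
bias. Layer/depth comparisons use two-sided Wilcoxon rank-sum tests and
OLS regressions of mean accuracy on mean population properties (R²,
slope p-value).

## Worked example

```python
from laminar_decode import (
    DecodingConfig, LayerProfile, compare_layers, generate_population,
    make_stimulus_set, subsampled_decode,
)
from laminar_decode.studies import split_by_layer

stim = make_stimulus_set("custom", {"n_directions": 8, "n_repeats": 40})
profiles = [
    LayerProfile(n_neurons=100, layer_label="L2/3", noise_sd=1.0),
    LayerProfile(n_neurons=100, layer_label="L4", noise_sd=0.5),
    LayerProfile(n_neurons=100, layer_label="L5", noise_sd=1.2),
    LayerProfile(n_neurons=100, layer_label="L6", noise_sd=1.0),
]
tensor = generate_population(profiles, stim, seed=7)
config = DecodingConfig(decoder="nn-corr", population_size=64, seed=21)
results = {lab: subsampled_decode(sub, config)
           for lab, sub in split_by_layer(tensor).items()}
for lab, r in results.items():
    print(f"{lab:5s} {r.mean_accuracy:.3f} +/- {r.sem_accuracy:.3f}")
print(compare_layers({k: v.accuracies for k, v in results.items()})
      [["layer_a", "layer_b", "p_value", "code"]])
```

prints

```
L2/3  0.225 +/- 0.006
L4    0.346 +/- 0.006
L5    0.154 +/- 0.005
L6    0.178 +/- 0.006
  layer_a layer_b       p_value code
0    L2/3      L4  6.361483e-22  ***
1    L2/3      L5  9.676593e-15  ***
2    L2/3      L6  1.566615e-07  ***
3      L4      L5  5.946377e-26  ***
4      L4      L6  4.218535e-25  ***
5      L5      L6  3.413813e-03   **
```

Each line is one layer's mean decoding accuracy (± SEM over 15 neuron
selections × 5 folds) on the 8-direction grating task at matched
population size 64. The generator gave L4 half the trial noise of the
other layers (and L5 the most), and the pipeline recovers exactly that
laminar ordering: L4 decodes best, L5 worst, every pairwise rank-sum
comparison significant.

## Analysis scripts

The `analysis/` drivers run the full narrative on synthetic data and write
their tables under `results/`:

1. `01_simulate_populations.py` — 4-layer population + a 30 Hz trace session
2. `02_neuron_properties.py` — OSI/DSI/SNR/reliability tables per layer
3. `03_layer_decoding.py` — size-matched layer comparison, decoder
   bake-off, population-size sweep
4. `04_depth_profile.py` — 11-depth series and the accuracy-vs-SNR
   regression

A `laminar-decode` CLI exposes the same steps for file-based workflows
(`simulate`, `convert`, `props`, `run`, `compare`, `regress`,
`reproduce`); see `laminar-decode --help`.

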