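"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
import pytest

from laminar_decode import (
    LayerProfile,
    StimulusSet,
    TrialResponseTensor,
    generate_population,
    make_stimulus_set,
)


# ---------------------------------------------------------------------------
# Oracles (kept deliberately naive and independent of the implementation)


def pearson_oracle(x, y) -> float:
    """Two-pass covariance Pearson correlation."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = sqrt(sum((a - mx) ** 2 for a in x))
    sy = sqrt(sum((b - my) ** 2 for b in y))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return cov / (sx * sy)


def nn_corr_oracle(train_X, train_y, test_X):
    """Exhaustive correlation template decoding, one correlation at a time."""
    classes = sorted(set(train_y))
    templates = {}
    for c in classes:
        rows = [train_X[i] for i in range(len(train_y)) if train_y[i] == c]
        templates[c] = [sum(col) / len(col) for col in zip(*rows)]
    labels = []
    for row in test_X:
        best_c, best_r = None, None
        for c in classes:  # ascending, so near-ties keep the lowest class
            r = pearson_oracle(row, templates[c])
            if best_r is None or r > best_r + 1e-12:
                best_c, best_r = c, r
        labels.append(best_c)
    return labels


def rank_sum_exhaustive_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating every group assignment.

    Requires no ties in the pooled sample.  Uses the sum of x-ranks as the
    statistic and doubles the one-sided tail (capped at 1), the classical
    two-sided convention for the symmetric null distribution.
    """
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    nx = len(x)
    all_vals = sorted(pooled)
    rank_of = {v: i + 1 for i, v in enumerate(all_vals)}
    observed = sum(rank_of[v] for v in x)
    sums = [
        sum(subset)
        for subset in combinations(range(1, len(pooled) + 1), nx)
    ]
    total = len(sums)
    ge = sum(s >= observed for s in sums)
    le = sum(s <= observed for s in sums)
    return min(1.0, 2.0 * min(ge, le) / total)


def binomial_bounds(n: int, p: float, alpha: float = 0.01):
    """Exact central binomial acceptance interval on the success count."""
    from scipy import stats

    lo = stats.binom.ppf(alpha / 2.0, n, p)
    hi = stats.binom.ppf(1.0 - alpha / 2.0, n, p)
    return int(lo), int(hi)


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def dg8() -> StimulusSet:
    """8-direction grating set, 10 repeats, single (untracked) TF."""
    return make_stimulus_set("custom", {"n_directions": 8, "n_repeats": 10})


@pytest.fixture(scope="session")
def small_population(dg8) -> TrialResponseTensor:
    """One 30-neuron L4 population on the 8-direction task."""
    profile = LayerProfile(n_neurons=30, layer_label="L4")
    return generate_population([profile], dg8, seed=101)


def make_tensor(responses, stimuli, depths=None, layers=None) -> TrialResponseTensor:
    """Hand-rolled tensor from an explicit (neuron, condition, repeat) array."""
    responses = np.asarray(responses, dtype=float)
    n = responses.shape[0]
    neurons = pd.DataFrame(
        {
            "neuron_id": np.arange(n),
            "depth_um": depths if depths is not None else [300.0] * n,
            "layer_label": layers if layers is not None else ["L4"] * n,
            "area_label": ["VISp"] * n,
        }
    )
    return TrialResponseTensor(responses=responses, stimuli=stimuli, neurons=neurons)
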