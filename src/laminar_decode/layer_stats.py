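"""Depth-to-layer mapping, pairwise layer comparisons, and accuracy-property
regressions.

Imaging depths map onto cortical layers with the representative ranges
< 250 um (L2/3), 250-365 um (L4), 375-500 um (L5) and >= 550 um (L6); depths
falling in the gaps between ranges stay unassigned and are excluded from
layer comparisons.  Accuracy distributions are compared pairwise with
two-sided Wilcoxon rank-sum tests (signed-rank for paired observations),
annotated with the conventional significance codes (* p<=0.05, ** p<=0.01,
*** p<=0.001, ns otherwise).  The relation between a population's mean
tuning property (OSI, DSI, reliability, SNR) and its mean decoding accuracy
is summarized by simple ordinary-least-squares regression with R^2 and a
two-sided slope p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import DecodingResult

__all__ = [
    "assign_layer",
    "significance_code",
    "LayerComparison",
    "compare_layers",
    "RegressionSummary",
    "accuracy_vs_property",
    "depth_profile",
]

LAYER_RANGES = {
    "L2/3": (0.0, 250.0),     # depth < 250
    "L4": (250.0, 365.0),     # 250 <= depth <= 365
    "L5": (375.0, 500.0),     # 375 <= depth <= 500
    "L6": (550.0, math.inf),  # depth >= 550
}


def assign_layer(depth_um: float) -> Optional[str]:
    """Map an imaging depth (um below pia) to its cortical layer.

    Returns ``None`` for depths in the unmapped gaps (365, 375) and
    (500, 550) um; raises on negative depth.
    """
    if depth_um < 0:
        raise ValueError("depth must be nonnegative")
    if depth_um < 250.0:
        return "L2/3"
    if depth_um <= 365.0:
        return "L4"
    if 375.0 <= depth_um <= 500.0:
        return "L5"
    if depth_um >= 550.0:
        return "L6"
    return None


def significance_code(p: float) -> str:
    if math.isnan(p):
        return "ns"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class LayerComparison:
    layer_a: str
    layer_b: str
    statistic: float
    p_value: float
    test: str  # "rank-sum" | "signed-rank"
    code: str


def _rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney); exact for small untied
    samples, normal approximation with tie/continuity correction otherwise."""
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (no_ties and max(x.size, y.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    d = x - y
    if np.all(d == 0):
        # no information either way; report ns rather than erroring mid-pipeline
        return 0.0, 1.0
    res = stats.wilcoxon(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_layers(
    results: Mapping[str, Sequence[float]],
    paired: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """All pairwise two-sided comparisons of per-layer accuracy lists.

    Layers are compared in the mapping's key order.  With ``holm`` the
    p-values receive a Holm step-down correction before coding (off by
    default; raw pairwise significance is reported otherwise).
    """
    labels = list(results)
    if len(labels) < 2:
        raise ValueError("need at least 2 layers to compare")
    arrays = {k: np.asarray(v, dtype=float) for k, v in results.items()}
    for k, v in arrays.items():
        if v.size < 3:
            raise ValueError(f"layer {k!r} has fewer than 3 observations")
    rows = []
    for a, b in itertools.combinations(labels, 2):
        x, y = arrays[a], arrays[b]
        if paired:
            if x.size != y.size:
                raise ValueError("paired comparison requires equal lengths")
            statistic, p = _signed_rank(x, y)
            test = "signed-rank"
        else:
            statistic, p = _rank_sum(x, y)
            test = "rank-sum"
        rows.append(
            {
                "layer_a": a,
                "layer_b": b,
                "statistic": statistic,
                "p_value": p,
                "test": test,
                "median_a": float(np.median(x)),
                "median_b": float(np.median(y)),
            }
        )
    df = pd.DataFrame(rows)
    if holm:
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adjusted = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_value"].iloc[idx])
            adjusted[idx] = min(1.0, running)
        df["p_value"] = adjusted
    df["code"] = [significance_code(p) for p in df["p_value"]]
    return df


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fit of mean decoding accuracy on a mean population property."""

    predictor: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def accuracy_vs_property(
    property_values: Sequence[float],
    accuracies: Sequence[float],
    predictor: str = "property",
) -> RegressionSummary:
    """Simple OLS of per-group mean accuracy on a per-group mean property.

    ``r_squared`` is the squared Pearson correlation of the two series.  A
    constant response yields slope 0 / r^2 0 / p 1; a constant predictor is
    an error.
    """
    x = np.asarray(property_values, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if x.shape != y.shape:
        raise ValueError("property and accuracy series must align")
    if x.size < 3:
        raise ValueError("need at least 3 groups")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression inputs")
    if np.ptp(x) == 0:
        raise ValueError("zero predictor variance")
    if np.ptp(y) == 0:
        return RegressionSummary(predictor, 0.0, float(y[0]), 0.0, 1.0, x.size)
    fit = stats.linregress(x, y)
    return RegressionSummary(
        predictor=predictor,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=x.size,
    )


def depth_profile(
    results: Mapping[float, DecodingResult],
    props: Mapping[float, Mapping[str, float]],
) -> pd.DataFrame:
    """Combine per-depth decoding results and mean neuron properties.

    Returns one row per imaging depth, sorted ascending, with mean accuracy
    +/- SEM and the mean OSI/DSI/reliability/SNR of that depth's neurons —
    the table an accuracy-vs-property regression runs on.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 depths")
    if set(results) != set(props):
        raise ValueError("mismatched depth keys between results and properties")
    rows = []
    for depth in sorted(results):
        res = results[depth]
        prop = props[depth]
        rows.append(
            {
                "depth_um": float(depth),
                "mean_accuracy": res.mean_accuracy,
                "sem_accuracy": res.sem_accuracy,
                "mean_osi": float(prop.get("osi", math.nan)),
                "mean_dsi": float(prop.get("dsi", math.nan)),
                "mean_reliability": float(prop.get("reliability", math.nan)),
                "mean_snr": float(prop.get("snr", math.nan)),
            }
        )
    return pd.DataFrame(rows)
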