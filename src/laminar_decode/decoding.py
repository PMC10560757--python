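"""Population decoding: classifiers, cross-validation, size-matched protocol.

Samples are single-trial population vectors (one row per stimulus
presentation, one column per neuron); labels are condition ids.  Six
decoders share a fit/predict contract:

* ``nn-corr`` — the correlation template decoder: class templates are the
  element-wise means of the training population vectors, and a test trial is
  assigned to the class whose template it has the highest Pearson
  correlation with.  Suited to large populations, where high-dimensional
  correlations swamp stimulus-unrelated high-amplitude responses.
* ``svm-ecoc`` — linear SVMs under an error-correcting output code reduction
  of the k-class problem (seeded random dense codebook, ~10*log2(k) bits).
* ``knn``, ``decision-tree``, ``naive-bayes``, ``logistic`` — standard
  multiclass baselines.

The evaluation protocol is stratified 5-fold cross-validation with an 80/20
split (repeated stratified holdout when a different test fraction is
requested), and decoding accuracy is the fraction of correctly labeled test
trials.  To compare populations at matched size, neuron subsets of a fixed
size are redrawn ``n_selection_repeats`` times (default 15) and fold
accuracies pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.multiclass import OutputCodeClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .dataio import TrialResponseTensor, normalize_across_neurons

__all__ = [
    "DECODER_NAMES",
    "DecodingConfig",
    "DecodingResult",
    "NearestCorrelationClassifier",
    "nn_corr_fit",
    "nn_corr_predict",
    "make_classifier",
    "cross_validated_accuracy",
    "subsampled_decode",
    "decoder_suite",
]

DECODER_NAMES = (
    "svm-ecoc",
    "knn",
    "decision-tree",
    "naive-bayes",
    "logistic",
    "nn-corr",
)


@dataclass(frozen=True)
class DecodingConfig:
    """Protocol constants for one decoding experiment."""

    decoder: str = "svm-ecoc"
    population_size: int = 64
    n_selection_repeats: int = 15
    cv_folds: int = 5
    test_fraction: float = 0.2
    seed: int = 0
    normalize: bool = True
    normalize_on_train_only: bool = False

    def __post_init__(self) -> None:
        if self.decoder not in DECODER_NAMES:
            raise ValueError(f"unknown decoder: {self.decoder!r}")
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if self.n_selection_repeats < 1:
            raise ValueError("n_selection_repeats must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class DecodingResult:
    """Pooled per-fold accuracies for one (population, decoder, size) cell."""

    accuracies: list[float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        accs = np.asarray(self.accuracies, dtype=float)
        if accs.size == 0:
            raise ValueError("no accuracies")
        if (accs < 0).any() or (accs > 1).any():
            raise ValueError("accuracies must lie in [0, 1]")
        self.accuracies = [float(a) for a in accs]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sem_accuracy(self) -> float:
        accs = np.asarray(self.accuracies)
        if accs.size < 2:
            return 0.0
        return float(accs.std(ddof=1) / math.sqrt(accs.size))


# ---------------------------------------------------------------------------
# Correlation nearest-neighbor decoder


def nn_corr_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class templates: element-wise mean training vector per class.

    Returns ``(classes, templates)`` with classes sorted ascending and
    ``templates[i]`` the mean of rows labeled ``classes[i]``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (trials, neurons) aligned with y")
    if X.shape[1] < 2:
        raise ValueError("nn-corr needs at least 2 neurons")
    classes = np.unique(y)
    templates = np.stack([X[y == c].mean(axis=0) for c in classes])
    return classes, templates


def _row_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between rows of A and rows of B.

    Zero-variance rows correlate 0 with everything (sentinel convention).
    """
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    denom = na[:, None] * nb[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Ac @ Bc.T) / denom
    corr[~np.isfinite(corr)] = 0.0
    return corr


def nn_corr_predict(
    classes: np.ndarray, templates: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Assign each test vector the class of its best-correlated template.

    Ties (including the all-zero-correlation case) break toward the lowest
    class id; classes are sorted in ``nn_corr_fit`` so argmax suffices.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != templates.shape[1]:
        raise ValueError("test vector length does not match templates")
    corr = _row_corr(X, templates)
    # ties within numerical tolerance break toward the lowest class id
    best = corr.max(axis=1, keepdims=True)
    return classes[np.argmax(corr >= best - 1e-12, axis=1)]


class NearestCorrelationClassifier:
    """sklearn-style wrapper around the correlation template decoder."""

    def fit(self, X, y):
        self.classes_, self.templates_ = nn_corr_fit(X, y)
        return self

    def predict(self, X):
        return nn_corr_predict(self.classes_, self.templates_, X)


# ---------------------------------------------------------------------------
# Classifier backends


def make_classifier(name: str, n_classes: int, seed: int):
    """Instantiate a decoder backend by name (fresh, unfitted)."""
    if name == "nn-corr":
        return NearestCorrelationClassifier()
    if name == "svm-ecoc":
        n_bits = max(n_classes, math.ceil(10.0 * math.log2(max(2, n_classes))))
        return OutputCodeClassifier(
            estimator=LinearSVC(),
            code_size=n_bits / n_classes,
            random_state=seed,
        )
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "decision-tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "naive-bayes":
        return GaussianNB()
    if name == "logistic":
        return LogisticRegression(max_iter=1000)
    raise ValueError(f"unknown decoder: {name!r}")


# ---------------------------------------------------------------------------
# Cross-validation and the size-matched protocol


def _prepare_samples(
    t: TrialResponseTensor,
    neuron_subset: Optional[Sequence[int]],
    config: DecodingConfig,
):
    tensor = t
    if config.normalize and not t.normalized and not config.normalize_on_train_only:
        tensor = normalize_across_neurons(t)
    X, y = tensor.as_samples(neuron_subset)
    return X, y


def _fold_splitter(config: DecodingConfig, y: np.ndarray):
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"a condition has {counts.min()} repeats, fewer than cv_folds={config.cv_folds}"
        )
    if abs(config.test_fraction - 1.0 / config.cv_folds) < 1e-9:
        return StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed % (2**31)
        )
    # train/test-ratio sweeps: repeated stratified holdout at the requested
    # fraction, one holdout per "fold"
    return StratifiedShuffleSplit(
        n_splits=config.cv_folds,
        test_size=config.test_fraction,
        random_state=config.seed % (2**31),
    )


def _zscore_train_test(train_X, test_X):
    mean = train_X.mean(axis=0, keepdims=True)
    sd = train_X.std(axis=0, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (train_X - mean) / sd, (test_X - mean) / sd


def cross_validated_accuracy(
    t: TrialResponseTensor,
    neuron_subset: Optional[Sequence[int]],
    config: DecodingConfig,
) -> list[float]:
    """Stratified CV of one decoder on one neuron subset.

    Returns the per-fold fractions of correctly labeled test trials.  By
    default neuron-wise normalization is fit on the full tensor before
    splitting, matching the preprocessing order of the analysis recipe;
    ``normalize_on_train_only`` refits the z-score on training folds to
    avoid that (documented) leakage.
    """
    X, y = _prepare_samples(t, neuron_subset, config)
    splitter = _fold_splitter(config, y)
    accuracies = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        train_X, test_X = X[train_idx], X[test_idx]
        if config.normalize and config.normalize_on_train_only and not t.normalized:
            train_X, test_X = _zscore_train_test(train_X, test_X)
        clf = make_classifier(
            config.decoder, n_classes=len(np.unique(y)), seed=(config.seed + fold) % (2**31)
        )
        clf.fit(train_X, y[train_idx])
        pred = clf.predict(test_X)
        accuracies.append(float(np.mean(pred == y[test_idx])))
    return accuracies


def subsampled_decode(
    t: TrialResponseTensor, config: DecodingConfig
) -> DecodingResult:
    """Size-matched decoding: redraw the neuron subset and pool accuracies.

    For selection repeat r (1-based), ``population_size`` neurons are drawn
    uniformly without replacement with seed ``config.seed + r``, then
    cross-validated; all fold accuracies are pooled into one result.
    """
    if config.population_size > t.n_neurons:
        raise ValueError(
            f"population_size {config.population_size} exceeds the "
            f"{t.n_neurons} available neurons"
        )
    accuracies = []
    for r in range(1, config.n_selection_repeats + 1):
        rng = np.random.default_rng((config.seed + r) % (2**31))
        subset = rng.choice(t.n_neurons, size=config.population_size, replace=False)
        # fold assignment is held fixed across selection repeats: repeats
        # differ only in which neurons were drawn
        accuracies.extend(cross_validated_accuracy(t, subset, config))
    layers = t.neurons["layer_label"].dropna().unique()
    depths = t.neurons["depth_um"].unique()
    meta = {
        "decoder": config.decoder,
        "task": t.stimuli.task_kind,
        "population_size": config.population_size,
        "n_selection_repeats": config.n_selection_repeats,
        "cv_folds": config.cv_folds,
        "test_fraction": config.test_fraction,
        "seed": config.seed,
        "layer": layers[0] if len(layers) == 1 else None,
        "depth_um": float(depths[0]) if len(depths) == 1 else None,
    }
    return DecodingResult(accuracies=accuracies, metadata=meta)


def decoder_suite(
    t: TrialResponseTensor,
    sizes: Sequence[int],
    decoders: Sequence[str],
    config: DecodingConfig,
    test_fractions: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Full factorial sweep over decoder x population size [x test fraction].

    Returns one row per cell with the pooled mean accuracy, its SEM and the
    raw accuracy list.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be sorted ascending")
    fracs = [config.test_fraction] if test_fractions is None else list(test_fractions)
    rows = []
    for name in decoders:
        for size in sizes:
            for frac in fracs:
                cell = replace(
                    config, decoder=name, population_size=int(size), test_fraction=frac
                )
                result = subsampled_decode(t, cell)
                rows.append(
                    {
                        "decoder": name,
                        "population_size": int(size),
                        "test_fraction": frac,
                        "mean_accuracy": result.mean_accuracy,
                        "sem_accuracy": result.sem_accuracy,
                        "n_accuracies": len(result.accuracies),
                        "accuracies": result.accuracies,
                    }
                )
    return pd.DataFrame(rows)
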