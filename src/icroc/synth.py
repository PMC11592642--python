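"""Synthetic data generators for score/label samples and two-class feature tables.

Two kinds of inputs are emulated: (i) per-class score samples drawn from a
Bi-distributional generating pair at the study's class sizes (200 negative,
300 positive by default), and (ii) a two-class Gaussian feature table
shaped like a breast-cancer diagnostic dataset (569 instances, 30 numeric
features, ~37% positive class), with a configurable planted subset of
informative features whose class-1 mean is shifted by a standardized
effect size.  Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import FeatureTable
from .families import ParamVector, sample

__all__ = ["SyntheticTableSpec", "make_feature_table", "make_score_labels"]


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Parameters of the planted-signal two-class Gaussian table.

    ``effect_size`` is the class-1 mean shift of each informative feature in
    units of the feature's standard deviation (``noise_sd``); the remaining
    features are pure noise in both classes.  ``class_balance`` is the
    proportion of class-1 (positive) instances.
    """

    n_instances: int = 569
    n_features: int = 30
    n_informative: int = 5
    class_balance: float = 0.37
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must lie in [0, n_features]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def make_feature_table(spec: SyntheticTableSpec = SyntheticTableSpec()) -> FeatureTable:
    """Draw the planted-signal feature table described by ``spec``.

    The first ``n_informative`` columns are informative; the class-1 rows of
    those columns are shifted by ``effect_size * noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n_instances * spec.class_balance))
    n1 = min(max(n1, 1), spec.n_instances - 1)
    y = np.zeros(spec.n_instances, dtype=int)
    y[rng.choice(spec.n_instances, size=n1, replace=False)] = 1
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_instances, spec.n_features))
    shift = spec.effect_size * spec.noise_sd
    X[y == 1, : spec.n_informative] += shift
    names = [f"f{i + 1:02d}" for i in range(spec.n_features)]
    return FeatureTable(X=X, y=y, feature_names=names)


def make_score_labels(
    pos: ParamVector,
    neg: ParamVector,
    n_neg: int = 200,
    n_pos: int = 300,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Score/label rows from a generating pair, shuffled, label 1 = positive."""
    scores = np.concatenate(
        [sample(neg, n_neg, 2 * seed + 1), sample(pos, n_pos, 2 * seed + 2)]
    )
    labels = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    order = np.random.default_rng(seed).permutation(scores.size)
    return scores[order], labels[order]
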