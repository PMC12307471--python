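"""Local adaptive weighting (LAW) and the final refined feature set.

Each feature gets a cohort-level score s_i (mean, optionally median, of its
transformed values over patients); the weight is the sigmoid

    W_i = 1 / (1 + exp(-gamma * (s_i - mu)))

with mu the grand mean of all scores, so features scoring above the cohort
average are emphasised (W > 0.5) and below-average ones attenuated, smoothly
and strictly within (0, 1).  gamma controls how sharply the sigmoid
discriminates around mu.

The refined feature set keeps one weighted column per retained feature
(column i times W_i); the scalar per-patient weighted sum over all features
is also emitted as an auditable summary ("serfe_scalar").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import FeatureMatrix
from .errors import AlignmentError, ValidationError

SCALAR_NAME = "serfe_scalar"


@dataclass
class AdaptiveWeightSet:
    """Per-feature sigmoid weights with the scores they derive from."""

    feature_names: list[str]
    scores: np.ndarray
    mu: float
    gamma: float
    weights: np.ndarray

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names, "score": self.scores, "weight": self.weights}
        )


@dataclass
class RefinedFeatureSet:
    """Weighted feature matrix plus full per-feature provenance.

    ``provenance`` has one row per input feature of the whole pipeline run,
    recording its entropy factor, the fractal shift applied, its adaptive
    weight, and whether/why it was dropped.
    """

    matrix: FeatureMatrix
    weights: AdaptiveWeightSet
    serfe_scalar: np.ndarray
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["feature", "entropy_factor", "fractal_shift", "weight", "status"]
        )
    )


class AdaptiveWeighter:
    """Transformer applying sigmoid weights to feature columns.

    Fitted attributes: ``scores_``, ``mu_``, ``weights_``.
    """

    def __init__(self, gamma: float = 4.0, score_statistic: str = "mean"):
        self.gamma = gamma
        self.score_statistic = score_statistic

    def fit(self, X: np.ndarray, y=None) -> "AdaptiveWeighter":
        if self.gamma <= 0:
            raise ValidationError("gamma must be > 0")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValidationError("adaptive weighting needs a non-empty 2-D matrix")
        if self.score_statistic == "mean":
            self.scores_ = X.mean(axis=0)
        elif self.score_statistic == "median":
            self.scores_ = np.median(X, axis=0)
        else:
            raise ValidationError("score_statistic must be 'mean' or 'median'")
        self.mu_ = float(self.scores_.mean())
        if X.shape[1] == 1:
            warnings.warn(
                "single-feature matrix: adaptive weight is 0.5 by construction",
                stacklevel=2,
            )
        self.weights_ = expit(self.gamma * (self.scores_ - self.mu_))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.weights_.shape[0]:
            raise AlignmentError("matrix width does not match fitted weights")
        return X * self.weights_

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"gamma": self.gamma, "score_statistic": self.score_statistic}

    def set_params(self, **params) -> "AdaptiveWeighter":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


def compute_adaptive_weights(
    matrix: FeatureMatrix, gamma: float = 4.0, score_statistic: str = "mean"
) -> AdaptiveWeightSet:
    """Sigmoid weights W_i = sigmoid(gamma * (s_i - mu)) from cohort feature scores."""
    est = AdaptiveWeighter(gamma=gamma, score_statistic=score_statistic).fit(matrix.values)
    return AdaptiveWeightSet(
        list(matrix.feature_names), est.scores_, est.mu_, gamma, est.weights_
    )


def compose_refined(
    matrix: FeatureMatrix, weights: AdaptiveWeightSet
) -> RefinedFeatureSet:
    """Apply adaptive weights column-wise and emit the per-patient weighted sum."""
    if matrix.feature_names != weights.feature_names:
        raise AlignmentError("weight set features do not match the matrix")
    weighted = matrix.with_values(matrix.values * weights.weights)
    scalar = matrix.values @ weights.weights
    return RefinedFeatureSet(matrix=weighted, weights=weights, serfe_scalar=scalar)
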