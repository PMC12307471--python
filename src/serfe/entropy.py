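"""Entropy-driven feature refinement (EFR).

Each feature's Shannon entropy is estimated from an equal-width histogram of
its cohort distribution on [0, 1].  Features are then re-scaled by
``(H_i / H_max) ** alpha`` so that high-information features keep their
magnitude while low-information ones are shrunk, and features whose entropy
falls below a floor are discarded outright as carrying too little information
to discriminate anything.

Entropy is reported in bits (log base 2); the base cancels in the weighting
ratio but is fixed for reporting.  Probabilities are maximum-likelihood bin
frequencies with no smoothing — smoothing would destroy the exact H = 0
behaviour of constant features that the relevance filter relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FeatureMatrix
from .errors import AlignmentError, DegenerateDataError, ValidationError

_RANGE_TOL = 1e-9


@dataclass
class EntropyProfile:
    """Per-feature entropy summary backing the weighting and the filter."""

    feature_names: list[str]
    entropy_bits: np.ndarray
    bin_count: int
    alpha: float
    floor: float

    @property
    def h_max(self) -> float:
        return float(self.entropy_bits.max())

    @property
    def factors(self) -> np.ndarray:
        """Weight factors (H_i / H_max) ** alpha, in [0, 1]."""
        return (self.entropy_bits / self.h_max) ** self.alpha

    @property
    def low_information(self) -> np.ndarray:
        return self.entropy_bits < self.floor

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "H_bits": self.entropy_bits,
                "factor": self.factors,
                "low_information": self.low_information,
            }
        )


def histogram_entropy_bits(column: np.ndarray, bins: int) -> float:
    """Shannon entropy in bits of one feature's equal-width histogram on [0, 1]."""
    counts, _ = np.histogram(column, bins=bins, range=(0.0, 1.0))
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


class EntropyRefiner:
    """Transformer combining entropy weighting and the relevance filter.

    fit() estimates per-feature entropies on a [0, 1]-normalized matrix;
    transform() drops low-information columns and multiplies the survivors by
    their entropy factor.  Fitted attributes: ``entropy_bits_``, ``h_max_``,
    ``factors_``, ``low_information_``, ``support_``.
    """

    def __init__(self, bins: int = 64, floor: float = 0.5, alpha: float = 1.0):
        self.bins = bins
        self.floor = floor
        self.alpha = alpha

    def fit(self, X: np.ndarray, y=None) -> "EntropyRefiner":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValidationError("entropy estimation needs >= 2 patients")
        if X.min() < -_RANGE_TOL or X.max() > 1 + _RANGE_TOL:
            raise ValidationError(
                "entropy estimation expects features normalized to [0, 1]"
            )
        self.entropy_bits_ = np.array(
            [histogram_entropy_bits(X[:, j], self.bins) for j in range(X.shape[1])]
        )
        if self.entropy_bits_.max() == 0.0:
            raise DegenerateDataError(
                "all features are constant (H_max = 0); entropy weighting undefined"
            )
        self.h_max_ = float(self.entropy_bits_.max())
        self.factors_ = (self.entropy_bits_ / self.h_max_) ** self.alpha
        self.low_information_ = self.entropy_bits_ < self.floor
        self.support_ = ~self.low_information_
        if not self.support_.any():
            raise DegenerateDataError("relevance filter would drop every feature")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.entropy_bits_.shape[0]:
            raise AlignmentError("matrix width does not match fitted profile")
        return (X * self.factors_)[:, self.support_]

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"bins": self.bins, "floor": self.floor, "alpha": self.alpha}

    def set_params(self, **params) -> "EntropyRefiner":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


def estimate_entropy(
    matrix: FeatureMatrix, bins: int = 64, floor: float = 0.5, alpha: float = 1.0
) -> EntropyProfile:
    """Per-feature histogram entropy of a [0, 1]-normalized feature matrix."""
    refiner = EntropyRefiner(bins=bins, floor=floor, alpha=alpha).fit(matrix.values)
    return EntropyProfile(
        list(matrix.feature_names), refiner.entropy_bits_, bins, alpha, floor
    )


def _check_aligned(matrix: FeatureMatrix, profile: EntropyProfile) -> None:
    if matrix.feature_names != profile.feature_names:
        raise AlignmentError("entropy profile features do not match the matrix")


def entropy_weight_transform(
    matrix: FeatureMatrix, profile: EntropyProfile, alpha: float | None = None
) -> FeatureMatrix:
    """Multiply column i by (H_i / H_max) ** alpha.

    The maximal-entropy feature is unchanged; alpha = 0 is the identity.
    """
    _check_aligned(matrix, profile)
    a = profile.alpha if alpha is None else alpha
    if a < 0:
        raise ValidationError("alpha must be >= 0")
    factors = (profile.entropy_bits / profile.h_max) ** a
    return matrix.with_values(matrix.values * factors)


def relevance_filter(
    matrix: FeatureMatrix, profile: EntropyProfile
) -> tuple[FeatureMatrix, list[str]]:
    """Drop features flagged low-information; returns (filtered, dropped names)."""
    _check_aligned(matrix, profile)
    keep = ~profile.low_information
    if not keep.any():
        raise DegenerateDataError("relevance filter would drop every feature")
    kept_names = [f for f, k in zip(matrix.feature_names, keep) if k]
    dropped = [f for f, k in zip(matrix.feature_names, keep) if not k]
    return matrix.select_features(kept_names), dropped
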