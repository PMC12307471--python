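"""Feature-quality metrology: redundancy and test-retest stability.

Redundancy: a feature is redundant when its absolute Pearson correlation with
an already-retained feature exceeds a threshold (0.85 by default).  Retention
is greedy in descending priority — by default the adaptive weight, ties broken
lexicographically by name — so that the more informative member of a
correlated pair survives.  The redundancy rate is the percentage of features
flagged redundant relative to the candidate count.

Stability: each feature's intraclass correlation coefficient (ICC) is
estimated from repeated extractions by a one-way random-effects ANOVA,

    ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2),

where sigma_b^2 is between-subject and sigma_w^2 within-subject variance.
Features with ICC >= 0.75 (default) count as stable; the stability score is
the percentage of stable features among the candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FeatureMatrix, ReplicateSet
from .errors import ValidationError

DROP_REASONS = ("low_entropy", "redundant", "unstable")


@dataclass
class FilterReport:
    """Aggregated quality-filter outcome for one pipeline run."""

    initial_features: list[str]
    retained_features: list[str]
    dropped: list[tuple[str, str]]  # (feature, reason)
    redundancy_rate: float | None = None
    stability_score: float | None = None
    icc: dict[str, float] | None = None
    variance_components: dict[str, tuple[float, float]] | None = None
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        retained = set(self.retained_features)
        dropped_list = [f for f, _ in self.dropped]
        dropped = set(dropped_list)
        if len(dropped) != len(dropped_list):
            raise ValidationError("a feature was dropped more than once")
        if retained & dropped:
            raise ValidationError(
                f"features both retained and dropped: {sorted(retained & dropped)}"
            )
        if retained | dropped != set(self.initial_features):
            raise ValidationError(
                "retained + dropped does not partition the initial feature set"
            )
        for f, reason in self.dropped:
            if reason not in DROP_REASONS:
                raise ValidationError(f"unknown drop reason {reason!r} for {f!r}")

    def to_dict(self) -> dict:
        return {
            "n_initial": len(self.initial_features),
            "n_retained": len(self.retained_features),
            "retained_features": self.retained_features,
            "dropped": [{"feature": f, "reason": r} for f, r in self.dropped],
            "redundancy_rate_pct": self.redundancy_rate,
            "stability_score_pct": (
                self.stability_score if self.stability_score is not None else "not_assessed"
            ),
            "icc": self.icc if self.icc is not None else "not_assessed",
            "thresholds": self.thresholds,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def drop_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["feature", "reason"])


class RedundancyFilter:
    """Greedy Pearson-correlation de-duplication.

    Fitted attributes: ``support_`` (boolean retained mask), ``dropped_``
    (column indices), ``redundancy_rate_`` (percent of candidates dropped).
    """

    def __init__(self, threshold: float = 0.85):
        self.threshold = threshold

    def fit(self, X: np.ndarray, y=None, priority: np.ndarray | None = None,
            names: list[str] | None = None) -> "RedundancyFilter":
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        if n < 3:
            raise ValidationError("redundancy filtering needs >= 3 patients")
        if priority is None:
            priority = np.zeros(m)
        priority = np.asarray(priority, dtype=float)
        if priority.shape != (m,):
            raise ValidationError("priority must cover every feature")
        if names is None:
            names = [str(j) for j in range(m)]
        std = X.std(axis=0)
        degenerate = std == 0
        # scan order: priority desc, name asc on ties
        order = sorted(range(m), key=lambda j: (-priority[j], names[j]))
        centered = X - X.mean(axis=0)
        denom = np.where(degenerate, 1.0, std * np.sqrt(n))
        Z = centered / denom  # so Z_i . Z_j = pearson r for non-degenerate pairs
        retained: list[int] = []
        dropped: list[int] = []
        for j in order:
            if degenerate[j]:
                dropped.append(j)  # r undefined: counted redundant by convention
                continue
            if retained:
                r = np.abs(Z[:, retained].T @ Z[:, j])
                if float(r.max()) > self.threshold:
                    dropped.append(j)
                    continue
            retained.append(j)
        self.support_ = np.zeros(m, dtype=bool)
        self.support_[retained] = True
        self.dropped_ = sorted(dropped)
        self.redundancy_rate_ = 100.0 * len(dropped) / m
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.support_]

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold}

    def set_params(self, **params) -> "RedundancyFilter":
        for k, v in params.items():
            if k != "threshold":
                raise ValueError(f"unknown parameter {k!r}")
            self.threshold = v
        return self


def redundancy_filter(
    matrix: FeatureMatrix,
    threshold: float = 0.85,
    priority: np.ndarray | dict[str, float] | None = None,
) -> tuple[FeatureMatrix, list[str], float]:
    """Drop features correlated above ``threshold`` with a retained feature.

    Returns (retained matrix, dropped names, redundancy rate in percent).
    """
    if isinstance(priority, dict):
        missing = [f for f in matrix.feature_names if f not in priority]
        if missing:
            raise ValidationError(f"priority missing features: {missing}")
        priority = np.array([priority[f] for f in matrix.feature_names])
    est = RedundancyFilter(threshold).fit(
        matrix.values, priority=priority, names=matrix.feature_names
    )
    kept = [f for f, k in zip(matrix.feature_names, est.support_) if k]
    dropped = [matrix.feature_names[j] for j in est.dropped_]
    return matrix.select_features(kept), dropped, est.redundancy_rate_


def icc_estimate(replicates: ReplicateSet) -> pd.DataFrame:
    """Per-feature one-way random-effects ICC with variance components.

    For n subjects and k replicates per subject (balanced), the ANOVA
    estimators are sigma_w^2 = MS_within and
    sigma_b^2 = (MS_between - MS_within) / k clipped at 0;
    ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2), with 0/0 -> 0.
    """
    R = replicates.replicate_values  # (n, m, k)
    n, m, k = R.shape
    if n < 2:
        raise ValidationError("ICC needs >= 2 subjects")
    subj_means = R.mean(axis=2)  # (n, m)
    grand = subj_means.mean(axis=0)  # (m,)
    ms_between = k * ((subj_means - grand) ** 2).sum(axis=0) / (n - 1)
    ms_within = ((R - subj_means[:, :, None]) ** 2).sum(axis=(0, 2)) / (n * (k - 1))
    sigma_b2 = np.clip((ms_between - ms_within) / k, 0.0, None)
    total = sigma_b2 + ms_within
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(total > 0, sigma_b2 / np.where(total > 0, total, 1.0), 0.0)
    return pd.DataFrame(
        {
            "feature": replicates.base.feature_names,
            "icc": icc,
            "sigma_b2": sigma_b2,
            "sigma_w2": ms_within,
        }
    )


class StabilityFilter:
    """Retains features whose test-retest ICC meets the threshold.

    fit() takes a (subjects, features, replicates) array.  Fitted attributes:
    ``icc_``, ``support_``, ``stability_score_`` (percent stable among
    candidates, computed before dropping).
    """

    def __init__(self, threshold: float = 0.75):
        self.threshold = threshold

    def fit(self, R: np.ndarray, y=None) -> "StabilityFilter":
        R = np.asarray(R, dtype=float)
        if R.ndim != 3:
            raise ValidationError("expected a subjects x features x replicates array")
        n, m, k = R.shape
        base = FeatureMatrix(
            [f"s{i}" for i in range(n)], [f"f{j}" for j in range(m)], R.mean(axis=2)
        )
        table = icc_estimate(ReplicateSet(base, R))
        self.icc_ = table["icc"].to_numpy()
        self.support_ = self.icc_ >= self.threshold
        self.stability_score_ = 100.0 * self.support_.sum() / m
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.support_]

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold}

    def set_params(self, **params) -> "StabilityFilter":
        for k, v in params.items():
            if k != "threshold":
                raise ValueError(f"unknown parameter {k!r}")
            self.threshold = v
        return self


def stability_filter(
    iccs: dict[str, float] | pd.DataFrame, threshold: float = 0.75
) -> tuple[list[str], float]:
    """Retain features with ICC >= threshold (inclusive).

    Returns (retained names, stability score in percent over the candidates).
    """
    if isinstance(iccs, pd.DataFrame):
        items = list(zip(iccs["feature"], iccs["icc"]))
    else:
        items = list(iccs.items())
    if not items:
        raise ValidationError("no ICC values supplied")
    retained = [f for f, v in items if v >= threshold]
    score = 100.0 * len(retained) / len(items)
    return retained, score


def relative_redundancy_reduction(baseline_rate: float, refined_rate: float) -> float:
    """Relative reduction (percent) between two redundancy rates."""
    if baseline_rate <= 0:
        raise ValidationError("baseline redundancy rate must be positive")
    return 100.0 * (baseline_rate - refined_rate) / baseline_rate


def assemble_filter_report(
    initial_features: list[str],
    dropped_low_entropy: list[str],
    dropped_redundant: list[str],
    redundancy_rate: float | None,
    dropped_unstable: list[str] | None = None,
    stability_score: float | None = None,
    icc: dict[str, float] | None = None,
    thresholds: dict[str, float] | None = None,
) -> FilterReport:
    """Combine per-stage drop lists into one consistency-checked report."""
    dropped = [(f, "low_entropy") for f in dropped_low_entropy]
    dropped += [(f, "redundant") for f in dropped_redundant]
    if dropped_unstable:
        dropped += [(f, "unstable") for f in dropped_unstable]
    dropped_set = {f for f, _ in dropped}
    retained = [f for f in initial_features if f not in dropped_set]
    return FilterReport(
        initial_features=list(initial_features),
        retained_features=retained,
        dropped=dropped,
        redundancy_rate=redundancy_rate,
        stability_score=stability_score,
        icc=icc,
        thresholds=thresholds or {},
    )
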