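"""Redundancy filtering, ICC estimation and stability scoring."""

import numpy as np
import pandas as pd
import pytest

from serfe import (
    FeatureMatrix,
    ReplicateSet,
    assemble_filter_report,
    icc_estimate,
    redundancy_filter,
    relative_redundancy_reduction,
    stability_filter,
)
from serfe.errors import ValidationError


def _matrix(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{j}" for j in range(values.shape[1])]
    return FeatureMatrix([f"p{i}" for i in range(values.shape[0])], names, values)


class TestRedundancyFilter:
    def test_exact_duplicate_dropped_rate_25(self, rng):
        f1 = rng.standard_normal(50)
        f3 = rng.standard_normal(50)
        f4 = rng.standard_normal(50)
        m = _matrix(np.column_stack([f1, 2 * f1, f3, f4]))
        kept, dropped, rate = redundancy_filter(m, threshold=0.85)
        assert len(dropped) == 1
        assert rate == pytest.approx(25.0)

    def test_three_identical_features_keep_one(self, rng):
        f = rng.standard_normal(30)
        m = _matrix(np.column_stack([f, f, f]))
        kept, dropped, rate = redundancy_filter(m, threshold=0.85)
        assert kept.n_features == 1
        assert rate == pytest.approx(200.0 / 3)

    def test_threshold_one_drops_nothing(self, rng):
        m = _matrix(rng.standard_normal((40, 6)))
        kept, dropped, rate = redundancy_filter(m, threshold=1.0)
        assert dropped == [] and rate == 0.0

    def test_zero_variance_feature_counted_redundant(self, rng):
        vals = rng.standard_normal((20, 3))
        vals[:, 1] = 7.0
        kept, dropped, rate = redundancy_filter(_matrix(vals), threshold=0.85)
        assert "f1" in dropped

    def test_priority_decides_survivor(self, rng):
        f = rng.standard_normal(30)
        m = _matrix(np.column_stack([f, f + rng.normal(0, 0.01, 30)]), ["low", "high"])
        kept, dropped, _ = redundancy_filter(
            m, threshold=0.85, priority={"low": 0.1, "high": 0.9}
        )
        assert kept.feature_names == ["high"] and dropped == ["low"]

    def test_postfilter_no_pair_above_threshold(self, rng):
        """Brute-force oracle: full pairwise scan of the retained set."""
        base = rng.standard_normal((60, 8))
        noisy_dups = base[:, :4] + rng.normal(0, 0.05, (60, 4))
        m = _matrix(np.column_stack([base, noisy_dups]))
        kept, _, _ = redundancy_filter(m, threshold=0.85)
        r = np.corrcoef(kept.values, rowvar=False)
        off_diag = np.abs(r[~np.eye(kept.n_features, dtype=bool)])
        assert off_diag.max() <= 0.85

    def test_too_few_patients_rejected(self, rng):
        with pytest.raises(ValidationError):
            redundancy_filter(_matrix(rng.standard_normal((2, 3))))


def _replicates(R):
    R = np.asarray(R, dtype=float)
    n, m, _ = R.shape
    base = _matrix(R.mean(axis=2), [f"f{j}" for j in range(m)])
    return ReplicateSet(base, R)


class TestICC:
    def test_identical_replicates_give_icc_one(self):
        R = np.array([[[1.0, 1.0]], [[2.0, 2.0]], [[3.0, 3.0]]])
        table = icc_estimate(_replicates(R))
        assert table["icc"][0] == pytest.approx(1.0)
        assert table["sigma_w2"][0] == 0.0

    def test_pure_noise_clipped_to_zero(self, rng):
        # all subjects share one mean; replicate scatter is pure noise
        R = rng.normal(5.0, 1.0, (40, 1, 4))
        table = icc_estimate(_replicates(R))
        assert 0.0 <= table["icc"][0] < 0.2

    def test_shift_invariance_and_scale_equivariance(self, rng):
        R = rng.standard_normal((30, 2, 3)) + rng.standard_normal((30, 1, 1))
        base = icc_estimate(_replicates(R))["icc"].to_numpy()
        shifted = icc_estimate(_replicates(R + 100.0))["icc"].to_numpy()
        scaled = icc_estimate(_replicates(R * 7.0))["icc"].to_numpy()
        np.testing.assert_allclose(base, shifted, atol=1e-9)
        np.testing.assert_allclose(base, scaled, atol=1e-9)

    @pytest.mark.parametrize("sb2, sw2", [(1, 1), (3, 1), (1, 3), (9, 1)])
    def test_parameter_recovery(self, sb2, sw2):
        """ANOVA estimator recovers the population ICC on the variance grid."""
        rng = np.random.default_rng(42)
        n, k, reps = 200, 3, 50
        target = sb2 / (sb2 + sw2)
        estimates = []
        for _ in range(reps):
            true = rng.normal(0, np.sqrt(sb2), (n, 1))
            R = true[:, :, None] + rng.normal(0, np.sqrt(sw2), (n, 1, k))
            estimates.append(icc_estimate(_replicates(R))["icc"][0])
        assert np.mean(estimates) == pytest.approx(target, abs=0.03)


class TestStabilityFilter:
    def test_score_is_percentage_of_stable(self):
        iccs = {f"f{j}": (0.9 if j < 92 else 0.1) for j in range(100)}
        retained, score = stability_filter(iccs, threshold=0.75)
        assert score == pytest.approx(92.0)
        assert len(retained) == 92

    def test_threshold_zero_retains_all(self):
        # every clipped ICC is >= 0, so a 0 threshold keeps everything
        retained, score = stability_filter({"a": 0.0, "b": 0.5}, threshold=0.0)
        assert score == 100.0 and sorted(retained) == ["a", "b"]

    def test_threshold_is_inclusive(self):
        retained, _ = stability_filter(
            {"a": 0.8, "b": 0.74999, "c": 0.75}, threshold=0.75
        )
        assert sorted(retained) == ["a", "c"]


class TestFilterReport:
    def test_conservation(self, default_cohort):
        base, labels, reps, truth = default_cohort
        report = assemble_filter_report(
            initial_features=base.feature_names,
            dropped_low_entropy=truth.low_entropy,
            dropped_redundant=truth.redundant[:5],
            redundancy_rate=5.0,
        )
        assert len(report.retained_features) + len(report.dropped) == base.n_features

    def test_no_replicates_marked_not_assessed(self):
        report = assemble_filter_report(["a", "b"], [], [], 0.0)
        d = report.to_dict()
        assert d["stability_score_pct"] == "not_assessed"
        assert d["icc"] == "not_assessed"

    def test_inconsistent_partition_rejected(self):
        with pytest.raises(ValidationError):
            assemble_filter_report(["a"], ["a"], ["a"], 50.0)


def test_relative_redundancy_reduction_arithmetic():
    assert relative_redundancy_reduction(40.0, 10.0) == pytest.approx(75.0)
    with pytest.raises(ValidationError):
        relative_redundancy_reduction(0.0, 1.0)
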