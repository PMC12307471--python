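"""Entropy estimation, weighting and relevance filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serfe import (
    FeatureMatrix,
    entropy_weight_transform,
    estimate_entropy,
    min_max_normalize,
    relevance_filter,
)
from serfe.entropy import EntropyRefiner, histogram_entropy_bits
from serfe.errors import AlignmentError, DegenerateDataError


def _matrix(columns: dict[str, list[float]]) -> FeatureMatrix:
    names = list(columns)
    values = np.array([columns[c] for c in names]).T
    ids = [f"p{i}" for i in range(values.shape[0])]
    return FeatureMatrix(ids, names, values)


class TestEstimateEntropy:
    def test_uniform_k_bins_gives_log2_k(self):
        # one value per bin across k = 8 occupied bins, equal counts
        k, bins = 8, 64
        centers = (np.arange(k) + 0.5) / bins
        m = _matrix({"f": centers.tolist()})
        prof = estimate_entropy(m, bins=bins, floor=0.0)
        assert prof.entropy_bits[0] == pytest.approx(np.log2(k), abs=1e-12)

    def test_constant_feature_zero_entropy_flagged(self):
        m = _matrix({"c": [0.3] * 10, "v": np.linspace(0, 1, 10).tolist()})
        prof = estimate_entropy(m, bins=16, floor=0.5)
        assert prof.entropy_bits[0] == 0.0
        assert prof.low_information[0] and not prof.low_information[1]

    def test_half_quarter_quarter_is_1_5_bits(self):
        # bin probabilities (0.5, 0.25, 0.25)
        vals = [0.05, 0.05, 0.35, 0.65]
        m = _matrix({"f": vals})
        prof = estimate_entropy(m, bins=10, floor=0.0)
        assert prof.entropy_bits[0] == pytest.approx(1.5, abs=1e-12)

    def test_all_constant_matrix_is_degenerate(self):
        m = _matrix({"a": [0.5] * 5, "b": [0.2] * 5})
        with pytest.raises(DegenerateDataError):
            estimate_entropy(m, bins=16)

    def test_entropy_bounded_by_log2_bins(self, rng):
        col = rng.uniform(0, 1, 500)
        h = histogram_entropy_bits(col, 32)
        assert 0 <= h <= np.log2(32)

    def test_permutation_invariance(self, rng):
        col = rng.uniform(0, 1, 100)
        h1 = histogram_entropy_bits(col, 64)
        h2 = histogram_entropy_bits(rng.permutation(col), 64)
        assert h1 == h2

    def test_affine_rescale_then_renormalize_preserves_entropy(self, rng):
        # same bin occupancy after re-normalization => same H
        col = rng.uniform(0, 1, 200)
        m1 = _matrix({"f": col.tolist()})
        m2 = _matrix({"f": (5 * col - 2).tolist()})
        m1n, _ = min_max_normalize(m1)
        m2n, _ = min_max_normalize(m2)
        p1 = estimate_entropy(m1n, bins=32, floor=0.0)
        p2 = estimate_entropy(m2n, bins=32, floor=0.0)
        assert p1.entropy_bits[0] == pytest.approx(p2.entropy_bits[0], abs=1e-12)


class TestEntropyWeightTransform:
    @pytest.fixture
    def normalized(self, rng):
        vals = np.column_stack(
            [rng.uniform(0, 1, 50), rng.beta(0.2, 0.2, 50), np.clip(rng.normal(0.5, 0.05, 50), 0, 1)]
        )
        return FeatureMatrix([f"p{i}" for i in range(50)], ["u", "b", "n"], vals)

    def test_alpha_zero_is_identity(self, normalized):
        prof = estimate_entropy(normalized, bins=32, floor=0.0)
        out = entropy_weight_transform(normalized, prof, alpha=0.0)
        np.testing.assert_array_equal(out.values, normalized.values)

    def test_max_entropy_feature_unchanged(self, normalized):
        prof = estimate_entropy(normalized, bins=32, floor=0.0)
        out = entropy_weight_transform(normalized, prof, alpha=2.0)
        j = int(np.argmax(prof.entropy_bits))
        np.testing.assert_array_equal(out.values[:, j], normalized.values[:, j])

    def test_half_entropy_alpha_one_halves_column(self):
        m = _matrix({"f": [0.1, 0.9] * 8, "g": [0.4, 0.6] * 8})
        prof = estimate_entropy(m, bins=2, floor=0.0)
        # force an exact ratio via a synthetic profile
        prof.entropy_bits = np.array([4.0, 2.0])
        out = entropy_weight_transform(m, prof, alpha=1.0)
        np.testing.assert_allclose(out.values[:, 1], 0.5 * m.values[:, 1])

    def test_composition_in_alpha(self, normalized):
        prof = estimate_entropy(normalized, bins=32, floor=0.0)
        once = entropy_weight_transform(
            entropy_weight_transform(normalized, prof, alpha=0.7), prof, alpha=1.3
        )
        direct = entropy_weight_transform(normalized, prof, alpha=2.0)
        np.testing.assert_allclose(once.values, direct.values, rtol=1e-12)

    def test_misaligned_profile_rejected(self, normalized):
        prof = estimate_entropy(normalized, bins=32, floor=0.0)
        other = normalized.select_features(["b", "u", "n"])
        with pytest.raises(AlignmentError):
            entropy_weight_transform(other, prof)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(alpha=st.floats(0.0, 5.0))
    def test_factors_in_unit_interval(self, alpha):
        rng = np.random.default_rng(0)
        vals = np.clip(rng.uniform(0, 1, (30, 5)), 0, 1)
        m = FeatureMatrix([f"p{i}" for i in range(30)], [f"f{j}" for j in range(5)], vals)
        prof = estimate_entropy(m, bins=16, floor=0.0, alpha=alpha)
        f = prof.factors
        assert np.all((0 <= f) & (f <= 1)) and np.isclose(f.max(), 1.0)


class TestRelevanceFilter:
    def test_constant_feature_dropped(self):
        m = _matrix({"c": [0.5] * 10, "v": np.linspace(0, 1, 10).tolist()})
        prof = estimate_entropy(m, bins=16, floor=0.5)
        out, dropped = relevance_filter(m, prof)
        assert dropped == ["c"] and out.feature_names == ["v"]

    def test_floor_zero_drops_nothing_nonconstant(self, rng):
        vals = rng.uniform(0, 1, (20, 4))
        m = FeatureMatrix([f"p{i}" for i in range(20)], list("abcd"), vals)
        prof = estimate_entropy(m, bins=16, floor=0.0)
        out, dropped = relevance_filter(m, prof)
        assert dropped == [] and out.n_features == 4

    def test_constructed_low_entropy_counts(self, rng):
        # 10 features, 3 built as near-constant spikes below the 0.5-bit floor
        cols = {}
        for j in range(7):
            cols[f"hi{j}"] = rng.uniform(0, 1, 60).tolist()
        for j in range(3):
            col = np.full(60, 0.5)
            col[j] = 1.0  # single outlier: H = h(1/60) << 0.5 bits
            cols[f"lo{j}"] = col.tolist()
        m = _matrix(cols)
        prof = estimate_entropy(m, bins=64, floor=0.5)
        out, dropped = relevance_filter(m, prof)
        assert sorted(dropped) == ["lo0", "lo1", "lo2"]
        assert out.n_features == 7

    def test_refiner_transform_matches_functions(self, rng):
        vals = np.clip(rng.uniform(0, 1, (40, 6)), 0, 1)
        m = FeatureMatrix([f"p{i}" for i in range(40)], [f"f{j}" for j in range(6)], vals)
        ref = EntropyRefiner(bins=32, floor=0.0, alpha=1.5)
        out = ref.fit_transform(m.values)
        prof = estimate_entropy(m, bins=32, floor=0.0, alpha=1.5)
        expected = entropy_weight_transform(m, prof).values
        np.testing.assert_allclose(out, expected)
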