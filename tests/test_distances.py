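import numpy as np
import pandas as pd
import pytest

from germdiv import (
    BandMatrix,
    TraitTable,
    binary_distance,
    euclidean_distance,
    gower_distance,
    pearson_similarity,
)
from germdiv.errors import (
    DataError,
    IncomparablePairError,
    UndefinedCorrelationError,
)


class TestEuclidean:
    def test_three_four_five(self):
        d = euclidean_distance([[0, 0], [3, 4]], standardize=False)
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_identical_rows_zero(self):
        d = euclidean_distance([[1, 2, 3], [1, 2, 3]], standardize=False)
        assert d.values[0, 1] == 0.0

    def test_constant_feature_dropped(self):
        X = pd.DataFrame({"v": [0.0, 1.0, 2.0], "const": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="const"):
            d = euclidean_distance(X, standardize=True)
        # z-scores of [0,1,2] with population SD sqrt(2/3)
        z = (np.array([0, 1, 2]) - 1) / np.sqrt(2 / 3)
        assert d.values[0, 2] == pytest.approx(abs(z[2] - z[0]))

    def test_missing_is_hard_error(self):
        with pytest.raises(DataError, match="impute"):
            euclidean_distance([[1.0, np.nan], [0.0, 1.0]])

    def test_affine_feature_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.random((5, 3))
        Y = X.copy()
        Y[:, 1] = 100.0 * Y[:, 1] - 7.0
        d1 = euclidean_distance(X, standardize=True)
        d2 = euclidean_distance(Y, standardize=True)
        assert np.allclose(d1.values, d2.values)

    def test_triangle_inequality_sampled(self):
        rng = np.random.default_rng(1)
        d = euclidean_distance(rng.random((8, 4)), standardize=True)
        for _ in range(50):
            i, j, k = rng.integers(0, 8, size=3)
            assert d.values[i, j] <= d.values[i, k] + d.values[k, j] + 1e-9


class TestGower:
    def test_counting_law_qualitative(self):
        values = pd.DataFrame(
            {"q1": ["a", "a"], "q2": ["b", "b"], "q3": ["c", "d"], "q4": ["e", "e"]},
            index=["g1", "g2"],
        )
        t = TraitTable(values, {f"q{i}": "qualitative" for i in range(1, 5)})
        assert gower_distance(t).values[0, 1] == pytest.approx(0.25)

    def test_mixed_example(self):
        values = pd.DataFrame(
            {"size": [2.0, 7.0, 12.0], "color": ["red", "red", "red"]},
            index=["g1", "g2", "g3"],
        )
        t = TraitTable(values, {"size": "quantitative", "color": "qualitative"})
        # range 10: |2-7|/10 = 0.5 averaged with matching qualitative 0
        assert gower_distance(t).values[0, 1] == pytest.approx(0.25)

    def test_identical_rows(self, trait_table_small):
        d = gower_distance(trait_table_small)
        assert np.all(np.diag(d.values) == 0)
        assert d.values.max() <= 1.0 + 1e-12

    def test_pairwise_deletion(self):
        values = pd.DataFrame(
            {"x": [0.0, np.nan, 10.0], "c": ["a", "a", "b"]},
            index=["g1", "g2", "g3"],
        )
        t = TraitTable(values, {"x": "quantitative", "c": "qualitative"})
        d = gower_distance(t)
        assert d.values[0, 1] == pytest.approx(0.0)  # only c comparable, equal
        assert d.values[0, 2] == pytest.approx((1.0 + 1.0) / 2)

    def test_incomparable_pair_rejected(self):
        values = pd.DataFrame(
            {"x": [1.0, np.nan], "y": [np.nan, 2.0]}, index=["g1", "g2"]
        )
        t = TraitTable(values, {"x": "quantitative", "y": "quantitative"})
        with pytest.raises(IncomparablePairError):
            gower_distance(t)

    def test_equals_simple_matching_on_binary_qualitative(self):
        rng = np.random.default_rng(2)
        raw = rng.integers(0, 2, size=(6, 5))
        ids = [f"g{i}" for i in range(6)]
        values = pd.DataFrame(
            {f"q{j}": [str(v) for v in raw[:, j]] for j in range(5)}, index=ids
        )
        t = TraitTable(values, {f"q{j}": "qualitative" for j in range(5)})
        bands = [f"q{j}" for j in range(5)]
        m = BandMatrix(ids, bands, {b: "P1" for b in bands}, raw.astype(float))
        assert np.allclose(
            gower_distance(t).values, binary_distance(m, "simple-matching").values
        )


class TestBinary:
    def _matrix(self, rows):
        calls = np.asarray(rows, dtype=float)
        bands = [f"b{j}" for j in range(calls.shape[1])]
        return BandMatrix(
            [f"g{i}" for i in range(calls.shape[0])],
            bands,
            {b: "P1" for b in bands},
            calls,
        )

    def test_identical_profiles(self):
        m = self._matrix([[1, 0, 1, 0], [1, 0, 1, 0]])
        assert binary_distance(m, "simple-matching").values[0, 1] == 0.0
        assert binary_distance(m, "jaccard").values[0, 1] == 0.0

    def test_full_mismatch(self):
        m = self._matrix([[1, 0, 1, 0], [0, 1, 0, 1]])
        assert binary_distance(m, "simple-matching").values[0, 1] == 1.0

    def test_jaccard_counts(self):
        m = self._matrix([[1, 1, 0, 0], [1, 0, 1, 0]])
        assert binary_distance(m, "jaccard").values[0, 1] == pytest.approx(1 - 1 / 3)

    def test_missing_excluded_pairwise(self):
        m = self._matrix([[1, 0, np.nan], [1, 1, 1]])
        assert binary_distance(m, "simple-matching").values[0, 1] == pytest.approx(0.5)

    def test_no_shared_bands_rejected(self):
        m = self._matrix([[1, np.nan], [np.nan, 1]])
        with pytest.raises(IncomparablePairError):
            binary_distance(m)


class TestPearson:
    def test_self_and_negation(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        sim, dist = pearson_similarity(X)
        assert sim.iloc[0, 0] == pytest.approx(1.0)
        assert sim.iloc[0, 1] == pytest.approx(-1.0)
        assert dist.values[0, 1] == pytest.approx(2.0)

    def test_affine_invariance(self):
        sim, dist = pearson_similarity([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        assert sim.iloc[0, 1] == pytest.approx(1.0)
        assert dist.values[0, 1] == pytest.approx(0.0)

    def test_constant_profile_named(self):
        with pytest.raises(UndefinedCorrelationError, match="flatty"):
            pearson_similarity(
                pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                             index=["flatty", "ok"])
            )
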