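import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from germdiv import (
    BandMatrix,
    band_frequency,
    band_informativeness,
    discriminating_power,
    gene_diversity_band,
    panel_summary,
    pic_band,
    primer_summary,
)
from germdiv.errors import DegenerateBandError, InsufficientDataError


def _matrix_from_calls(calls, n_primers=1):
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    bands = [f"b{j}" for j in range(m)]
    per = int(np.ceil(m / n_primers))
    primers = {b: f"P{j // per + 1}" for j, b in enumerate(bands)}
    return BandMatrix([f"g{i}" for i in range(n)], bands, primers, calls)


class TestPerBand:
    @pytest.mark.parametrize(
        "calls,expected",
        [([1, 1, 1, 1], 1.0), ([1, 0, np.nan, 0], 1 / 3), ([1, 0, 1, 0], 0.5)],
    )
    def test_frequency(self, calls, expected):
        assert band_frequency(calls) == pytest.approx(expected)

    def test_all_missing_band_is_degenerate(self):
        with pytest.raises(DegenerateBandError):
            band_frequency([np.nan, np.nan])

    @pytest.mark.parametrize(
        "p,H,PIC,Ib",
        [
            (0.5, 0.5, 0.375, 1.0),
            (0.0, 0.0, 0.0, 0.0),
            (1.0, 0.0, 0.0, 0.0),
            (0.2, 0.32, 0.2688, 0.4),
            (0.75, 0.375, 0.3046875, 0.5),
        ],
    )
    def test_informativeness_formulas(self, p, H, PIC, Ib):
        assert gene_diversity_band(p) == pytest.approx(H)
        assert pic_band(p) == pytest.approx(PIC)
        assert band_informativeness(p) == pytest.approx(Ib)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_ordering_and_symmetry(self, p):
        """0 <= PIC <= H <= 0.5, equality only at fixed bands; p <-> 1-p symmetry."""
        H, PIC = gene_diversity_band(p), pic_band(p)
        assert -1e-12 <= PIC <= H + 1e-12 <= 0.5 + 1e-12
        if 1e-9 < p < 1 - 1e-9:  # strict gap away from the fixed-band limits
            assert PIC < H
        q = 1.0 - p
        assert H == pytest.approx(gene_diversity_band(q))
        assert PIC == pytest.approx(pic_band(q))
        assert band_informativeness(p) == pytest.approx(band_informativeness(q))


class TestDiscriminatingPower:
    def test_extremes(self):
        same = np.tile([1, 0, 1], (5, 1))
        assert discriminating_power(same) == pytest.approx(0.0)
        unique = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert discriminating_power(unique) == pytest.approx(1.0)

    def test_known_pattern_counts(self):
        # N=4, pattern counts {2,1,1} -> 1 - 0.5/3
        calls = np.array([[1, 1], [1, 1], [0, 1], [1, 0]])
        assert discriminating_power(calls) == pytest.approx(1 - 0.5 / 3)

    def test_matches_pairwise_brute_force(self):
        """DP = P(two genotypes drawn without replacement differ in pattern)."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(2, 7)
            m = rng.integers(1, 5)
            calls = rng.integers(0, 2, size=(n, m)).astype(float)
            pairs = list(itertools.combinations(range(n), 2))
            differ = sum(
                1 for i, j in pairs if not np.array_equal(calls[i], calls[j])
            )
            assert discriminating_power(calls) == pytest.approx(differ / len(pairs))

    def test_missing_genotypes_excluded(self):
        calls = np.array([[1.0, 0.0], [np.nan, 1.0], [0.0, 1.0], [1.0, 0.0]])
        # g1 dropped -> patterns {10:2, 01:1} over N=3
        expected = 1 - (2 / 3 * (3 * 2 / 3 - 1) / 2 + 1 / 3 * (3 / 3 - 1) / 2)
        assert discriminating_power(calls) == pytest.approx(expected)

    def test_too_few_complete_genotypes(self):
        calls = np.array([[1.0, np.nan], [np.nan, 1.0], [0.0, 1.0]])
        with pytest.raises(InsufficientDataError):
            discriminating_power(calls)


class TestPrimerAndPanelSummaries:
    def test_all_half_frequency_bands(self):
        # 10 bands at p = 0.5 with 4 genotypes
        col = [1, 1, 0, 0]
        calls = np.column_stack([col] * 10)
        m = _matrix_from_calls(calls)
        s = primer_summary(m, "P1")
        assert s.polymorphic_bands == 10
        assert s.percent_polymorphic == 100.0
        assert s.E == pytest.approx(10.0)
        assert s.MI == pytest.approx(3.75)
        assert s.RP == pytest.approx(10.0)

    def test_monomorphic_primer(self):
        calls = np.column_stack([[1, 1, 1], [0, 0, 0], [1, 1, 1]])
        m = _matrix_from_calls(calls)
        s = primer_summary(m, "P1")
        assert s.polymorphic_bands == 0
        assert s.percent_polymorphic == 0.0
        assert s.E == s.MI == s.RP == 0.0

    def test_e_formula_switch(self, band_matrix_small):
        mult = primer_summary(band_matrix_small, "P1", e_formula="multiplex")
        frac = primer_summary(band_matrix_small, "P1", e_formula="fraction")
        assert mult.E == pytest.approx(frac.E * mult.n_bands)

    def test_partial_polymorphism_percentage(self):
        # 16 bands, 9 polymorphic -> 56.25%
        poly = np.column_stack([[1, 0, 1, 0]] * 9)
        mono = np.column_stack([[1, 1, 1, 1]] * 7)
        m = _matrix_from_calls(np.hstack([poly, mono]))
        s = primer_summary(m, "P1")
        assert s.percent_polymorphic == pytest.approx(56.25)

    def test_panel_totals_and_averages(self, band_matrix_small):
        summ = panel_summary(band_matrix_small)
        assert summ.total_bands == 6
        per = summ.per_primer
        assert summ.total_polymorphic == per["polymorphic_bands"].sum()
        assert summ.mean_polymorphic_per_primer == pytest.approx(
            summ.total_polymorphic / len(per)
        )

    def test_single_primer_panel_averages_are_identity(self):
        calls = np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0]], dtype=float)
        m = _matrix_from_calls(calls)
        summ = panel_summary(m)
        s = primer_summary(m, "P1")
        assert summ.averages["MI"] == pytest.approx(s.MI)
        assert summ.averages["RP"] == pytest.approx(s.RP)

    def test_permutation_invariance(self, band_matrix_small):
        m = band_matrix_small
        rng = np.random.default_rng(3)
        gp = rng.permutation(m.n_genotypes)
        bp = rng.permutation(m.n_bands)
        shuffled = BandMatrix(
            [m.genotype_ids[i] for i in gp],
            [m.band_ids[j] for j in bp],
            m.primer_of_band,
            m.calls[np.ix_(gp, bp)],
        )
        a, b = panel_summary(m), panel_summary(shuffled)
        assert a.total_bands == b.total_bands
        assert a.total_polymorphic == b.total_polymorphic
        assert np.allclose(
            a.averages.sort_index(), b.averages.sort_index()
        )
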