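"""Concordance statistics, with an independent brute-force oracle for the
exact symmetry test (full cartesian enumeration in rational arithmetic)."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gistvol.concordance import (
    SquareTable,
    bland_altman,
    bowker_statistic,
    cross_tabulate,
    exact_symmetry_test,
    spearman,
)


def oracle_exact_p(table: SquareTable) -> Fraction:
    """Enumerate every off-diagonal configuration jointly (independent of
    the implementation's convolution over per-pair distributions)."""
    pairs = [(a, b) for a, b in table.discordant_pairs() if a + b > 0]
    if not pairs:
        return Fraction(1)
    pmfs = [
        [Fraction(math.comb(a + b, x), 2 ** (a + b)) for x in range(a + b + 1)]
        for a, b in pairs
    ]
    observed = Fraction(1)
    for (a, b), pmf in zip(pairs, pmfs):
        observed *= pmf[a]
    total = Fraction(0)
    for combo in itertools.product(*pmfs):
        prob = Fraction(1)
        for q in combo:
            prob *= q
        if prob <= observed:
            total += prob
    return total


def table3(counts):
    return SquareTable.from_array(counts, ("A", "B", "C"))


class TestSquareTable:
    def test_marginals(self):
        t = table3([[12, 1, 1], [16, 11, 6], [0, 1, 2]])
        assert t.row_totals() == (14, 33, 3)
        assert t.col_totals() == (28, 13, 9)
        assert t.total == 50

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            SquareTable(("A", "B"), ((1, 2, 3), (4, 5, 6)))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            table3([[1, -1, 0], [0, 0, 0], [0, 0, 0]])


class TestCrossTabulate:
    def test_table2_training_3mo_reconstruction(self):
        # Rebuild per-patient call series from the printed counts and
        # check the marginals come back.
        counts = [[12, 1, 1], [16, 11, 6], [0, 1, 2]]
        labels = ("DECREASE", "NO_CHANGE", "INCREASE")
        calls_a, calls_b = {}, {}
        k = 0
        for i, row in enumerate(counts):
            for j, c in enumerate(row):
                for _ in range(c):
                    calls_a[f"P{k}"] = labels[i]
                    calls_b[f"P{k}"] = labels[j]
                    k += 1
        t = cross_tabulate(calls_a, calls_b, labels)
        assert t.row_totals() == (14, 33, 3)
        assert t.col_totals() == (28, 13, 9)
        assert t.total == 50

    def test_identical_series_is_diagonal(self):
        calls = {"P1": "A", "P2": "B", "P3": "A"}
        t = cross_tabulate(calls, dict(calls), ("A", "B"))
        assert t.counts == ((2, 0), (0, 1))

    def test_swapped_pair_is_symmetric(self):
        a = {"P1": "A", "P2": "B"}
        b = {"P1": "B", "P2": "A"}
        t = cross_tabulate(a, b, ("A", "B"))
        assert t.counts == ((0, 1), (1, 0))

    def test_mismatched_subjects_listed(self):
        with pytest.raises(ValueError, match="P2"):
            cross_tabulate({"P1": "A", "P2": "A"}, {"P1": "A"}, ("A",))


class TestExactSymmetry:
    def test_training_12mo(self):
        # discordant pairs (5 vs 0) and (4 vs 0): p = 4 * (1/2)^9
        t = table3([[23, 0, 0], [5, 7, 4], [0, 0, 7]])
        res = exact_symmetry_test(t)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(4 * 0.5**9)
        assert res.n_discordant == 9

    def test_validation_6mo(self):
        # pairs (1 vs 6) and (1 vs 0): enumeration gives exactly 1/8
        t = table3([[12, 1, 0], [6, 3, 1], [0, 0, 4]])
        res = exact_symmetry_test(t)
        assert res.p_value == pytest.approx(0.125)
        assert oracle_exact_p(t) == Fraction(1, 8)

    def test_symmetric_table_p_one(self):
        t = table3([[5, 3, 0], [3, 2, 1], [0, 1, 4]])
        assert exact_symmetry_test(t).p_value == pytest.approx(1.0)

    def test_all_zero_off_diagonal(self):
        t = table3([[5, 0, 0], [0, 2, 0], [0, 0, 4]])
        res = exact_symmetry_test(t)
        assert res.p_value == 1.0
        assert res.n_discordant == 0

    @pytest.mark.parametrize("n", [1, 2, 5, 10])
    def test_single_pair_closed_form(self, n):
        t = SquareTable.from_array([[0, n], [0, 0]], ("A", "B"))
        assert exact_symmetry_test(t).p_value == pytest.approx(2 * 0.5**n)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            counts = rng.integers(0, 7, size=(3, 3))
            t = table3(counts.tolist())
            res = exact_symmetry_test(t, method="exact")
            assert res.p_value == pytest.approx(float(oracle_exact_p(t)), rel=1e-12)

    @given(st.lists(st.integers(min_value=0, max_value=6), min_size=9, max_size=9))
    @settings(max_examples=60, deadline=None)
    def test_transpose_invariance(self, flat):
        counts = [flat[:3], flat[3:6], flat[6:]]
        if sum(flat) == 0:
            counts[0][0] = 1
        t = table3(counts)
        assert exact_symmetry_test(t).p_value == pytest.approx(
            exact_symmetry_test(t.transpose()).p_value
        )

    @given(st.lists(st.integers(min_value=0, max_value=6), min_size=9, max_size=9),
           st.permutations([0, 1, 2]))
    @settings(max_examples=60, deadline=None)
    def test_relabel_invariance(self, flat, perm):
        counts = np.array(flat).reshape(3, 3)
        if counts.sum() == 0:
            counts[0, 0] = 1
        t = table3(counts.tolist())
        relabeled = table3(counts[np.ix_(perm, perm)].tolist())
        assert exact_symmetry_test(t).p_value == pytest.approx(
            exact_symmetry_test(relabeled).p_value
        )

    def test_bowker_tracks_exact_extremeness_ranking(self):
        """On larger tables the asymptotic statistic should order tables by
        extremeness like the exact p (strong inverse rank correlation)."""
        rng = np.random.default_rng(7)
        chi2s, ps = [], []
        for _ in range(40):
            counts = rng.integers(0, 12, size=(3, 3))
            t = table3(counts.tolist())
            if t.array.sum() == 0:
                continue
            chi2, df = bowker_statistic(t)
            if df == 0:
                continue
            chi2s.append(chi2)
            ps.append(exact_symmetry_test(t, method="exact").p_value)
        rho = stats.spearmanr(chi2s, ps).statistic
        assert rho < -0.85

    def test_asymptotic_method_reported(self):
        t = table3([[0, 30, 0], [10, 0, 0], [0, 0, 1]])
        res = exact_symmetry_test(t, method="asymptotic_bowker")
        assert res.method == "asymptotic_bowker"
        assert res.statistic == pytest.approx((30 - 10) ** 2 / 40)


class TestBlandAltman:
    def test_identity(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(a, a)
        assert res.bias == 0
        assert res.loa_low == res.loa_high == 0
        assert res.relative_variability_pct == 0

    def test_constant_offset_sign_convention(self):
        a = np.array([10.0, 20.0, 30.0])
        res = bland_altman(a, a + 2)
        assert res.sign_convention == "a-b"
        assert res.bias == pytest.approx(-2.0)
        assert res.sd_diff == pytest.approx(0.0)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])

    def test_recovers_simulated_variability(self):
        """Paired 1D measurements differing by 0.15% CV noise only."""
        rng = np.random.default_rng(1)
        truth = rng.lognormal(math.log(40), 0.4, size=4000)
        cv = 0.0015
        sigma = math.sqrt(math.log(1 + cv**2))
        a = truth * np.exp(rng.normal(0, sigma, truth.size))
        b = truth * np.exp(rng.normal(0, sigma, truth.size))
        res = bland_altman(a, b)
        # E|a-b|/mid for two independent CV-sigma log-normals ~ 2*sigma/sqrt(pi)
        expected = 100 * 2 * math.sqrt(2) * sigma / math.sqrt(2 * math.pi)
        assert res.relative_variability_pct == pytest.approx(expected, rel=0.1)
        assert abs(res.bias) < 0.05


class TestSpearman:
    def test_monotone(self):
        r, p = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(5))

    def test_reversed(self):
        r, _ = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_exact_permutation_matches_scipy_r(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=8)
        y = x + rng.normal(scale=0.5, size=8)
        r, p = spearman(x, y)
        assert r == pytest.approx(stats.spearmanr(x, y).statistic)
        assert 0 < p < 1

    def test_cube_law_pairs_strongly_correlated(self):
        """Diameter/volume pairs under the cube law with measurement noise."""
        rng = np.random.default_rng(9)
        d = rng.lognormal(math.log(40), 0.45, size=300)
        v = (math.pi / 6) * d**3 * np.exp(rng.normal(0, 0.096, d.size))
        r, p = spearman(d, v)
        assert r >= 0.95
        assert p < 1e-4
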