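"""Exact-test oracle equivalence, BH correction, fold changes, DE calls.

The NB exact test is checked against an independent oracle that
enumerates the conditional split distribution in exact rational
arithmetic (``fractions.Fraction``): for dispersions whose inverse is an
integer the NB pmf is, up to a factor common to every split, a product
of binomial coefficients and rational powers, so p-values are computed
with zero rounding error.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xregen.de_analysis import (
    DEConfig,
    bh_adjust,
    call_de,
    compute_log2fc,
    estimate_dispersion,
    filter_expressed,
    nb_exact_test,
    normalize_libsizes,
    run_de,
)
from xregen.io_formats import CountMatrix


def exact_conditional_pvalue(a, b, size_a=1, size_b=1, phi=Fraction(0)):
    """Independent oracle: exact rational two-sided conditional p-value.

    phi must be 0 or have an integer inverse (e.g. 1/10, 1/20, 1/2).
    """
    s = a + b
    if s == 0:
        return Fraction(1)
    frac = Fraction(size_a, size_a + size_b) if isinstance(size_a, int) else (
        Fraction(size_a) / (Fraction(size_a) + Fraction(size_b))
    )
    phi = Fraction(phi)
    if phi == 0:
        f = [comb(s, k) * frac**k * (1 - frac) ** (s - k) for k in range(s + 1)]
    else:
        r = 1 / phi
        assert r.denominator == 1, "oracle needs an integer inverse dispersion"
        r = int(r)
        mu_a, mu_b = s * frac, s * (1 - frac)
        q_a = mu_a / (r + mu_a)  # NB failure probability, exact rational
        q_b = mu_b / (r + mu_b)
        f = [
            comb(k + r - 1, k) * q_a**k * comb(s - k + r - 1, s - k) * q_b ** (s - k)
            for k in range(s + 1)
        ]
    obs = f[a]
    return sum(x for x in f if x <= obs) / sum(f)


def bh_oracle(p):
    """Independent brute-force step-up: adj_(i) = min_{j>=i} p_(j) m / j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_pos, i in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestExactTest:
    def test_symmetric_mode_gives_p_one(self):
        for phi in (0.0, 0.1, 0.5):
            assert nb_exact_test(5, 5, 1, 1, phi) == 1.0

    def test_extreme_binomial_tail_closed_form(self):
        assert nb_exact_test(0, 50, 1, 1, 0.0) == pytest.approx(2 * 2**-50, rel=1e-9)

    def test_zero_total_is_uninformative(self):
        assert nb_exact_test(0, 0) == 1.0

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(1, 2, dispersion=-0.1)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.1, 0.5])
    def test_matches_exact_rational_oracle_small_totals(self, phi):
        phi_frac = Fraction(phi).limit_denominator(100)
        worst = 0.0
        for s in range(0, 21):
            for a in range(s + 1):
                got = nb_exact_test(a, s - a, 1, 1, phi)
                want = float(exact_conditional_pvalue(a, s - a, 1, 1, phi_frac))
                worst = max(worst, abs(got - want))
        assert worst < 1e-10

    def test_unequal_library_sizes_against_oracle(self):
        for a, b in [(3, 9), (0, 12), (7, 2), (10, 10)]:
            got = nb_exact_test(a, b, 2.0, 1.0, 0.1)
            want = float(exact_conditional_pvalue(a, b, 2, 1, Fraction(1, 10)))
            assert got == pytest.approx(want, abs=1e-10)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = rng.integers(0, 300, size=2)
            p = nb_exact_test(int(a), int(b), 1.3, 0.9, 0.1)
            assert 0 < p <= 1


class TestBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, float("nan")])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_bruteforce_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestFilterAndNormalize:
    def _cm(self, rows, times=None, **kw):
        times = times if times is not None else list(range(0, 6 * len(rows[0]), 6))
        return CountMatrix(
            "sp", [f"g{i}" for i in range(len(rows))], times[: len(rows[0])], np.array(rows), **kw
        )

    def test_more_than_20_is_strict(self):
        cm = self._cm([[5, 15, 19], [0, 0, 21]])
        assert filter_expressed(cm, DEConfig()) == ["g1"]

    def test_rpkm_rescues_short_library(self):
        # 10 counts, 1 kb gene, 1e6 library -> rpkm 10 > 1 although counts <= 20
        counts = np.zeros((2, 3), dtype=int)
        counts[0] = [10, 10, 10]
        counts[1] = [999990, 999990, 999990]  # filler so library size is 1e6
        cm = self._cm(counts.tolist(), gene_length_bp=np.array([1000.0, 1e9]))
        kept = filter_expressed(cm, DEConfig())
        assert "g0" in kept

    def test_equal_sums_unit_factors(self):
        cm = self._cm([[10, 10], [5, 5]])
        np.testing.assert_allclose(normalize_libsizes(cm), [1.0, 1.0])

    def test_geometric_mean_formula(self):
        cm = CountMatrix("sp", ["g0"], [0, 6], np.array([[1_000_000, 2_000_000]]))
        np.testing.assert_allclose(
            normalize_libsizes(cm), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_single_column_unit_factor(self):
        cm = CountMatrix("sp", ["g0"], [0], np.array([[7]]))
        np.testing.assert_allclose(normalize_libsizes(cm), [1.0])

    def test_median_ratio_ignores_composition(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=(500, 2))
        base[:20, 1] *= 8  # asymmetric DE inflates the total of column 2
        cm = self._cm(base.tolist())
        f = normalize_libsizes(cm, method="median_ratio")
        assert abs(f[1] / f[0] - 1) < 0.05


class TestLog2FC:
    def test_direct_formula(self):
        cm = CountMatrix("sp", ["g0"], [0, 6], np.array([[10, 40]]))
        fc = compute_log2fc(cm, np.array([1.0, 1.0]), DEConfig())
        assert fc[0, 1] == pytest.approx(np.log2(40.5 / 10.5))

    def test_identical_columns_zero(self):
        cm = CountMatrix("sp", ["g0", "g1"], [0, 6], np.array([[3, 3], [9, 9]]))
        fc = compute_log2fc(cm, np.array([1.0, 1.0]), DEConfig())
        np.testing.assert_allclose(fc, 0.0)

    def test_zero_vs_zero_is_zero(self):
        cm = CountMatrix("sp", ["g0"], [0, 6], np.array([[0, 0]]))
        fc = compute_log2fc(cm, np.array([1.0, 1.0]), DEConfig())
        assert fc[0, 1] == 0.0


class TestCallDE:
    def test_thresholds_strict(self):
        fc = np.array([[0.0, 2.5, 2.0, 3.0]])
        padj = np.array([[1.0, 0.01, 0.01, 0.06]])
        is_de, gene_de = call_de(fc, padj, DEConfig())
        assert is_de.tolist() == [[False, True, False, False]]
        assert gene_de.tolist() == [True]

    def test_scaling_columns_preserves_sign_driven_calls(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(100, size=(50, 3))
        counts[0, 1:] *= 16
        cm = CountMatrix("sp", [f"g{i}" for i in range(50)], [0, 6, 12], counts)
        res1 = run_de(cm, DEConfig(dispersion=0.0))
        cm2 = CountMatrix("sp", cm.gene_ids, cm.time_points_h, counts * 3)
        res2 = run_de(cm2, DEConfig(dispersion=0.0))
        s1 = np.sign(res1.table.set_index(["gene_id", "time_h"]).log2fc)
        s2 = np.sign(res2.table.set_index(["gene_id", "time_h"]).log2fc)
        both = res1.table.set_index(["gene_id", "time_h"]).is_de & res2.table.set_index(
            ["gene_id", "time_h"]
        ).is_de
        assert (s1[both] == s2[both]).all()


def test_estimate_dispersion_recovers_order_of_magnitude():
    rng = np.random.default_rng(3)
    phi, mu = 0.1, 200.0
    r = 1 / phi
    counts = rng.negative_binomial(r, r / (r + mu), size=(3000, 6))
    cm = CountMatrix("sp", [f"g{i}" for i in range(3000)], [0, 6, 12, 24, 36, 48], counts)
    est = estimate_dispersion(cm)
    assert 0.05 < est < 0.2
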