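"""Statistical core: hypergeometric overlap tests, Fisher's exact test,
chi-square, combined score and p-value adjustment, checked against exact
enumeration oracles and independent reference implementations."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from scarskit.enrichment import (
    ContingencyTable2x2,
    OverlapParams,
    adjust_pvalues,
    chi_square_test,
    combined_score,
    fisher_exact_two_tailed,
    gene_set_enrichment,
    hypergeom_overlap_test,
    hypergeom_sf,
)
from scarskit.io_formats import GeneSetLibrary


# ---------------------------------------------------------------------------
# exact-rational enumeration oracles (independent of the log-space code path)
# ---------------------------------------------------------------------------


def oracle_pmf(N: int, K: int, n: int) -> dict[int, Fraction]:
    """Hypergeometric pmf by exact integer combinatorics."""
    denom = math.comb(N, n)
    lo, hi = max(0, n + K - N), min(n, K)
    return {
        k: Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
        for k in range(lo, hi + 1)
    }


def oracle_sf(N: int, K: int, n: int, k: int) -> Fraction:
    pmf = oracle_pmf(N, K, n)
    return sum((p for kk, p in pmf.items() if kk >= k), Fraction(0))


def oracle_fisher_two_tailed(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-tailed Fisher p by exact enumeration over the conditional support."""
    N, r1, c1 = a + b + c + d, a + b, a + c
    pmf = oracle_pmf(N, c1, r1)  # table indexed by its a cell
    observed = pmf[a]
    # exact rational arithmetic: no tie tolerance needed
    return sum((p for p in pmf.values() if p <= observed), Fraction(0))


# ---------------------------------------------------------------------------
# hypergeometric overlap test
# ---------------------------------------------------------------------------


class TestHypergeomOverlap:
    def test_pmf_oracle_sums_to_one(self):
        for N in range(1, 61, 7):
            for K in range(0, N + 1, max(1, N // 4)):
                for n in range(0, N + 1, max(1, N // 4)):
                    total = sum(oracle_pmf(N, K, n).values())
                    assert total == 1

    def test_sf_matches_oracle_for_all_small_populations(self):
        """Log-space tail equals exact enumeration over every N <= 60."""
        for N in range(1, 61):
            for K in range(0, N + 1, max(1, N // 5)):
                for n in range(0, N + 1, max(1, N // 5)):
                    lo, hi = max(0, n + K - N), min(n, K)
                    for k in range(lo, hi + 1):
                        exact = float(oracle_sf(N, K, n, k))
                        got = hypergeom_sf(k, N, K, n)
                        assert got == pytest.approx(exact, rel=1e-10)

    def test_sf_matches_scipy_at_scale(self):
        # independent cross-check at the population sizes the tables use
        for N, K, n, k in [(26178, 9430, 100, 91), (63677, 18766, 1496, 762)]:
            assert hypergeom_sf(k, N, K, n) == pytest.approx(
                scipy.stats.hypergeom.sf(k - 1, N, K, n), rel=1e-10
            )

    def test_small_example_brute_force(self):
        """(N=40, K=10, n=8, k=2): tail equals the explicit binomial sum."""
        expected = sum(
            math.comb(10, j) * math.comb(30, 8 - j) for j in range(2, 9)
        ) / math.comb(40, 8)
        result = hypergeom_overlap_test(OverlapParams(40, 10, 8, 2))
        assert result.p == pytest.approx(expected, rel=1e-12)

    def test_saturated_sample_has_p_one(self):
        assert hypergeom_overlap_test(OverlapParams(10, 10, 5, 5)).p == 1.0

    def test_p_non_increasing_in_k(self):
        N, K, n = 500, 120, 60
        ps = [hypergeom_sf(k, N, K, n) for k in range(0, min(n, K) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_expected_and_oe(self):
        r = hypergeom_overlap_test(OverlapParams(26178, 9430, 100, 91))
        assert r.expected == pytest.approx(100 * 9430 / 26178)
        assert r.oe_ratio == pytest.approx(91 / r.expected)

    def test_tiny_p_representable(self):
        # the deepest tail in the reproduced tables is ~1e-109 and must be a
        # positive float; beyond float underflow the log-scale tail and the
        # combined score stay finite
        r = hypergeom_overlap_test(OverlapParams(63677, 25421, 836, 647))
        assert 0.0 < r.p < 1e-100
        extreme = hypergeom_overlap_test(OverlapParams(63677, 25421, 836, 836))
        assert extreme.log_p < -700 and np.isfinite(extreme.log_p)
        assert np.isfinite(extreme.combined)

    def test_k_zero_with_empty_margin(self):
        r = hypergeom_overlap_test(OverlapParams(100, 0, 10, 0))
        assert r.p == 1.0 and r.oe_ratio is None

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            OverlapParams(100, 0, 10, 1)  # k > 0 with no successes
        with pytest.raises(ValueError):
            OverlapParams(100, 20, 10, 11)  # k > n
        with pytest.raises(ValueError):
            OverlapParams(100, 120, 10, 5)  # K > N


class TestCombinedScore:
    def test_p_one_gives_zero(self):
        assert combined_score(1.0, OverlapParams(100, 20, 10, 2)) == 0.0

    def test_k_at_expectation_gives_zero(self):
        params = OverlapParams(100, 20, 10, 2)  # expected = 2 exactly
        assert combined_score(0.5, params) == 0.0

    def test_direct_evaluation(self):
        params = OverlapParams(100, 20, 10, 8)
        p = hypergeom_sf(8, 100, 20, 10)
        z = (8 - 2.0) / math.sqrt(10 * 0.2 * 0.8 * (90 / 99))
        assert combined_score(p, params) == pytest.approx(math.log(p) * z)

    def test_zero_variance_is_missing(self):
        assert combined_score(1.0, OverlapParams(10, 10, 5, 5)) is None

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            combined_score(0.0, OverlapParams(100, 20, 10, 2))


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((3, 1, 1, 3), 34 / 70),
            ((5, 0, 0, 5), 2 / 252),
            ((2, 2, 2, 2), 1.0),
        ],
    )
    def test_enumeration_examples(self, table, expected):
        assert fisher_exact_two_tailed(ContingencyTable2x2(*table)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_two_tailed(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        st.tuples(
            st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
        ).filter(lambda t: sum(t) > 0)
    )
    def test_matches_exact_oracle_and_dominates_one_tail(self, counts):
        a, b, c, d = counts
        table = ContingencyTable2x2(a, b, c, d)
        N, r1, c1 = a + b + c + d, a + b, a + c
        if r1 in (0, N) or c1 in (0, N):
            return  # degenerate margins covered separately
        p = fisher_exact_two_tailed(table)
        assert p == pytest.approx(float(oracle_fisher_two_tailed(a, b, c, d)), rel=1e-9)
        one_tail = min(
            float(oracle_sf(N, c1, r1, a)),
            float(sum(q for k, q in oracle_pmf(N, c1, r1).items() if k <= a)),
        )
        assert p >= one_tail - 1e-12

    def test_matches_scipy_reference(self):
        for counts in [(12, 5, 7, 14), (1, 9, 11, 3), (8, 8, 8, 8)]:
            a, b, c, d = counts
            _, p_ref = scipy.stats.fisher_exact([[a, b], [c, d]])
            assert fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d)) == pytest.approx(
                p_ref, rel=1e-9
            )


class TestChiSquare:
    def test_balanced_table(self):
        assert chi_square_test(ContingencyTable2x2(10, 10, 10, 10)) == 1.0

    def test_hand_computed_statistic(self):
        # stat = 50*(|20*20-5*5|)^2 / 25^4 = 18
        p = chi_square_test(ContingencyTable2x2(20, 5, 5, 20))
        assert p == pytest.approx(float(scipy.stats.chi2.sf(18.0, 1)), rel=1e-12)

    def test_yates_matches_reference(self):
        table = ContingencyTable2x2(20, 5, 5, 20)
        _, p_ref, _, _ = scipy.stats.chi2_contingency(
            [[20, 5], [5, 20]], correction=True
        )
        assert chi_square_test(table, correction=True) == pytest.approx(p_ref, rel=1e-12)

    def test_zero_expected_cell_raises(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            chi_square_test(ContingencyTable2x2(3, 4, 0, 0))

    def test_agrees_with_fisher_for_large_counts(self):
        table = ContingencyTable2x2(515, 485, 485, 515)
        p_chi = chi_square_test(table)
        p_fisher = fisher_exact_two_tailed(table)
        assert p_chi == pytest.approx(p_fisher, rel=0.10)


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------


class TestAdjustPvalues:
    def test_bonferroni_hand_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "bonferroni") == pytest.approx(
            [0.03, 0.06, 0.09]
        )

    def test_bh_step_up_hand_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "bh") == pytest.approx([0.03] * 3)

    def test_single_p_unchanged(self):
        for method in ("bh", "bonferroni"):
            assert adjust_pvalues([0.2], method) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bh")

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_bh_monotone_and_dominates_nominal(self, ps):
        adjusted = adjust_pvalues(ps, "bh")
        assert np.all(adjusted >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adjusted[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# library-wide enrichment
# ---------------------------------------------------------------------------


class TestGeneSetEnrichment:
    def test_background_as_library_set(self):
        background = [f"g{i}" for i in range(50)]
        lib = GeneSetLibrary()
        lib.add("all", "", background)
        (result,) = gene_set_enrichment(background[:10], lib, background)
        assert result.params.k == result.params.n == 10
        assert result.oe_ratio == pytest.approx(1.0)
        assert result.p == 1.0

    def test_disjoint_query_all_zero(self):
        background = [f"g{i}" for i in range(40)]
        lib = GeneSetLibrary()
        lib.add("s1", "", background[20:30])
        results = gene_set_enrichment(background[:5], lib, background)
        assert all(r.params.k == 0 for r in results)

    def test_empty_query_rejected(self):
        lib = GeneSetLibrary()
        lib.add("s", "", ["a"])
        with pytest.raises(ValueError):
            gene_set_enrichment([], lib, ["a", "b"])

    def test_sorted_by_p_with_name_tie_break(self):
        background = [f"g{i}" for i in range(30)]
        lib = GeneSetLibrary()
        lib.add("zeta", "", background[:5])
        lib.add("alpha", "", background[:5])  # identical overlap: p ties
        results = gene_set_enrichment(background[:10], lib, background)
        assert [r.set_name for r in results] == ["alpha", "zeta"]
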