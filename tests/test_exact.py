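"""Exact-test module: Fisher closed forms, Boschloo oracles and properties."""

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given
from hypothesis import strategies as hst

from cladodem.exact import (
    TwoByTwoTable,
    boschloo_all_tables,
    boschloo_test,
    fisher_exact,
    fisher_p_grid,
    pairwise_clonality_tests,
)


def brute_force_boschloo(table, alternative, grid_points=10_000):
    """Independent oracle: scipy Fisher p per candidate table, rejection
    mass summed over all (n_a+1)(n_b+1) outcomes on a uniform pi grid."""
    n_a, n_b = table.n_a, table.n_b
    alt = {"two_sided": "two-sided"}.get(alternative, alternative)
    F = np.empty((n_a + 1, n_b + 1))
    for xa in range(n_a + 1):
        for xb in range(n_b + 1):
            F[xa, xb] = st.fisher_exact(
                [[xa, n_a - xa], [xb, n_b - xb]], alternative=alt
            ).pvalue
    mask = F <= F[table.successes_a, table.successes_b] * (1 + 1e-12)
    grid = np.linspace(1e-6, 1 - 1e-6, grid_points)
    tot = np.zeros(grid.size)
    for xa in range(n_a + 1):
        pa = st.binom.pmf(xa, n_a, grid)
        for xb in range(n_b + 1):
            if mask[xa, xb]:
                tot += pa * st.binom.pmf(xb, n_b, grid)
    return float(tot.max())


class TestFisher:
    def test_maximally_unbalanced_table_hits_hypergeometric_atom(self):
        # one-sided p of (10,0 / 0,10) is the single most extreme table:
        # 1 / C(20,10)
        t = TwoByTwoTable(10, 0, 0, 10)
        from math import comb

        assert fisher_exact(t, "greater") == pytest.approx(1 / comb(20, 10), rel=1e-12)

    def test_balanced_table_is_never_evidence(self):
        assert fisher_exact(TwoByTwoTable(5, 5, 5, 5), "two_sided") == 1.0

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_matches_scipy_on_random_tables(self, alternative):
        rng = np.random.default_rng(42)
        alt = {"two_sided": "two-sided"}.get(alternative, alternative)
        for _ in range(25):
            n_a, n_b = rng.integers(2, 15, size=2)
            xa, xb = rng.integers(0, n_a + 1), rng.integers(0, n_b + 1)
            mine = fisher_exact(TwoByTwoTable(xa, n_a - xa, xb, n_b - xb), alternative)
            ref = st.fisher_exact(
                [[xa, n_a - xa], [xb, n_b - xb]], alternative=alt
            ).pvalue
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_grid_agrees_with_elementwise_calls(self):
        grid = fisher_p_grid(6, 4, "two_sided")
        for xa in (0, 3, 6):
            for xb in (0, 2, 4):
                t = TwoByTwoTable(xa, 6 - xa, xb, 4 - xb)
                assert grid[xa, xb] == pytest.approx(fisher_exact(t, "two_sided"))


class TestBoschloo:
    @pytest.mark.parametrize(
        "table, alternative",
        [
            (TwoByTwoTable(7, 3, 2, 8), "greater"),
            (TwoByTwoTable(7, 3, 2, 8), "two_sided"),
            (TwoByTwoTable(24, 6, 10, 14), "greater"),
            (TwoByTwoTable(5, 5, 5, 5), "two_sided"),
            (TwoByTwoTable(1, 9, 6, 4), "less"),
        ],
    )
    def test_matches_brute_force_enumeration(self, table, alternative):
        mine = boschloo_test(table, alternative)
        oracle = brute_force_boschloo(table, alternative)
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_headline_rooting_table_against_dense_oracle(self):
        # 24 rooted of 30 vs 10 of 24, one-sided: the headline clonality
        # contrast shape
        t = TwoByTwoTable(24, 6, 10, 14)
        assert boschloo_test(t, "greater") == pytest.approx(
            brute_force_boschloo(t, "greater"), abs=1e-6
        )

    def test_matches_scipy_one_sided(self):
        # scipy's boschloo_exact takes samples as columns
        for (xa, na, xb, nb) in [(7, 10, 2, 10), (24, 30, 10, 24), (3, 8, 5, 8)]:
            t = TwoByTwoTable(xa, na - xa, xb, nb - xb)
            ref = st.boschloo_exact(
                [[xa, xb], [na - xa, nb - xb]], alternative="greater"
            ).pvalue
            assert boschloo_test(t, "greater") == pytest.approx(ref, abs=1e-7)

    def test_equal_proportions_give_p_one(self):
        assert boschloo_test(TwoByTwoTable(4, 4, 4, 4), "two_sided") == 1.0

    @given(
        xa=hst.integers(0, 8),
        xb=hst.integers(0, 8),
        na=hst.integers(1, 8),
        nb=hst.integers(1, 8),
        alternative=hst.sampled_from(["greater", "less", "two_sided"]),
    )
    def test_never_exceeds_fisher(self, xa, xb, na, nb, alternative):
        if xa > na or xb > nb:
            return
        t = TwoByTwoTable(xa, na - xa, xb, nb - xb)
        assert boschloo_test(t, alternative) <= fisher_exact(t, alternative) + 1e-10

    def test_row_swap_mirrors_alternative(self):
        t = TwoByTwoTable(9, 3, 4, 8)
        assert boschloo_test(t, "greater") == pytest.approx(
            boschloo_test(t.swapped(), "less"), abs=1e-9
        )

    def test_grid_doubling_is_stable(self):
        t = TwoByTwoTable(17, 13, 8, 16)
        p1 = boschloo_test(t, "two_sided", grid_points=1000)
        p2 = boschloo_test(t, "two_sided", grid_points=2000)
        assert abs(p1 - p2) < 1e-4

    def test_all_tables_matches_single_calls(self):
        allp = boschloo_all_tables(6, 5, "greater")
        for xa in (0, 2, 6):
            for xb in (0, 3, 5):
                t = TwoByTwoTable(xa, 6 - xa, xb, 5 - xb)
                single = boschloo_test(t, "greater", refine=False)
                assert allp[xa, xb] == pytest.approx(single, abs=1e-12)

    def test_validity_attained_size_never_exceeds_alpha(self):
        # enumeration at n_a = n_b = 10: for every nuisance pi the
        # rejection probability at alpha = 0.05 stays below alpha
        n = 10
        pvals = np.empty((n + 1, n + 1))
        for xa in range(n + 1):
            for xb in range(n + 1):
                pvals[xa, xb] = boschloo_test(
                    TwoByTwoTable(xa, n - xa, xb, n - xb), "two_sided"
                )
        reject = pvals <= 0.05
        grid = np.linspace(0.01, 0.99, 99)
        pa = st.binom.pmf(np.arange(n + 1)[:, None], n, grid[None, :])
        size = np.einsum("ig,jg,ij->g", pa, pa, reject.astype(float))
        assert size.max() <= 0.05 + 1e-9

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(0, 0, 3, 4)


class TestPairwiseClonality:
    def test_three_genders_emit_six_tests(self, small_bundle):
        out = pairwise_clonality_tests(small_bundle.clonality)
        assert len(out) == 6
        assert set(out.outcome) == {"rooted", "budded"}

    def test_all_rooted_everywhere_is_null(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "cladode_id": [f"c{i}" for i in range(12)],
                "gender": ["male"] * 6 + ["female"] * 6,
                "rooted": 1,
                "budded": 1,
            }
        )
        out = pairwise_clonality_tests(df)
        assert (out.boschloo_p_two == 1.0).all()

    def test_missing_column_is_an_input_error(self):
        import pandas as pd

        with pytest.raises(ValueError, match="rooted"):
            pairwise_clonality_tests(pd.DataFrame({"gender": ["male"]}))
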