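"""Effect sizes, pooling, bootstrap and p-value combination."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from cladodem.meta import (
    EffectSize,
    bootstrap_ci,
    combine_pvalues_correlated,
    d_continuous,
    d_dichotomous,
    gender_comparison,
    hedges_correction,
    pool,
)


def eff(d, v, pair=("male", "hermaphrodite"), trait="t", p=0.5):
    return EffectSize(trait, pair[0], pair[1], d, v, p, "continuous")


class TestHedgesCorrection:
    def test_limit_and_value(self):
        assert hedges_correction(10) == pytest.approx(1 - 3 / 39)
        assert hedges_correction(10**9) == pytest.approx(1.0, abs=1e-8)

    def test_strictly_increasing(self):
        js = [hedges_correction(df) for df in range(2, 200)]
        assert all(b > a for a, b in zip(js, js[1:]))

    def test_small_df_rejected(self):
        with pytest.raises(ValueError):
            hedges_correction(1)


class TestContinuousD:
    def test_hand_computed_chain(self):
        # means 10 vs 8, both sd 2 (se = 2/sqrt(20)), n = 20 each:
        # raw d = 1, J(38) = 1 - 3/151, v = 40/400 + d^2/80
        se = 2.0 / np.sqrt(20)
        e = d_continuous(10.0, se, 20, 8.0, se, 20)
        assert e.d == pytest.approx(0.980, abs=1e-3)
        assert e.v == pytest.approx(0.1120, abs=1e-3)

    def test_equal_means_give_zero(self):
        assert d_continuous(5.0, 0.3, 10, 5.0, 0.4, 12).d == 0.0

    def test_swapping_groups_negates_d_keeps_v(self):
        e1 = d_continuous(10.0, 0.5, 15, 8.0, 0.6, 18)
        e2 = d_continuous(8.0, 0.6, 18, 10.0, 0.5, 15)
        assert e1.d == pytest.approx(-e2.d)
        assert e1.v == pytest.approx(e2.v)

    def test_lower_direction_flips_sign(self):
        e_hi = d_continuous(10.0, 0.5, 15, 8.0, 0.6, 18, direction="higher")
        e_lo = d_continuous(10.0, 0.5, 15, 8.0, 0.6, 18, direction="lower")
        assert e_lo.d == pytest.approx(-e_hi.d)

    def test_zero_spread_with_unequal_means_is_an_error(self):
        with pytest.raises(ValueError):
            d_continuous(10.0, 0.0, 15, 8.0, 0.0, 18)


class TestDichotomousD:
    def test_hand_computed_chain(self):
        # OR = 4 at z = 2: SE = ln(4)/2, d = ln(4)*sqrt(3)/pi
        p_two = 2 * st.norm.sf(2.0)
        e = d_dichotomous(4.0, p_two)
        assert e.d == pytest.approx(np.log(4) * np.sqrt(3) / np.pi, abs=1e-4)
        assert e.d == pytest.approx(0.7645, abs=1e-3)
        assert e.v == pytest.approx(0.1460, abs=1e-3)

    def test_inverted_or_negates_d_keeps_v(self):
        e1 = d_dichotomous(4.0, 0.03)
        e2 = d_dichotomous(0.25, 0.03)
        assert e1.d == pytest.approx(-e2.d)
        assert e1.v == pytest.approx(e2.v)

    def test_unit_or_is_an_error(self):
        with pytest.raises(ValueError):
            d_dichotomous(1.0, 0.5)


class TestPooling:
    def test_single_effect_identity(self):
        r = pool([eff(0.7, 0.2)])
        assert r.d_plus_plus == pytest.approx(0.7)
        assert r.u == pytest.approx(0.7)

    def test_equal_variances_make_both_means_agree(self):
        r = pool([eff(0.2, 0.1), eff(0.8, 0.1), eff(-0.4, 0.1)])
        assert r.d_plus_plus == pytest.approx(r.u, rel=1e-12)

    def test_weighted_mean_bounded_by_extremes(self):
        effects = [eff(0.1, 0.5), eff(1.4, 0.02), eff(-0.3, 0.9)]
        r = pool(effects)
        ds = [e.d for e in effects]
        assert min(ds) <= r.d_plus_plus <= max(ds)

    def test_variance_rescaling_leaves_dpp_unchanged(self):
        effects = [eff(0.1, 0.5), eff(1.4, 0.02), eff(-0.3, 0.9)]
        scaled = [eff(e.d, 7.0 * e.v) for e in effects]
        assert pool(effects).d_plus_plus == pytest.approx(
            pool(scaled).d_plus_plus, rel=1e-12
        )

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            pool([eff(0.1, 0.1), eff(0.2, 0.1, pair=("male", "female"))])
        with pytest.raises(ValueError):
            pool([])


class TestBootstrap:
    def test_identical_effects_collapse_interval(self):
        ci = bootstrap_ci([eff(0.5, 0.1)] * 4, n_boot=200, seed=0)
        lo, hi = ci["ci95_d_plus_plus"]
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_seed_reproducibility(self):
        effects = [eff(0.1, 0.5), eff(1.4, 0.02), eff(-0.3, 0.9)]
        c1 = bootstrap_ci(effects, n_boot=500, seed=3)
        c2 = bootstrap_ci(effects, n_boot=500, seed=3)
        assert c1 == c2

    def test_single_trait_interval_is_degenerate(self):
        ci = bootstrap_ci([eff(0.5, 0.1)], seed=0)
        assert ci["degenerate"]

    def test_interval_spans_point_estimate(self):
        rng = np.random.default_rng(0)
        for rep in range(20):
            effects = [
                eff(float(rng.normal()), float(rng.uniform(0.05, 0.5)))
                for _ in range(6)
            ]
            r = pool(effects)
            ci = bootstrap_ci(effects, n_boot=500, seed=rep)
            lo, hi = ci["ci95_d_plus_plus"]
            assert lo - 1e-9 <= r.d_plus_plus <= hi + 1e-9


class TestCombinePValues:
    def test_all_ones_give_one(self):
        assert combine_pvalues_correlated([1.0] * 5, n_mc=500, seed=0) == 1.0

    def test_matches_fisher_closed_form_under_independence(self):
        p = [0.2, 0.04, 0.5, 0.11, 0.33, 0.71, 0.06, 0.9, 0.15]
        T = -2 * np.sum(np.log(p))
        exact = st.chi2.sf(T, 2 * len(p))
        n_mc = 40_000
        approx = combine_pvalues_correlated(p, n_mc=n_mc, seed=1)
        se = np.sqrt(exact * (1 - exact) / n_mc)
        assert abs(approx - exact) <= 3 * se + 1e-12

    def test_monotone_in_each_p(self):
        base = [0.5] * 9
        sharper = [0.1] + [0.5] * 8
        p_base = combine_pvalues_correlated(base, n_mc=20_000, seed=2)
        p_sharp = combine_pvalues_correlated(sharper, n_mc=20_000, seed=2)
        assert p_sharp <= p_base

    def test_zero_p_is_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            out = combine_pvalues_correlated([0.0, 0.5], n_mc=500, seed=0)
        assert 0.0 <= out <= 1.0


class TestGenderComparison:
    def _null_inputs(self):
        summaries = []
        tests = []
        for trait in ("lag", "max_size", "flowering"):
            for g in ("male", "female", "hermaphrodite"):
                summaries.append(
                    {"trait": trait, "gender": g, "mean": 1.0, "se": 0.1,
                     "n": 20, "direction": "higher"}
                )
            for a, b in (("male", "hermaphrodite"), ("female", "hermaphrodite"),
                         ("male", "female")):
                tests.append(
                    {"trait": trait, "gender_a": a, "gender_b": b,
                     "kind": "continuous", "p_one_tailed": 0.5,
                     "p_two_sided": 1.0, "odds_ratio": np.nan}
                )
        return pd.DataFrame(summaries), pd.DataFrame(tests)

    def test_identical_genders_recover_null(self):
        summaries, tests = self._null_inputs()
        effects, results = gender_comparison(summaries, tests, n_boot=300,
                                             n_mc=500, seed=0)
        assert (effects.d == 0).all()
        for r in results.values():
            assert r.d_plus_plus == pytest.approx(0.0, abs=1e-12)
            lo, hi = r.ci95_d_plus_plus
            assert lo <= 0.0 <= hi

    def test_missing_trait_reduces_k_with_warning(self):
        summaries, tests = self._null_inputs()
        tests = pd.concat(
            [tests,
             pd.DataFrame([{"trait": "ghost", "gender_a": "male",
                            "gender_b": "hermaphrodite", "kind": "continuous",
                            "p_one_tailed": 0.5, "p_two_sided": 1.0,
                            "odds_ratio": np.nan}])],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="ghost"):
            _, results = gender_comparison(summaries, tests, n_boot=100,
                                           n_mc=200, seed=0)
        assert results[("male", "hermaphrodite")].k == 3
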