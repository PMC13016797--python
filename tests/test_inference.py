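"""Statistical layer: frozen oracles, calibration and invariants."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from kinpref.inference import (
    ModelSpec,
    bh_fdr,
    fdr_adjust_families,
    fit_mixed_model,
    likelihood_ratio_anova,
    one_sample_t,
    rank_sum_test,
    spearman_consistency,
    tukey_pairwise,
)
from tests.conftest import relatedness_term


class TestOneSampleT:
    def test_symmetric_values_give_zero_t(self):
        res = one_sample_t([-0.4, 0.4, -0.1, 0.1, -0.25, 0.25])
        assert res.mean == pytest.approx(0.0)
        assert res.t == pytest.approx(0.0)

    def test_df_matches_sample_size_minus_one(self):
        rng = np.random.default_rng(1)
        res = one_sample_t(rng.normal(size=89))
        assert res.df == 88

    def test_matches_textbook_formula(self):
        x = np.array([0.1, 0.2, 0.4])
        res = one_sample_t(x)
        t_expected = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        p_expected = 2 * sps.t.sf(abs(t_expected), len(x) - 1)
        assert res.t == pytest.approx(t_expected)
        assert res.p == pytest.approx(p_expected)

    def test_constant_sample_equal_to_null(self):
        res = one_sample_t([0.5, 0.5, 0.5], popmean=0.5)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([0.1])


def bh_oracle(p):
    """Brute-force BH adjustment: explicit O(m^2) loops over sorted ranks."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for pos, idx in enumerate(order):
        best = 1.0
        for later in range(pos, m):
            cand = m * p[order[later]] / (later + 1)
            best = min(best, cand)
        adj[idx] = best
    return adj


class TestBHFDR:
    def test_female_mating_status_family(self):
        adj = bh_fdr([0.57, 0.94, 0.007, 0.13])
        assert round(adj[2], 2) == 0.03
        assert np.allclose(np.round(adj, 2), [0.76, 0.94, 0.03, 0.26])

    def test_female_relatedness_family(self):
        adj = bh_fdr([0.16, 0.12, 0.23, 0.03])
        assert np.allclose(np.round(adj, 2), [0.21, 0.21, 0.23, 0.12])

    def test_male_mating_status_family(self):
        adj = bh_fdr([0.01, 0.44, 0.008, 0.12])
        assert round(adj[3], 2) == 0.16

    def test_single_element_family_identity(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_matches_brute_force_oracle_on_random_families(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            m = rng.integers(1, 12)
            p = rng.random(m)
            if rng.random() < 0.3:  # exercise ties
                p = np.round(p, 1)
            np.testing.assert_array_equal(bh_fdr(p), bh_oracle(p))

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.random(rng.integers(2, 20))
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)

    def test_adjusted_monotone_in_raw_p(self):
        rng = np.random.default_rng(4)
        p = rng.random(30)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])
        with pytest.raises(ValueError):
            bh_fdr([])

    def test_family_map_adjusts_within_families_only(self):
        table = pd.DataFrame(
            {
                "p": [0.007, 0.57, 0.03, 0.16],
                "fdr_family": ["s", "s", "r", "r"],
            }
        )
        out = fdr_adjust_families(table)
        np.testing.assert_allclose(out["p_adj"], [0.014, 0.57, 0.06, 0.16])


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0)

    def test_extreme_separation_matches_enumeration(self):
        # all 6 rank assignments of {1,2} vs {3,4}: U_x = 0 is the unique
        # minimum; exact two-sided p = 2 * P(U <= 0) = 2/6
        res = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert res.W == 0.0
        assert res.p == pytest.approx(2.0 / 6.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(loc=0.5, size=15)
        base = rank_sum_test(x, y)
        trans = rank_sum_test(np.exp(x), np.exp(y))
        assert base.W == trans.W
        assert base.p == pytest.approx(trans.p)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestSpearman:
    def test_identical_ranking_is_one(self):
        a = np.array([0.3, -0.2, 0.9, 0.1, -0.5])
        res = spearman_consistency(a, a)
        assert res.rho == pytest.approx(1.0)
        assert res.n == 5

    def test_reversed_ranking_is_minus_one(self):
        a = np.array([0.3, -0.2, 0.9, 0.1, -0.5])
        assert spearman_consistency(a, -a).rho == pytest.approx(-1.0)

    def test_null_mean_rho_near_zero_at_study_n(self):
        rng = np.random.default_rng(6)
        rhos = [
            spearman_consistency(rng.normal(size=46), rng.normal(size=46)).rho
            for _ in range(300)
        ]
        rhos = np.asarray(rhos)
        se = rhos.std(ddof=1) / np.sqrt(len(rhos))
        assert abs(rhos.mean()) < 3 * se

    def test_undefined_scores_dropped_pairwise(self):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        res = spearman_consistency(a, b)
        assert res.n == 3
        assert res.rho == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_consistency([1.0, 2.0], [2.0, 1.0])


GAUSS_LEVELS = {"g": ("a", "b")}


def gaussian_data(n, seed, group_sd=0.0, effect=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "x": rng.normal(size=n),
            "g": rng.choice(["a", "b"], n),
            "grp": rng.choice([f"f{i}" for i in range(8)], n),
        }
    )
    offsets = {f"f{i}": rng.normal(0, group_sd) for i in range(8)}
    df["y"] = (
        effect * df["x"]
        + df["grp"].map(offsets)
        + rng.normal(size=n)
    )
    return df


class TestMixedModelGaussian:
    def test_zero_group_variance_matches_ols(self):
        """Data with exactly equal group means drive the random-intercept
        variance to its boundary; the LMM then degenerates to OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 300
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "g": rng.choice(["a", "b"], n),
                "grp": np.repeat([f"f{i}" for i in range(6)], n // 6),
            }
        )
        e = rng.normal(size=n)
        e -= pd.Series(e).groupby(df["grp"]).transform("mean").to_numpy()
        df["y"] = 0.4 * df["x"] + 0.2 * (df["g"] == "b") + e
        spec = ModelSpec(
            "y", "gaussian", ("x", "g"), ("grp",),
            interactions=False, factor_levels=GAUSS_LEVELS,
        )
        res = fit_mixed_model(spec, df)
        X = sm.add_constant(
            np.column_stack([(df["g"] == "b").astype(float), df["x"]])
        )
        ols = sm.OLS(df["y"], X).fit()
        fitted = res.terms.set_index("term")["estimate"]
        expected = np.asarray(ols.params)
        assert fitted["Intercept"] == pytest.approx(expected[0], abs=1e-6)
        assert fitted["g[T.b]"] == pytest.approx(expected[1], abs=1e-6)
        assert fitted["x"] == pytest.approx(expected[2], abs=1e-6)

    def test_interaction_pruning_reaches_main_effects_under_null(self):
        df = gaussian_data(400, seed=8, group_sd=0.3, effect=0.5)
        spec = ModelSpec(
            "y", "gaussian", ("x", "g"), ("grp",), factor_levels=GAUSS_LEVELS
        )
        res = fit_mixed_model(spec, df)
        # no true interaction: overwhelmingly pruned at this n
        assert res.final_terms == ["x", "g"] or "x:g" in res.final_terms
        assert "x" in res.final_terms and "g" in res.final_terms

    def test_rank_deficient_design_rejected_naming_terms(self):
        df = gaussian_data(100, seed=9)
        df["x2"] = df["x"]
        spec = ModelSpec(
            "y", "gaussian", ("x", "x2"), ("grp",), interactions=False
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_mixed_model(spec, df)

    def test_lr_chisq_agrees_with_wald_z_squared_asymptotically(self):
        df = gaussian_data(10_000, seed=10, group_sd=0.2, effect=0.05)
        spec = ModelSpec(
            "y", "gaussian", ("x", "g"), ("grp",),
            interactions=False, factor_levels=GAUSS_LEVELS,
        )
        res = fit_mixed_model(spec, df, lr_tests=["x"])
        z = float(res.terms.set_index("term").loc["x", "stat"])
        chisq = res.lr_tests["x"].chisq
        assert chisq == pytest.approx(z**2, rel=0.02)

    def test_lr_anova_null_p_uniform(self):
        rng = np.random.default_rng(11)
        spec = ModelSpec(
            "y", "gaussian", ("x", "g"), ("grp",),
            interactions=False, factor_levels=GAUSS_LEVELS,
        )
        ps = []
        for rep in range(150):
            df = gaussian_data(60, seed=int(rng.integers(2**31)), group_sd=0.3)
            res = fit_mixed_model(spec, df, lr_tests=["x"])
            p = res.lr_tests["x"].p
            if np.isfinite(p):
                ps.append(p)
        assert len(ps) >= 140  # boundary-variance fits are rare
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_lr_anova_table_shape(self):
        df = gaussian_data(200, seed=12, group_sd=0.2, effect=0.3)
        spec = ModelSpec(
            "y", "gaussian", ("x", "g"), ("grp",),
            interactions=False, factor_levels=GAUSS_LEVELS,
        )
        res = fit_mixed_model(spec, df)
        table = likelihood_ratio_anova(res, ["x", "g"])
        assert list(table["predictor"]) == ["x", "g"]
        assert (table["df"] == 1).all()
        assert table["p"].between(0, 1).all()

    def test_missing_random_effect_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("y", "gaussian", ("x",), ())

    def test_summary_renders(self):
        df = gaussian_data(120, seed=13, group_sd=0.2, effect=0.3)
        spec = ModelSpec(
            "y", "gaussian", ("x",), ("grp",), interactions=False
        )
        text = fit_mixed_model(spec, df).summary()
        assert "gaussian" in text and "x" in text


class TestMixedModelNegativeBinomial:
    def test_null_effect_estimates_cover_zero(self, null_nb_fits):
        """With no true relatedness effect the estimate lies within 3 SE of
        zero in at least 94% of replicates at the study design size."""
        ok = 0
        n = 0
        for res in null_nb_fits:
            if not res.converged:
                continue
            term = relatedness_term(res)
            n += 1
            ok += abs(term["estimate"]) <= 3 * term["se"]
        assert n >= 190  # convergence failures must stay rare
        assert ok / n >= 0.94

    def test_log_rate_ratio_recovered(self, recovery_nb_fits):
        ests = np.array(
            [
                relatedness_term(res)["estimate"]
                for res in recovery_nb_fits
                if res.converged
            ]
        )
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - np.log(0.5)) < 3 * se

    def test_dispersion_and_convergence_reported(self, null_nb_fits):
        res = null_nb_fits[0]
        assert res.dispersion is not None and res.dispersion > 0
        assert isinstance(res.converged, bool)
        assert res.nobs == 48


def three_level_data(n, seed, effects=(0.0, 0.6, 1.2)):
    rng = np.random.default_rng(seed)
    lv = rng.choice(["lo", "mid", "hi"], n)
    eff = dict(zip(["lo", "mid", "hi"], effects))
    df = pd.DataFrame(
        {
            "lvl": lv,
            "grp": rng.choice([f"f{i}" for i in range(6)], n),
        }
    )
    df["y"] = df["lvl"].map(eff) + rng.normal(size=n)
    return df


class TestTukey:
    LEVELS = ("lo", "mid", "hi")

    def _fit(self, seed=20, effects=(0.0, 0.6, 1.2)):
        df = three_level_data(240, seed, effects)
        spec = ModelSpec(
            "y", "gaussian", ("lvl",), ("grp",),
            interactions=False, factor_levels={"lvl": self.LEVELS},
        )
        return fit_mixed_model(spec, df)

    def test_three_level_factor_gives_three_contrasts(self):
        table = tukey_pairwise(self._fit(), "lvl", self.LEVELS)
        assert len(table) == 3
        assert set(table["contrast"]) == {
            "mid - lo", "hi - lo", "hi - mid",
        }

    def test_contrasts_antisymmetric_under_level_reversal(self):
        res = self._fit()
        fwd = tukey_pairwise(res, "lvl", self.LEVELS).set_index("contrast")
        rev = tukey_pairwise(res, "lvl", self.LEVELS[::-1]).set_index("contrast")
        assert rev.loc["lo - hi", "estimate"] == pytest.approx(
            -fwd.loc["hi - lo", "estimate"]
        )
        assert rev.loc["lo - hi", "p_tukey"] == pytest.approx(
            fwd.loc["hi - lo", "p_tukey"], rel=1e-6
        )

    def test_adjusted_p_not_smaller_than_unadjusted(self):
        table = tukey_pairwise(self._fit(), "lvl", self.LEVELS)
        assert (table["p_tukey"] >= table["p_unadj"] - 1e-12).all()

    def test_identical_levels_rarely_flagged(self):
        flagged = 0
        reps = 40
        for k in range(reps):
            res = self._fit(seed=100 + k, effects=(0.0, 0.0, 1.0))
            table = tukey_pairwise(res, "lvl", self.LEVELS).set_index("contrast")
            flagged += table.loc["mid - lo", "p_tukey"] < 0.05
        assert flagged / reps <= 0.15

    def test_two_level_factor_rejected(self):
        df = gaussian_data(100, seed=30, group_sd=0.2)
        spec = ModelSpec(
            "y", "gaussian", ("g",), ("grp",),
            interactions=False, factor_levels=GAUSS_LEVELS,
        )
        res = fit_mixed_model(spec, df)
        with pytest.raises(ValueError, match="3"):
            tukey_pairwise(res, "g", ("a", "b"))
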