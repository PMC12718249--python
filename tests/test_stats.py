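"""Moderation models, Johnson-Neyman probing, descriptives and the
random-pairing permutation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from dyadsync import stats, wtc
from dyadsync.simulate import coupled_band_signals
from dyadsync.stats import (ModerationModel, ModerationSpec,
                            correlation_table, johnson_neyman, mean_center,
                            permutation_check, permuted_coherence,
                            random_pairings)


def synthetic_table(rng, n=80, b_int=0.0, noise=0.3):
    pa = rng.normal(36.2, 6.8, n)
    na = rng.normal(19.5, 7.3, n)
    sync = rng.normal(-0.01, 0.05, n)
    gender = rng.integers(0, 2, n)
    income = rng.integers(1, 5, n)
    pac, sc = pa - pa.mean(), sync - sync.mean()
    y = (1.79 - 0.01 * pac + 0.02 * (na - na.mean()) - 2.0 * sc
         + b_int * pac * sc + rng.normal(0, noise, n))
    return pd.DataFrame(dict(pa=pa, na=na, rsa_sync=sync, gender=gender,
                             income=income, dysregulation=y))


class TestMeanCenter:
    def test_examples(self):
        np.testing.assert_allclose(mean_center([1, 2, 3]), [-1, 0, 1])
        np.testing.assert_allclose(mean_center(np.full(5, 7.0)), np.zeros(5))

    def test_output_mean_zero(self, rng):
        x = rng.normal(3, 2, 101)
        assert abs(mean_center(x).mean()) < 1e-12

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            mean_center([np.nan, np.nan])


class TestModerationFit:
    def test_noiseless_interpolation_exact(self, rng):
        n = 40
        iv = rng.normal(0, 1, n)
        mod = rng.normal(0, 1, n)
        ivc, modc = iv - iv.mean(), mod - mod.mean()
        y = 1 + 2 * ivc + 3 * modc + 4 * ivc * modc
        tab = pd.DataFrame(dict(pa=iv, rsa_sync=mod, dysregulation=y))
        res = ModerationModel(tab, ModerationSpec(covariates=())).fit()
        np.testing.assert_allclose(
            res.params.loc[["const", "pa", "rsa_sync", "pa_x_rsa_sync"], "B"],
            [1, 2, 3, 4], atol=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_df_layout_matches_six_predictor_design(self, rng):
        # 6 predictors (iv, moderator, interaction, 3 covariates): F(6, n-7)
        tab = synthetic_table(rng, n=71)
        res = ModerationModel.from_dataframe(tab).fit()
        assert res.f_df == (6, 64)
        assert res.n == 71

    def test_standardized_beta_bruteforce(self, rng):
        tab = synthetic_table(rng, b_int=-0.4)
        res = ModerationModel.from_dataframe(tab).fit()
        ivc = tab.pa - tab.pa.mean()
        modc = tab.rsa_sync - tab.rsa_sync.mean()
        inter = ivc * modc
        expect = (res.params.loc["pa_x_rsa_sync", "B"]
                  * inter.std(ddof=1) / tab.dysregulation.std(ddof=1))
        assert res.params.loc["pa_x_rsa_sync", "beta"] == pytest.approx(expect,
                                                                        abs=1e-10)

    def test_listwise_deletion(self, rng):
        tab = synthetic_table(rng, n=50)
        tab.loc[3, "pa"] = np.nan
        tab.loc[7, "rsa_sync"] = np.nan
        res = ModerationModel.from_dataframe(tab).fit()
        assert res.n == 48

    def test_singular_design_names_terms(self, rng):
        tab = synthetic_table(rng, n=30)
        tab["income"] = tab["gender"]  # perfectly collinear covariates
        with pytest.raises(ValueError, match="collinear"):
            ModerationModel.from_dataframe(tab).fit()

    def test_iv_cannot_be_covariate(self):
        with pytest.raises(ValueError):
            ModerationSpec(iv="pa", covariates=("pa", "gender"))


class TestJohnsonNeyman:
    @staticmethod
    def _grid_boundaries(res, lo=-50.0, hi=50.0, step=1e-4):
        m = np.arange(lo, hi, step)
        theta, se = res.simple_slope(m)
        t_crit = spstats.t.ppf(1 - res.spec.alpha / 2, res.f_df[1])
        sig = np.abs(theta) > t_crit * se
        flips = np.flatnonzero(np.diff(sig.astype(int)) != 0)
        return m[flips] + step / 2

    def test_boundaries_match_grid_scan(self, rng):
        tab = synthetic_table(rng, b_int=-0.4, noise=0.2)
        res = ModerationModel.from_dataframe(tab).fit()
        jn = res.johnson_neyman()
        grid = self._grid_boundaries(res, lo=-1.0, hi=1.0)
        inside = [b for b in jn.boundaries if -1 < b < 1]
        assert len(inside) == len(grid)
        for b, g in zip(sorted(inside), sorted(grid)):
            assert abs(b - g) < 1e-4

    def test_constructed_quadratic_case(self):
        # B_iv=1, B_int=-2, Var = I/100, alpha=.05, df=60: closed form vs grid
        params = pd.DataFrame({"B": [1.0, 0.0, -2.0]},
                              index=["iv", "mod", "iv_x_mod"])
        cov = pd.DataFrame(np.eye(3) / 100,
                           index=params.index, columns=params.index)
        res = stats.ModerationResults(
            spec=ModerationSpec(iv="iv", moderator="mod", covariates=()),
            params=params, r_squared=0.5, f_stat=10.0, f_df=(3, 60),
            f_pvalue=0.001, n=64, cov_params=cov,
            moderator_range=(-2.0, 2.0), moderator_mean=0.0)
        jn = johnson_neyman(res)
        grid = self._grid_boundaries(res, lo=-3, hi=3)
        assert len(jn.boundaries) == len(grid) == 2
        np.testing.assert_allclose(sorted(jn.boundaries), sorted(grid), atol=1e-4)

    def test_no_interaction_single_region(self):
        params = pd.DataFrame({"B": [0.5, 0.0, 0.0]},
                              index=["iv", "mod", "iv_x_mod"])
        cov = pd.DataFrame(np.diag([0.01, 0.01, 0.0]),
                           index=params.index, columns=params.index)
        res = stats.ModerationResults(
            spec=ModerationSpec(iv="iv", moderator="mod", covariates=()),
            params=params, r_squared=0.2, f_stat=5.0, f_df=(3, 60),
            f_pvalue=0.01, n=64, cov_params=cov,
            moderator_range=(-1.0, 1.0), moderator_mean=0.0)
        jn = johnson_neyman(res)
        assert jn.boundaries == []
        assert len(jn.regions) == 1 and jn.regions[0]["significant"]

    def test_two_sided_pattern_reachable(self, rng):
        # strong interaction: significant negative slope above one boundary,
        # significant positive slope below the other
        tab = synthetic_table(rng, b_int=-0.6, noise=0.15)
        res = ModerationModel.from_dataframe(tab).fit()
        jn = res.johnson_neyman()
        assert len(jn.boundaries) == 2
        signs = [(r["slope_sign"], r["significant"]) for r in jn.regions]
        assert signs[0] == ("+", True) and signs[-1] == ("-", True)
        assert not jn.regions[1]["significant"]

    def test_regions_partition_axis(self, rng):
        tab = synthetic_table(rng, b_int=-0.4)
        jn = ModerationModel.from_dataframe(tab).fit().johnson_neyman()
        edges = [jn.regions[0]["interval"][0]] + [r["interval"][1] for r in jn.regions]
        assert edges[0] == -np.inf and edges[-1] == np.inf
        assert all(a < b for a, b in zip(edges[:-1], edges[1:]))


class TestCorrelationTable:
    def test_self_and_anticorrelation(self, rng):
        x = rng.normal(0, 1, 50)
        tab = pd.DataFrame(dict(x=x, y=-x, z=rng.normal(0, 1, 50)))
        desc, mat = correlation_table(tab)
        assert mat.loc["x", "x"] == "1"
        assert mat.loc["y", "x"].startswith("-1.00")
        r, p = spstats.pearsonr(tab.x, tab.z)
        stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        assert mat.loc["z", "x"] == f"{r:.2f}{stars}"

    def test_zero_variance_blank(self, rng):
        tab = pd.DataFrame(dict(x=rng.normal(0, 1, 20), c=np.ones(20)))
        _, mat = correlation_table(tab)
        assert mat.loc["c", "x"] == ""

    def test_descriptives(self, rng):
        tab = pd.DataFrame(dict(x=rng.normal(5, 2, 500)))
        desc, _ = correlation_table(tab)
        assert desc.loc["x", "mean"] == pytest.approx(5.0, abs=0.3)
        assert desc.loc["x", "sd"] == pytest.approx(2.0, abs=0.2)


class TestRandomPairings:
    def test_three_dyads_only_two_derangements(self):
        scheme = random_pairings(["a", "b", "c"], n_permutations=50, seed=0)
        allowed = {(1, 2, 0), (2, 0, 1)}
        seen = {tuple(p) for p in scheme.permutations}
        assert seen == allowed

    def test_no_fixed_points_ever(self):
        scheme = random_pairings(list(range(12)), n_permutations=100, seed=1)
        assert scheme.n_permutations == 100
        for p in scheme.permutations:
            assert not np.any(p == np.arange(12))

    def test_uniform_over_derangements(self):
        # n=4 has 9 derangements; chi-square over 900 draws should not reject
        scheme = random_pairings(list(range(4)), n_permutations=900, seed=2)
        _, counts = np.unique(scheme.permutations, axis=0, return_counts=True)
        assert len(counts) == 9
        chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
        assert chi2 < spstats.chi2.ppf(0.999, df=8)

    def test_too_few_dyads_rejected(self):
        with pytest.raises(ValueError):
            random_pairings(["a", "b"], 10, 0)

    def test_seeded_reproducible(self):
        a = random_pairings(list(range(8)), 20, seed=5).permutations
        b = random_pairings(list(range(8)), 20, seed=5).permutations
        np.testing.assert_array_equal(a, b)


class TestPermutedCoherence:
    def test_identical_signals_pseudo_equals_one(self, rng):
        sig = rng.normal(0, 1, 300)
        ids = list(range(4))
        mothers = {i: sig for i in ids}
        children = {i: sig for i in ids}
        scheme = random_pairings(ids, 6, seed=0)
        pseudo = permuted_coherence(mothers, children, scheme)
        np.testing.assert_allclose(pseudo.to_numpy(), 1.0, atol=1e-6)

    def test_coupled_cohort_true_exceeds_pseudo(self):
        ids = list(range(5))
        mothers, children = {}, {}
        for i in ids:
            rng_i = np.random.default_rng(100 + i)
            mothers[i], children[i] = coupled_band_signals(0.8, 300, rng_i)
        true_vals = [wtc.dyad_coherence(mothers[i], children[i]).coherence
                     for i in ids]
        scheme = random_pairings(ids, 10, seed=3)
        pseudo = permuted_coherence(mothers, children, scheme)
        assert np.mean(true_vals) > pseudo.mean()

    def test_unequal_lengths_truncated(self, rng):
        ids = [0, 1, 2]
        mothers = {i: rng.normal(0, 1, 300) for i in ids}
        children = {i: rng.normal(0, 1, 290 + i) for i in ids}
        scheme = random_pairings(ids, 4, seed=0)
        pseudo = permuted_coherence(mothers, children, scheme)
        assert pseudo.notna().all()

    def test_deterministic_under_seed(self, rng):
        ids = [0, 1, 2, 3]
        mothers = {i: rng.normal(0, 1, 128) for i in ids}
        children = {i: rng.normal(0, 1, 128) for i in ids}
        a = permuted_coherence(mothers, children, random_pairings(ids, 5, 7))
        b = permuted_coherence(mothers, children, random_pairings(ids, 5, 7))
        pd.testing.assert_series_equal(a, b)


def test_benjamini_hochberg_stepup(rng):
    np.testing.assert_allclose(stats.benjamini_hochberg([0.01, 0.04, 0.03, 0.005]),
                               [0.02, 0.04, 0.04, 0.02])
    p = rng.uniform(0, 1, 25)
    adj = stats.benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
    # monotone: ordering of adjusted p respects ordering of raw p
    assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)


def test_permutation_check_refits_with_pseudo_moderator(rng):
    tab = synthetic_table(rng, n=40)
    tab["dyad_id"] = [f"d{i}" for i in range(40)]
    pseudo = pd.Series(rng.uniform(0.2, 0.5, 40), index=tab["dyad_id"])
    res = permutation_check(tab, pseudo, iv="pa")
    assert res.spec.moderator == "pseudo_coherence"
    assert res.n == 40
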