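"""Correlation matrices, comparison models, ELPD and Moran's I."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenometrics import (compare_models_elpd, fit_cross_trophic_model,
                          fit_herbivory_model, morans_i, spearman_matrix,
                          variance_explained_delta)
from phenometrics.compare import LinearComparisonModel, _beta_reg_fit


class TestSpearman:
    def test_monotone_pairs(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 4, 9, 16, 25],
                           "c": [5, 4, 3, 2, 1]})
        out = spearman_matrix(df, ["a", "b", "c"]).set_index(["metric_a", "metric_b"])
        assert out.loc[("a", "b"), "rho"] == pytest.approx(1.0)
        assert out.loc[("a", "c"), "rho"] == pytest.approx(-1.0)

    def test_tied_fixture_matches_rank_then_pearson_oracle(self):
        a = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        b = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0])
        out = spearman_matrix(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        oracle = np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1]
        assert out.loc[0, "rho"] == pytest.approx(oracle, abs=1e-12)

    def test_pairwise_complete_n(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5, np.nan],
                           "b": [1, 2, 3, 4, np.nan, 6]})
        out = spearman_matrix(df, ["a", "b"])
        assert out.loc[0, "n"] == 4

    def test_exact_permutation_p_at_small_n(self):
        # perfectly monotone n=5: exact two-sided p = 2/5! = 1/60
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [1, 3, 4, 7, 9]})
        out = spearman_matrix(df, ["a", "b"])
        assert out.loc[0, "p"] == pytest.approx(2 / 120, abs=1e-12)

    def test_all_tied_column_undefined(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 2, 2, 2, 2]})
        out = spearman_matrix(df, ["a", "b"])
        assert np.isnan(out.loc[0, "rho"])


class TestCrossTrophic:
    def make_table(self, n=40, b=0.2, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        half = 112 + 5 * rng.standard_normal(n)
        area = np.array(["Great Wood", "ForestGEO", "Marley"])[np.arange(n) % 3]
        off = {"Great Wood": 0.0, "ForestGEO": 2.3, "Marley": -1.2}
        y = 127.6 + b * half + np.array([off[a] for a in area])
        y = y + sd * rng.standard_normal(n)
        return pd.DataFrame({"budburst": half, "tc_peak": y, "area": area,
                             "x": rng.uniform(0, 900, n),
                             "y": rng.uniform(0, 900, n)})

    def test_zero_noise_exact_recovery(self):
        df = self.make_table(sd=0.0)
        res = fit_cross_trophic_model(df, "tc_peak", "budburst",
                                      area_reference="Great Wood",
                                      n_boot=50, random_state=1)
        coef = res.coef.set_index("term")["estimate"]
        assert coef["Intercept"] == pytest.approx(127.6, abs=1e-8)
        assert coef["budburst"] == pytest.approx(0.2, abs=1e-8)
        assert coef["area[ForestGEO]"] == pytest.approx(2.3, abs=1e-8)
        assert res.variance_explained > 1 - 1e-9

    def test_slope_interval_covers_truth(self):
        df = self.make_table(sd=2.0, seed=3)
        res = fit_cross_trophic_model(df, "tc_peak", "budburst",
                                      random_state=2)
        row = res.coef.set_index("term").loc["budburst"]
        assert row["ci_low"] <= 0.2 <= row["ci_high"]

    def test_permuted_predictor_interval_covers_zero(self):
        rng = np.random.default_rng(4)
        df = self.make_table(sd=2.0, seed=5)
        df["budburst"] = rng.permutation(df["budburst"].to_numpy())
        res = fit_cross_trophic_model(df, "tc_peak", "budburst", random_state=6)
        row = res.coef.set_index("term").loc["budburst"]
        assert row["ci_low"] <= 0.0 <= row["ci_high"]

    def test_single_area_dropped_with_warning(self):
        df = self.make_table(sd=1.0)
        df["area"] = "Great Wood"
        with pytest.warns(UserWarning, match="area term dropped"):
            res = fit_cross_trophic_model(df, "tc_peak", "budburst",
                                          n_boot=50, random_state=1)
        assert "area[Marley]" not in set(res.coef["term"])

    def test_too_few_rows_rejected(self):
        df = self.make_table(n=8)
        with pytest.raises(ValueError, match="at least 10"):
            fit_cross_trophic_model(df, "tc_peak", "budburst")


class TestVarianceExplained:
    def test_saturating_factor(self):
        # response exactly determined by factor level means: the delta is
        # the full remaining headroom 1 - R2(reduced)
        rng = np.random.default_rng(1)
        lev = np.repeat(["u", "v", "w"], 20)
        y = pd.Series(lev).map({"u": 1.0, "v": 5.0, "w": 9.0}).to_numpy()
        base = rng.normal(size=60)
        df = pd.DataFrame({"resp": y, "f": lev, "base": base})
        d = variance_explained_delta(df, "resp", ["base"], "f")
        X = np.column_stack([np.ones(60), base])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        r2_reduced = fitted.var() / (fitted.var() + (y - fitted).var())
        assert d == pytest.approx(1.0 - r2_reduced, abs=1e-9)

    def test_noise_factor_adds_little(self):
        rng = np.random.default_rng(2)
        deltas = []
        for rep in range(5):
            df = pd.DataFrame({
                "resp": rng.normal(size=100),
                "base": rng.normal(size=100),
                "noise_label": rng.choice(list("abcd"), size=100),
            })
            deltas.append(variance_explained_delta(df, "resp", ["base"], "noise_label"))
        assert np.median(deltas) < 0.05
        assert min(deltas) > -0.02  # nested fits: no real decrease possible

    def test_constructed_variance_share_recovered(self):
        rng = np.random.default_rng(3)
        n = 300
        lev = rng.choice(list("abcdef"), size=n)
        effects = dict(zip("abcdef", [-2.1, -1.2, -0.4, 0.4, 1.2, 2.1]))
        sig = np.array([effects[l] for l in lev])  # var ~ 1.96
        noise = rng.normal(scale=np.sqrt(sig.var() * 3 / 7), size=n)  # 70% share
        df = pd.DataFrame({"resp": sig + noise, "species": lev,
                           "const_base": np.ones(n)})
        d = variance_explained_delta(df, "resp", [], "species")
        assert d == pytest.approx(0.7, abs=0.1)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"resp": [1.0, 2.0, 3.0], "f": ["a", "a", "a"]})
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            variance_explained_delta(df, "resp", [], "f")


class TestHerbivoryModel:
    def make_table(self, n=72, slope=-0.07, seed=0):
        rng = np.random.default_rng(seed)
        half = 122 + 5 * rng.standard_normal(n)
        area = np.array(["Great Wood", "ForestGEO", "Marley"])[np.arange(n) % 3]
        canopy = rng.choice(["lower", "middle", "upper"], size=n)
        ce = {"lower": 0.2, "middle": 0.0, "upper": -0.2}
        logit = 5.85 + slope * half + np.array([ce[c] for c in canopy])
        mu = 1 / (1 + np.exp(-logit))
        herb = rng.beta(mu * 25, (1 - mu) * 25)
        return pd.DataFrame({"herbivory": herb, "half_leaf": half, "area": area,
                             "canopy_level": canopy})

    def test_negative_slope_recovered(self):
        res = fit_herbivory_model(self.make_table(seed=1), "half_leaf",
                                  area_reference="Great Wood", random_state=1)
        row = res.coef.set_index("term").loc["half_leaf"]
        assert row["ci_low"] <= -0.07 <= row["ci_high"]
        assert row["estimate"] < 0

    def test_matches_statsmodels_beta_regression(self):
        from statsmodels.othermod.betareg import BetaModel

        df = self.make_table(seed=2)
        X = np.column_stack([np.ones(len(df)), df["half_leaf"]])
        coefs, _ = _beta_reg_fit(X, df["herbivory"].to_numpy())
        sm_fit = BetaModel(df["herbivory"].to_numpy(), X).fit(disp=0)
        assert np.allclose(coefs, sm_fit.params[:2], atol=1e-4)

    def test_all_equal_herbivory_rejected(self):
        df = self.make_table()
        df["herbivory"] = 0.2
        with pytest.raises(ValueError, match="all equal"):
            fit_herbivory_model(df, "half_leaf")

    def test_boundary_squeeze_applied(self):
        df = self.make_table(seed=3)
        df.loc[df.index[0], "herbivory"] = 0.0
        res = fit_herbivory_model(df, "half_leaf", n_boot=50, random_state=2)
        assert any("squeeze" in n for n in res.notes)


class TestElpd:
    def test_duplicate_models_tie_at_zero(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"resp": rng.normal(size=30),
                           "pred": rng.normal(size=30)})
        r1 = fit_cross_trophic_model(df, "resp", "pred", area_col=None,
                                     n_boot=50, random_state=1)
        r2 = fit_cross_trophic_model(df, "resp", "pred", area_col=None,
                                     n_boot=50, random_state=2)
        tab = compare_models_elpd([r1, r2])
        assert np.allclose(tab["delta_elpd"], 0.0)

    def test_true_predictor_beats_intercept_only(self):
        rng = np.random.default_rng(7)
        wins = 0
        for rep in range(10):
            x = rng.normal(size=60)
            y = 2.0 * x + rng.normal(size=60)
            df = pd.DataFrame({"resp": y, "pred": x})
            rt = fit_cross_trophic_model(df, "resp", "pred", area_col=None,
                                         n_boot=20, random_state=rep)
            r0 = fit_cross_trophic_model(df, "resp", None, area_col=None,
                                         n_boot=20, random_state=rep)
            compare_models_elpd([rt, r0])
            wins += rt.delta_elpd == 0.0
        assert wins >= 9

    def test_mismatched_rows_rejected(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"resp": rng.normal(size=30), "pred": rng.normal(size=30)})
        r1 = fit_cross_trophic_model(df, "resp", "pred", area_col=None,
                                     n_boot=20, random_state=1)
        r2 = fit_cross_trophic_model(df.iloc[:20], "resp", "pred", area_col=None,
                                     n_boot=20, random_state=1)
        with pytest.raises(ValueError, match="identical rows"):
            compare_models_elpd([r1, r2])


class TestMoransI:
    def brute_force(self, z, W):
        n = len(z)
        zc = z - z.mean()
        num = sum(W[i, j] * zc[i] * zc[j] for i in range(n) for j in range(n))
        return (n / W.sum()) * num / np.sum(zc**2)

    def test_matches_double_sum_formula(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 100, size=(12, 2))
        z = rng.normal(size=12)
        I, expected, p = morans_i(z, coords, k=4, permutations=99, random_state=1)
        from scipy.spatial import cKDTree

        tree = cKDTree(coords)
        _, idx = tree.query(coords, k=5)
        W = np.zeros((12, 12))
        for i in range(12):
            for j in idx[i, 1:]:
                W[i, j] = 1.0
        W /= W.sum(axis=1, keepdims=True)
        assert I == pytest.approx(self.brute_force(z, W), abs=1e-12)
        assert expected == pytest.approx(-1 / 11, abs=1e-12)

    def test_iid_residuals_center_on_null_expectation(self):
        rng = np.random.default_rng(10)
        coords = rng.uniform(0, 1000, size=(50, 2))
        Is = [morans_i(rng.normal(size=50), coords, random_state=i,
                       permutations=49)[0] for i in range(30)]
        assert np.mean(Is) == pytest.approx(-1 / 49, abs=0.03)

    def test_area_clustering_detected(self):
        rng = np.random.default_rng(11)
        centers = np.array([[0, 0], [800, 0], [400, 700]])
        coords = np.vstack([c + rng.uniform(-60, 60, size=(15, 2)) for c in centers])
        z = np.repeat([2.0, 0.0, -2.0], 15) + 0.1 * rng.normal(size=45)
        I, _, p = morans_i(z, coords, random_state=2)
        assert I > 0.5
        assert p <= 0.05

    def test_duplicate_coordinates_collapsed(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 100, size=(15, 2))
        coords[1] = coords[0]
        with pytest.warns(UserWarning, match="duplicate coordinates"):
            morans_i(rng.normal(size=15), coords, permutations=49, random_state=3)
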