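"""Tests for the driver-inference statistics.

Cross-checks against independent oracles: dense eigendecomposition for PC1
variance, the textbook closed form and pingouin for partial correlation,
scikit-bio for the Mantel statistic, and the normal equations for OLS.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from soilcue.stats import (
    FactorGroups,
    cue_driver_screen,
    distance_matrix,
    group_compare,
    group_pc1,
    importance_screen,
    linear_fit_r2,
    mantel_test,
    partial_correlation,
)

rng0 = np.random.default_rng(42)


class TestGroupPc1:
    def test_two_perfectly_correlated_variables(self):
        x = rng0.normal(size=12)
        scores, ve = group_pc1(np.column_stack([x, 2 * x + 3]))
        assert ve == pytest.approx(100.0, abs=1e-9)

    def test_single_variable_is_standardized(self):
        x = rng0.normal(size=10)
        scores, ve = group_pc1(x[:, None])
        np.testing.assert_allclose(scores, (x - x.mean()) / x.std(ddof=1))
        assert ve == 100.0

    def test_variance_matches_eigendecomposition(self):
        X = rng0.normal(size=(15, 6))
        _, ve = group_pc1(X)
        eigvals = np.linalg.eigvalsh(np.corrcoef(X.T))
        assert ve == pytest.approx(100 * eigvals.max() / eigvals.sum(), abs=1e-10)

    def test_sign_convention_and_reorder_invariance(self):
        X = rng0.normal(size=(20, 4))
        X[:, 2] = X[:, 0] + 0.1 * rng0.normal(size=20)  # dominant pair
        scores, ve = group_pc1(X)
        perm = [3, 1, 0, 2]
        scores_p, ve_p = group_pc1(X[:, perm])
        assert ve_p == pytest.approx(ve, abs=1e-10)
        np.testing.assert_allclose(scores_p, scores, atol=1e-10)
        # positively correlated with the largest-loading variable
        anchors = np.array([np.corrcoef(scores, X[:, j])[0, 1] for j in range(4)])
        assert anchors[np.argmax(np.abs(anchors))] > 0

    def test_zero_variance_dropped_then_error(self):
        X = np.column_stack([rng0.normal(size=10), np.ones(10)])
        with pytest.warns(UserWarning, match="zero-variance"):
            _, ve = group_pc1(X)
        assert ve == 100.0
        with pytest.raises(ValueError, match="zero variance"):
            group_pc1(np.ones((10, 2)))


class TestPartialCorrelation:
    def test_no_controls_equals_pearson(self):
        x, y = rng0.normal(size=(2, 30))
        res = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_single_control_closed_form(self):
        x, y, z = rng0.normal(size=(3, 25))
        y = y + 0.5 * z
        x = x + 0.3 * z
        res = partial_correlation(x, y, z[:, None])
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        closed = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert res.r == pytest.approx(closed, abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        x, y, z1, z2 = rng0.normal(size=(4, 40))
        y = y + 0.4 * x + 0.6 * z1
        df = pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        res = partial_correlation(x, y, np.column_stack([z1, z2]))
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)

    def test_orthogonal_controls_keep_zero_order_r(self):
        x, y = rng0.normal(size=(2, 30))
        raw = rng0.normal(size=30)
        design = np.column_stack([np.ones(30), x, y])
        z = raw - design @ np.linalg.lstsq(design, raw, rcond=None)[0]
        res = partial_correlation(x, y, z[:, None])
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_control_absorbs_shared_signal(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=200)
        y = z + rng.normal(size=200)
        x = rng.normal(size=200)
        res = partial_correlation(x, y, z[:, None])
        assert abs(res.r) < 0.2

    def test_degenerate_control_errors(self):
        x, y = rng0.normal(size=(2, 20))
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, y, x[:, None])

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="n > k"):
            partial_correlation([1.0, 2, 3], [2.0, 1, 3], np.ones((3, 1)))


class TestDriverScreen:
    @staticmethod
    def make_groups(rng, cue):
        n = cue.size
        def block(signal, p=3):
            return pd.DataFrame(
                signal[:, None] + 0.3 * rng.normal(size=(n, p)),
                index=[f"s{i}" for i in range(n)],
            )
        return FactorGroups(
            {
                "ASG": block(cue),
                "SSG": block(-cue),
                "CS": block(rng.normal(size=n)),
            }
        )

    def test_generator_truth_recovered(self):
        rng = np.random.default_rng(11)
        cue = rng.normal(size=20)
        screen = cue_driver_screen(cue, self.make_groups(rng, cue))
        zero = {
            r.factor_group: r
            for r in screen
            if r.control_group == "zero-order"
        }
        assert zero["ASG"].r > 0 and zero["ASG"].p < 0.05
        assert zero["SSG"].r < 0 and zero["SSG"].p < 0.05

    def test_identical_groups_collapse_controlled_r(self):
        rng = np.random.default_rng(3)
        cue = rng.normal(size=18)
        base = cue[:, None] + 0.3 * rng.normal(size=(18, 3))
        idx = [f"s{i}" for i in range(18)]
        near = base + 1e-3 * rng.normal(size=base.shape)
        groups = FactorGroups(
            {"ASG": pd.DataFrame(base, index=idx), "SSG": pd.DataFrame(near, index=idx)}
        )
        screen = cue_driver_screen(cue, groups)
        ctl = next(
            r for r in screen if r.factor_group == "ASG" and r.control_group == "SSG"
        )
        zero = next(
            r for r in screen
            if r.factor_group == "ASG" and r.control_group == "zero-order"
        )
        assert abs(ctl.r) < 0.5 * abs(zero.r)

    def test_exactly_identical_groups_error(self):
        rng = np.random.default_rng(3)
        cue = rng.normal(size=18)
        base = pd.DataFrame(
            cue[:, None] + 0.3 * rng.normal(size=(18, 3)),
            index=[f"s{i}" for i in range(18)],
        )
        with pytest.raises(ValueError, match="collinear"):
            cue_driver_screen(cue, FactorGroups({"ASG": base, "SSG": base.copy()}))

    def test_all_controls_mode(self):
        rng = np.random.default_rng(5)
        cue = rng.normal(size=20)
        screen = cue_driver_screen(
            cue, self.make_groups(rng, cue), all_controls=True
        )
        combos = {r.control_group for r in screen if r.factor_group == "CS"}
        assert any("+" in c for c in combos)


class TestMantel:
    @staticmethod
    def random_distances(rng, n=8, p=3):
        return distance_matrix(rng.normal(size=(n, p)), standardize=False)

    def test_identity(self):
        d = self.random_distances(np.random.default_rng(1))
        r, p = mantel_test(d, d, permutations=199, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(1 / 200)

    def test_affine_invariance(self):
        d = self.random_distances(np.random.default_rng(2))
        off = 1 - np.eye(d.shape[0])
        r, _ = mantel_test(d, 3.0 * d + 0.7 * off, permutations=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_matches_skbio_statistic(self):
        skbio_mantel = pytest.importorskip("skbio.stats.distance").mantel
        rng = np.random.default_rng(4)
        d1 = self.random_distances(rng)
        d2 = self.random_distances(rng)
        r, _ = mantel_test(d1, d2, permutations=99, seed=0)
        r_ref, _, _ = skbio_mantel(d1, d2, permutations=0, alternative="greater")
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        d1, d2 = self.random_distances(rng), self.random_distances(rng)
        out1 = mantel_test(d1, d2, permutations=199, seed=9)
        out2 = mantel_test(d1, d2, permutations=199, seed=9)
        assert out1 == out2

    def test_relabeling_invariance_of_statistic(self):
        rng = np.random.default_rng(6)
        d1 = self.random_distances(rng)
        d2 = d1 + 0.1 * self.random_distances(rng)
        perm = rng.permutation(d1.shape[0])
        r, p = mantel_test(d1, d2, permutations=199, seed=0)
        r2, p2 = mantel_test(
            d1[np.ix_(perm, perm)], d2[np.ix_(perm, perm)], permutations=199, seed=0
        )
        assert r2 == pytest.approx(r, abs=1e-12)
        assert p == p2 == pytest.approx(1 / 200)  # strong signal: both minimal

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda d: d + np.triu(np.ones_like(d), 1) * 0.1,  # asymmetric
            lambda d: np.where(np.eye(len(d)) == 1, np.nan, d),  # NaN
        ],
    )
    def test_bad_matrix_rejected(self, mutate):
        d = self.random_distances(np.random.default_rng(7))
        with pytest.raises(ValueError):
            mantel_test(d, mutate(d.copy()), permutations=99, seed=0)


class TestImportanceScreen:
    def test_single_informative_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 5)),
                         columns=[f"g{i}" for i in range(5)])
        y = 3.0 * X["g0"].to_numpy()
        out = importance_screen(X, y, trees=200, seed=1)
        assert out.iloc[0]["feature"] == "g0"
        assert out.iloc[0]["pct_mse_increase"] > out.iloc[1]["pct_mse_increase"]

    def test_noise_features_stay_in_null_band(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 6)))
        y = rng.normal(size=30)
        observed = importance_screen(X, y, trees=200, seed=2)
        null_max = max(
            importance_screen(X, rng.permutation(y), trees=200, seed=3 + k)[
                "pct_mse_increase"
            ].max()
            for k in range(5)
        )
        assert observed["pct_mse_increase"].max() <= null_max * 2 + 5.0

    def test_reproducible_and_top_k(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(20, 4)))
        y = X[0].to_numpy() + 0.1 * rng.normal(size=20)
        a = importance_screen(X, y, trees=100, seed=5)
        b = importance_screen(X, y, trees=100, seed=5, top_k=2)
        pd.testing.assert_frame_equal(a.head(2), b)

    def test_constant_response_errors(self):
        X = pd.DataFrame(np.random.default_rng(3).normal(size=(12, 3)))
        with pytest.raises(ValueError, match="constant"):
            importance_screen(X, np.ones(12), trees=50, seed=0)


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r2, p = linear_fit_r2(x, 2 * x + 1)
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert intercept == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations(self):
        x = np.array([0.3, 1.7, 2.2, 4.8, 5.1])
        y = np.array([1.1, 0.4, 2.9, 3.3, 5.0])
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        slope, intercept, r2, _ = linear_fit_r2(x, y)
        assert intercept == pytest.approx(beta[0], abs=1e-12)
        assert slope == pytest.approx(beta[1], abs=1e-12)
        resid = y - X @ beta
        tss = ((y - y.mean()) ** 2).sum()
        assert r2 == pytest.approx(1 - resid @ resid / tss, abs=1e-12)

    def test_independent_data_low_r2(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 1000))
        assert linear_fit_r2(x, y)[2] < 0.01

    def test_constant_x_errors(self):
        with pytest.raises(ValueError, match="constant"):
            linear_fit_r2(np.ones(5), np.arange(5.0))


class TestGroupCompare:
    def test_identical_multisets_share_letter(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["a"] * 3 + ["b"] * 3
        F, p, letters = group_compare(values, labels)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert letters["a"] == letters["b"]

    def test_separated_groups_get_distinct_letters(self):
        values = [0.0, 0.0, 0.1, 10.0, 10.0, 10.1]
        labels = ["lo"] * 3 + ["hi"] * 3
        F, p, letters = group_compare(values, labels)
        assert p < 0.001
        assert set(letters["lo"]).isdisjoint(letters["hi"])

    def test_intermediate_group_shares_both_letters(self):
        rng = np.random.default_rng(8)
        values = np.concatenate(
            [rng.normal(0, 1, 8), rng.normal(1.2, 1, 8), rng.normal(2.4, 1, 8)]
        )
        labels = ["g1"] * 8 + ["g2"] * 8 + ["g3"] * 8
        _, _, letters = group_compare(values, labels)
        # every group gets at least one letter; extremes differ
        assert all(letters.values())
        assert set(letters["g1"]).isdisjoint(letters["g3"])

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="< 2"):
            group_compare([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_matches_scipy_anova(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=15)
        labels = ["x"] * 5 + ["y"] * 5 + ["z"] * 5
        F, p, _ = group_compare(values, labels)
        F_ref, p_ref = sps.f_oneway(values[:5], values[5:10], values[10:])
        assert F == pytest.approx(F_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)
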