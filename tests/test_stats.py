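"""Marker-comparison statistics: staging tests, ROC/DeLong, partial
Spearman, the reflect-sqrt transform and the regression models, validated
against exact identities, permutation/enumeration oracles and simulation
calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from fillstates import stats as st


# ---------------------------------------------------------------------------
# Kruskal-Wallis / Mann-Whitney

class TestStagingTests:
    def test_identical_groups_h_zero(self):
        h, p = st.kruskal_wallis([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_rank_formula(self):
        # groups {1,2} vs {10,11}: ranks {1,2} vs {3,4}, no ties.
        # H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1)
        #   = 12/20 * (3^2/2 + 7^2/2) - 15 = 0.6*29 - 15 = 2.4
        h, _ = st.kruskal_wallis([1, 2, 10, 11], ["a", "a", "b", "b"])
        assert h == pytest.approx(2.4, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(st.DegenerateDesignError):
            st.kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_two_group_kw_agrees_with_mann_whitney(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=25)
        b = rng.normal(0.4, size=25)
        _, p_kw = st.kruskal_wallis(np.r_[a, b], ["a"] * 25 + ["b"] * 25)
        _, p_mw = st.mann_whitney(a, b)
        assert abs(p_kw - p_mw) < 0.01

    def test_mw_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        _, p = st.mann_whitney(a, a.copy())
        assert p > 0.9

    def test_mw_complete_separation(self):
        u, _ = st.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_mw_empty_rejected(self):
        with pytest.raises(ValueError):
            st.mann_whitney([], [1.0])

    def test_mw_asymptotic_close_to_exact_enumeration(self):
        """Normal approximation within 0.02 of full enumeration at n=8/8."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(0.5, size=8)
            p_exact = sps.mannwhitneyu(a, b, method="exact").pvalue
            p_approx = sps.mannwhitneyu(
                a, b, method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(p_exact - p_approx) < 0.02
            # package routine picks exact enumeration in this regime
            _, p_pkg = st.mann_whitney(a, b)
            assert p_pkg == pytest.approx(p_exact)

    def test_kw_null_calibration(self):
        rejections = 0
        n_reps = 2000
        for i in range(n_reps):
            rng = np.random.default_rng(20000 + i)
            vals = rng.normal(size=45)
            _, p = st.kruskal_wallis(vals, np.repeat(["a", "b", "c"], 15))
            rejections += p < 0.05
        assert 0.035 <= rejections / n_reps <= 0.065

    def test_mw_null_calibration(self):
        rejections = 0
        n_reps = 2000
        for i in range(n_reps):
            rng = np.random.default_rng(50000 + i)
            _, p = st.mann_whitney(rng.normal(size=20), rng.normal(size=20))
            rejections += p < 0.05
        assert 0.035 <= rejections / n_reps <= 0.065


# ---------------------------------------------------------------------------
# ROC / DeLong

class TestROC:
    def test_perfect_separation(self):
        assert st.roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_chance_level(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        assert abs(st.roc_auc(scores, labels) - 0.5) < 0.03

    def test_direction_flip(self):
        assert st.roc_auc([3, 2, 1], [1, 1, 0], positive_direction="less") == 0.0
        assert st.roc_auc([3, 2, 1], [1, 1, 0], positive_direction="greater") == 1.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            st.roc_auc([1, 2], [1, 1])

    @given(hst.lists(hst.integers(0, 5), min_size=4, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_auc_u_identity_with_ties(self, vals):
        """AUC == U/(n_pos*n_neg) exactly, ties counted half, on any input."""
        rng = np.random.default_rng(len(vals))
        labels = np.zeros(len(vals), bool)
        labels[: len(vals) // 2 + 1] = True
        rng.shuffle(labels)
        if labels.all() or not labels.any():
            return
        scores = np.asarray(vals, float)
        auc = st.roc_auc(scores, labels)
        # independent U: count pairwise wins + half-ties
        pos, neg = scores[labels], scores[~labels]
        u = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert auc == pytest.approx(u / (pos.size * neg.size), abs=1e-12)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.normal(size=200) + np.repeat([0, 1], 100)
        labels = np.repeat([0, 1], 100).astype(bool)
        assert st.roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestDeLong:
    def test_identical_scores_degenerate(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=40)
        lab = np.repeat([True, False], 20)
        cmp_ = st.delong_test(s, s.copy(), lab)
        assert cmp_.degenerate
        assert cmp_.auc_a == cmp_.auc_b
        assert cmp_.p_value == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=60)
        lab = rng.random(60) < 0.5
        lab[:2] = [True, False]
        cmp_ = st.delong_test(s, np.exp(2 * s) + 5, lab)
        assert cmp_.auc_a == pytest.approx(cmp_.auc_b, abs=1e-12)
        assert cmp_.degenerate  # identical rankings -> zero-variance difference

    def test_variance_nonnegative_and_p_in_range(self):
        rng = np.random.default_rng(4)
        for i in range(20):
            n = int(rng.integers(6, 40))
            lab = np.zeros(2 * n, bool)
            lab[:n] = True
            a = rng.normal(size=2 * n) + lab * rng.uniform(0, 1)
            b = 0.5 * a + rng.normal(size=2 * n)
            cmp_ = st.delong_test(a, b, lab)
            assert 0.0 <= cmp_.p_value <= 1.0
            assert np.isfinite(cmp_.delong_z) or cmp_.degenerate

    def test_against_paired_permutation(self):
        """DeLong p within 0.03 of a 10,000-rep paired marker-swap permutation."""
        rng = np.random.default_rng(42)
        n = 40
        lab = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        latent = rng.normal(size=2 * n) + lab * 0.8
        a = latent + rng.normal(size=2 * n) * 0.8
        b = latent + rng.normal(size=2 * n) * 0.9 + lab * 0.3
        cmp_ = st.delong_test(a, b, lab)

        obs = st.roc_auc(a, lab) - st.roc_auc(b, lab)
        prng = np.random.default_rng(7)
        count = 0
        n_reps = 10_000
        for _ in range(n_reps):
            swap = prng.random(2 * n) < 0.5
            aa = np.where(swap, b, a)
            bb = np.where(swap, a, b)
            if abs(st.roc_auc(aa, lab) - st.roc_auc(bb, lab)) >= abs(obs) - 1e-12:
                count += 1
        assert abs(cmp_.p_value - count / n_reps) < 0.03


# ---------------------------------------------------------------------------
# partial Spearman and the reflect-sqrt transform

class TestPartialSpearman:
    def test_reduces_to_plain_spearman(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40) + 0.5 * x
        pc = st.partial_spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert pc.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert pc.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_monotone_function_gives_one(self, rng):
        x = rng.normal(size=30)
        assert st.partial_spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_matrix_identity_oracle(self, rng):
        """rho equals the negated scaled off-diagonal of the inverse rank
        correlation matrix."""
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        cov = rng.normal(size=(60, 3))
        cov[:, 0] += 0.3 * x
        pc = st.partial_spearman(x, y, cov)
        ranks = np.column_stack(
            [sps.rankdata(v) for v in [x, y, cov[:, 0], cov[:, 1], cov[:, 2]]]
        )
        prec = np.linalg.inv(np.corrcoef(ranks.T))
        rho_matrix = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert pc.rho == pytest.approx(rho_matrix, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        c = rng.normal(size=(50, 2))
        base = st.partial_spearman(x, y, c)
        warped = st.partial_spearman(
            np.exp(x), y**3 + 2 * y, np.column_stack([np.tanh(c[:, 0]), c[:, 1]])
        )
        assert warped.rho == pytest.approx(base.rho, abs=1e-12)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(st.DegenerateDesignError):
            st.partial_spearman(np.ones(20), rng.normal(size=20))
        x = rng.normal(size=20)
        dup = rng.normal(size=20)
        with pytest.raises(st.DegenerateDesignError):
            st.partial_spearman(x, rng.normal(size=20), np.column_stack([dup, dup]))


class TestReflectSqrt:
    def test_maximum_maps_to_one(self):
        out = st.reflect_sqrt_transform([3.0, 7.0, 7.0])
        assert out[1] == pytest.approx(1.0)

    @given(hst.lists(hst.integers(-10_000, 10_000), min_size=2, max_size=40, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_strictly_decreasing(self, vals):
        x = np.asarray(vals, dtype=float)
        t = st.reflect_sqrt_transform(x)
        order = np.argsort(x)
        assert (np.diff(t[order]) < 0).all()

    def test_spearman_sign_inverts_exactly(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40) + x
        before = sps.spearmanr(x, y).statistic
        after = sps.spearmanr(st.reflect_sqrt_transform(x), y).statistic
        assert after == pytest.approx(-before, abs=1e-12)


# ---------------------------------------------------------------------------
# regression models

class TestRegression:
    def test_single_dependent_reduces_to_partial_f(self, rng):
        df = pd.DataFrame(
            {"y": rng.normal(size=50), "x1": rng.normal(size=50), "x2": rng.normal(size=50)}
        )
        res = st.fit_regression(st.RegressionSpec(["y"], ["x1", "x2"]), df)
        uni = res.univariate
        for term in ["x1", "x2"]:
            t = uni.loc[uni.term == term, "t"].iloc[0]
            assert res.multivariate.loc[term, "F"] == pytest.approx(t**2, rel=1e-10)
            assert res.multivariate.loc[term, "p"] == pytest.approx(
                uni.loc[uni.term == term, "p"].iloc[0], rel=1e-10
            )

    def test_collinear_terms_named(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"y": rng.normal(size=30), "a": x, "b": 2 * x})
        with pytest.raises(st.DegenerateDesignError, match="b"):
            st.fit_regression(st.RegressionSpec(["y"], ["a", "b"]), df)

    def test_coefficient_coverage(self):
        """beta1 = -2 lies inside its 95% CI in >= 93% of seeded replicates."""
        hits = 0
        n_reps = 500
        for i in range(n_reps):
            rng = np.random.default_rng(90000 + i)
            x = rng.normal(size=500)
            c = rng.normal(size=500)
            y = 1.0 - 2.0 * x + 0.5 * c + rng.normal(size=500)
            df = pd.DataFrame({"y": y, "x": x, "c": c})
            res = st.fit_regression(st.RegressionSpec(["y"], ["x", "c"]), df)
            row = res.univariate.query("term == 'x'").iloc[0]
            hits += row.ci_low <= -2.0 <= row.ci_high
        assert hits / n_reps >= 0.93

    def test_multivariate_null_calibration(self):
        rejections = 0
        n_reps = 2000
        for i in range(n_reps):
            rng = np.random.default_rng(123_000 + i)
            df = pd.DataFrame(
                {
                    "y1": rng.normal(size=60),
                    "y2": rng.normal(size=60),
                    "x": rng.normal(size=60),
                    "a": rng.normal(size=60),
                }
            )
            res = st.fit_regression(st.RegressionSpec(["y1", "y2"], ["x", "a"]), df)
            rejections += res.multivariate.loc["x", "p"] < 0.05
        assert 0.035 <= rejections / n_reps <= 0.065


class TestBonferroni:
    @pytest.mark.parametrize("m,expected", [(1, 0.05), (3, 0.017), (5, 0.01)])
    def test_corrected_alpha(self, m, expected):
        assert st.bonferroni(0.05, m) == expected

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            st.bonferroni(0.05, 0)

    def test_tiers(self):
        tiers = st.significance_tiers(0.02, m=3)
        assert tiers == {"alpha_05": True, "alpha_bonferroni": False, "alpha_001": False}
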