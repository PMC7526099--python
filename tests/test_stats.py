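"""Agreement statistics, logistic models, ROC/AUC, and summary tables."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from agile_frailty import stats as vs


class TestCohensKappa:
    def test_identical_ratings(self):
        r = vs.cohens_kappa([1, 2, 1, 2, 3], [1, 2, 1, 2, 3])
        assert r.kappa == 1.0

    def test_hand_computed_two_by_two(self):
        # a=45, b=5, c=5, d=45: p_o = 0.9, p_e = 0.5 -> kappa = 0.8
        a = [1] * 50 + [0] * 50
        b = [1] * 45 + [0] * 5 + [1] * 5 + [0] * 45
        r = vs.cohens_kappa(a, b)
        assert r.kappa == pytest.approx(0.8)
        assert r.observed_agreement == pytest.approx(0.9)
        assert r.chance_agreement == pytest.approx(0.5)
        assert r.p_value < 1e-6

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, 10_000)
        b = rng.integers(0, 4, 10_000)
        r = vs.cohens_kappa(a, b)
        assert abs(r.kappa) < 0.05
        assert r.p_value > 1e-4  # no evidence of agreement

    def test_degenerate_constant_marginals(self):
        r = vs.cohens_kappa([1, 1, 1], [1, 1, 1])
        assert r.kappa == 1.0
        assert r.warning is not None

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                    min_size=5, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_matches_sklearn_and_relabeling_invariance(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        r = vs.cohens_kappa(a, b)
        if not math.isnan(r.kappa):
            expected = cohen_kappa_score(a, b)
            if not math.isnan(expected):
                assert r.kappa == pytest.approx(expected, abs=1e-12)
            # kappa is invariant to a relabeling of categories
            relabeled = vs.cohens_kappa(10 - a, 10 - b)
            assert relabeled.kappa == pytest.approx(r.kappa, abs=1e-12)


class TestCronbachAlpha:
    def test_parallel_items_give_one(self):
        x = np.random.default_rng(1).standard_normal(100)
        mat = np.column_stack([x, x, x])
        assert vs.cronbach_alpha(mat).alpha == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(2)
        mat = rng.standard_normal((10_000, 10))
        assert abs(vs.cronbach_alpha(mat).alpha) < 0.05

    def test_two_item_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        y = 0.7 * x + math.sqrt(1 - 0.49) * rng.standard_normal(500)
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
        r = float(np.corrcoef(x, y)[0, 1])
        alpha = vs.cronbach_alpha(np.column_stack([x, y])).alpha
        assert alpha == pytest.approx(2 * r / (1 + r), abs=1e-10)

    def test_zero_total_variance_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            vs.cronbach_alpha([[1, -1], [2, -2], [3, -3]])


class TestLinCCC:
    def test_identity(self):
        x = np.random.default_rng(4).standard_normal(200)
        assert vs.lin_ccc(x, x) == pytest.approx(1.0)

    def test_location_shift_penalised_below_pearson(self):
        x = np.random.default_rng(5).standard_normal(200)
        ccc = vs.lin_ccc(x, x + 1.5)
        assert ccc < 1.0
        # closed form: shift c gives 2s²/(2s² + c²)
        s2 = float(np.mean((x - x.mean()) ** 2))
        assert ccc == pytest.approx(2 * s2 / (2 * s2 + 1.5**2))

    def test_independent_near_zero(self):
        rng = np.random.default_rng(6)
        assert abs(vs.lin_ccc(rng.standard_normal(10_000),
                              rng.standard_normal(10_000))) < 0.05

    def test_joint_affine_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(300)
        y = x + 0.3 * rng.standard_normal(300)
        base = vs.lin_ccc(x, y)
        assert vs.lin_ccc(3.2 * x - 1.0, 3.2 * y - 1.0) == pytest.approx(base)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            vs.lin_ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCccSampleSize:
    def test_vanishing_effect_overflows(self):
        r = vs.ccc_sample_size(0.80, 0.80 + 1e-14)
        assert math.isinf(r.n)
        assert r.message is not None

    def test_inverse_square_law(self):
        n1 = vs.ccc_sample_size(0.75, 0.80).n
        # doubling the Fisher-scale distance quarters the (n-3) part
        delta = math.atanh(0.80) - math.atanh(0.75)
        alt2 = math.tanh(math.atanh(0.75) + 2 * delta)
        n2 = vs.ccc_sample_size(0.75, alt2).n
        assert (n1 - 3) / (n2 - 3) == pytest.approx(4.0, rel=0.02)

    def test_degenerate_quantiles_give_minimal_n(self):
        r = vs.ccc_sample_size(0.75, 0.80, alpha=0.5, power=0.5)
        assert r.n == 4  # z-sum is zero: only the floor remains

    def test_non_ordered_inputs_rejected(self):
        with pytest.raises(ValueError):
            vs.ccc_sample_size(0.80, 0.75)


def logistic_loglik(beta, X, y):
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def grid_search_mle(X, y, half_width=8.0, points=17, rounds=8):
    """Iteratively refined grid search over the log-likelihood surface."""
    center = np.zeros(X.shape[1])
    width = half_width
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, points) for c in center]
        best, best_ll = None, -np.inf
        for beta in itertools.product(*axes):
            ll = logistic_loglik(np.array(beta), X, y)
            if ll > best_ll:
                best, best_ll = np.array(beta), ll
        center = best
        width = 2 * width / (points - 1)  # shrink around the best node
    return center


class TestFitOutcomeModel:
    def test_null_predictor_covers_one(self):
        rng = np.random.default_rng(8)
        n = 4000
        df = pd.DataFrame({
            "score": rng.integers(0, 11, n),
            "age": rng.normal(77, 7, n),
            "sex": rng.choice(["male", "female"], n),
            "died": rng.random(n) < 0.2,
        })
        est = vs.fit_outcome_model(df, "died", "score")
        assert est.ci_low < 1.0 < est.ci_high
        assert est.rr == pytest.approx(1.0, abs=0.05)

    def test_matches_brute_force_likelihood_grid(self):
        rng = np.random.default_rng(9)
        n = 60
        x = rng.integers(0, 4, n).astype(float)
        w = rng.standard_normal(n)
        eta = -0.5 + 0.8 * x + 0.3 * w
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "age": w, "sex": ["male"] * n})
        est = vs.fit_outcome_model(df, "y", "x", adjust=("age",))
        X = np.column_stack([np.ones(n), x, w])
        beta_grid = grid_search_mle(X, y)
        assert math.log(est.rr) == pytest.approx(beta_grid[1], abs=1e-3)

    def test_perfect_separation_raises(self):
        df = pd.DataFrame({
            "y": [0, 0, 0, 1, 1, 1],
            "x": [0, 1, 2, 5, 6, 7],
            "age": [70] * 6,
            "sex": ["male"] * 6,
        })
        with pytest.raises(vs.SeparationError):
            vs.fit_outcome_model(df, "y", "x", adjust=())

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"y": [0, 0], "x": [1, 2], "age": [70, 71],
                           "sex": ["male", "female"]})
        with pytest.raises(ValueError, match="both classes"):
            vs.fit_outcome_model(df, "y", "x")


def pair_counting_auc(scores, outcome):
    """Exact-rational AUC oracle: (concordant + half the tied pairs) / (n1*n0)."""
    pos = [s for s, y in zip(scores, outcome) if y == 1]
    neg = [s for s, y in zip(scores, outcome) if y == 0]
    num = Fraction(0)
    for p in pos:
        for q in neg:
            if p > q:
                num += 1
            elif p == q:
                num += Fraction(1, 2)
    return num / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = vs.roc_auc([1, 1, 9, 9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_constant_score(self):
        r = vs.roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_small_tied_example(self):
        r = vs.roc_auc([1, 2, 2, 3], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.875)  # 3.5 of 4 pairs
        assert r.points[0] == (0.0, 0.0) and r.points[-1] == (1.0, 1.0)

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(10)
        s = rng.integers(0, 11, 500)
        y = (rng.random(500) < 0.3).astype(int)
        y[0], y[1] = 0, 1
        r = vs.roc_auc(s, y)
        assert r.points[0] == (0.0, 0.0) and r.points[-1] == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            vs.roc_auc([1, 2, 3], [1, 1, 1])

    @given(st.lists(st.tuples(st.integers(0, 10), st.integers(0, 1)),
                    min_size=4, max_size=80))
    @settings(max_examples=100, deadline=None)
    def test_trapezoid_equals_rank_and_sklearn(self, pairs):
        s = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs])
        if y.sum() in (0, len(y)):
            return
        auc = vs.roc_auc(s, y).auc
        assert auc == pytest.approx(vs.rank_auc(s, y), abs=1e-12)
        assert auc == pytest.approx(float(pair_counting_auc(s, y)), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestTablesAndTrend:
    @pytest.mark.parametrize(
        "count, total, cell",
        [(207, 400, "51.8 (207)"), (0, 72, "0.0 (0)"), (67, 68, "98.5 (67)")],
    )
    def test_percent_count_rendering(self, count, total, cell):
        assert vs.format_percent_count(count, total) == cell

    def test_trend_test_flat_vs_graded(self):
        chi_flat, p_flat = vs.chi_square_trend([20, 20, 20], [100, 100, 100])
        assert p_flat > 0.9
        chi_grad, p_grad = vs.chi_square_trend([5, 50, 60], [100, 100, 100])
        assert p_grad < 1e-6

    def test_stratum_summary_layout(self):
        rng = np.random.default_rng(11)
        n = 300
        df = pd.DataFrame({
            "agile_stratum": rng.choice(["light", "moderate", "severe"], n),
            "age": rng.normal(77, 7, n),
            "flag": (rng.random(n) < 0.4).astype(int),
        })
        out = vs.stratum_summary(df, continuous=["age"], binary=["flag"],
                                 bonferroni=True)
        assert out["strata"] == ["light", "moderate", "severe"]
        assert "±" in out["continuous"]["age"]["cells"]["all"]
        assert "(" in out["binary"]["flag"]["cells"]["all"]
        assert len(out["continuous"]["age"]["bonferroni_pairwise"]) == 3

    def test_identical_group_means_give_large_anova_p(self):
        df = pd.DataFrame({
            "agile_stratum": ["light", "moderate", "severe"] * 2000,
            "v": np.tile([1.0, 2.0], 3000),
        })
        out = vs.stratum_summary(df, continuous=["v"])
        assert out["continuous"]["v"]["anova_p"] > 0.99

    def test_empty_stratum_omitted_with_warning(self):
        df = pd.DataFrame({"agile_stratum": ["light"] * 5, "flag": [1, 0, 0, 1, 0]})
        out = vs.stratum_summary(df, binary=["flag"])
        assert out["strata"] == ["light"]
        assert any("moderate" in w for w in out["warnings"])
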