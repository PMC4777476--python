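"""Unit tests for the logistic-regression engine and its metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from favsdm import glm
from favsdm.glm import INTERCEPT

from conftest import simulate_logistic


def design(**cols):
    n = len(next(iter(cols.values())))
    d = {INTERCEPT: np.ones(n)}
    d.update({k: np.asarray(v, dtype=float) for k, v in cols.items()})
    return pd.DataFrame(d)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 5 + [0] * 15)
        m = glm.fit_logistic(design(dummy=np.zeros(20)).iloc[:, :1], y)
        assert m.predict_proba(pd.DataFrame(index=range(20))) == pytest.approx([0.25] * 20)
        assert m.log_lik == pytest.approx(5 * np.log(0.25) + 15 * np.log(0.75))
        assert m.log_lik == pytest.approx(m.null_log_lik)

    def test_perfect_separation_flagged(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        m = glm.fit_logistic(design(x=x), x.astype(int))
        assert m.separation

    def test_single_class_rejected(self):
        with pytest.raises(glm.SingleClassError):
            glm.fit_logistic(design(x=np.arange(6.0)), np.ones(6))

    def test_rank_deficiency_names_columns(self):
        x = np.arange(10.0)
        y = np.array([0, 1] * 5)
        with pytest.raises(glm.RankDeficiencyError) as err:
            glm.fit_logistic(design(a=x, b=2 * x), y)
        assert set(err.value.columns) & {"a", "b"}

    def test_matches_brute_force_on_tiny_instances(self):
        """IRLS agrees with direct likelihood maximization (|dbeta| < 1e-4)."""
        cases = [
            (np.array([-1.5, -1.0, -0.5, 0.5, 1.0, 1.5]), np.array([0, 0, 1, 0, 1, 1])),
            (np.array([-2.0, -1.0, 0.0, 0.0, 1.0, 2.0, 0.5, -0.5]), np.array([0, 1, 0, 1, 1, 1, 0, 0])),
            (np.array([0.1, 0.4, -0.3, 0.8, -0.9, 0.2, -0.2, 0.6]), np.array([1, 1, 0, 1, 0, 0, 1, 0])),
        ]
        for x, y in cases:
            X = design(x=x)
            m = glm.fit_logistic(X, y)

            def nll(b):
                eta = X.to_numpy() @ b
                return -(y @ eta - np.logaddexp(0, eta).sum())

            ref = minimize(nll, np.zeros(2), method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
            assert np.max(np.abs(m.beta - ref.x)) < 1e-4

    def test_matches_statsmodels(self, rng):
        X, y = simulate_logistic(rng, 500, -1.0, 0.8)
        m = glm.fit_logistic(X, y)
        import statsmodels.api as sm

        ref = sm.Logit(y, X.to_numpy()).fit(disp=0)
        assert np.allclose(m.beta, ref.params, atol=1e-6)
        assert np.allclose(m.se, ref.bse, rtol=1e-4)
        assert m.log_lik == pytest.approx(ref.llf, abs=1e-8)

    def test_coefficient_recovery(self, rng):
        X, y = simulate_logistic(rng, 2000, -3.0, 1.5)
        m = glm.fit_logistic(X, y)
        assert abs(m.beta[0] - (-3.0)) < 0.5 and abs(m.beta[1] - 1.5) < 0.5


class TestLrTest:
    def test_identical_models_give_p_one(self, rng):
        X, y = simulate_logistic(rng, 100, 0.0, 1.0)
        m = glm.fit_logistic(X, y)
        assert glm.lr_test(m, m) == 1.0

    def test_chi2_quantile(self, rng):
        # deviance difference 3.841 on 1 df sits at p ~ 0.050
        X, y = simulate_logistic(rng, 200, 0.0, 0.5)
        full = glm.fit_logistic(X, y)
        reduced = glm.fit_logistic(X.iloc[:, :1], y)
        from scipy.stats import chi2

        expect = chi2.sf(2 * (full.log_lik - reduced.log_lik), 1)
        assert glm.lr_test(full, reduced) == pytest.approx(expect)
        assert chi2.sf(3.841, 1) == pytest.approx(0.050, abs=5e-4)

    def test_null_term_p_uniform(self, rng):
        """Adding pure noise: rejection rate at 0.05 stays near 5%."""
        rejections = 0
        reps = 300
        for _ in range(reps):
            X, y = simulate_logistic(rng, 80, -0.5, 0.0)
            full = glm.fit_logistic(X, y)
            reduced = glm.fit_logistic(X.iloc[:, :1], y)
            if glm.lr_test(full, reduced) < 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_non_nested_rejected(self, rng):
        X, y = simulate_logistic(rng, 50, 0.0, 1.0)
        X2 = X.rename(columns={"x": "z"})
        a = glm.fit_logistic(X, y)
        b = glm.fit_logistic(X2, y)
        with pytest.raises(ValueError):
            glm.lr_test(a, b)


def oracle_step_up(p, q):
    """Literal Benjamini-Hochberg: check every index by hand."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * q / m:
            k = rank
    accepted = set(order[:k])
    return [i in accepted for i in range(m)]


class TestBhFdr:
    @pytest.mark.parametrize(
        "pvals, expect",
        [
            ([0.001, 0.04, 0.2], [True, False, False]),
            ([1.0, 1.0, 1.0], [False, False, False]),
            ([0.01, 0.02, 0.03, 0.04], [True, True, True, True]),
        ],
    )
    def test_worked_examples(self, pvals, expect):
        assert glm.bh_fdr(pvals, 0.05).tolist() == expect

    def test_empty(self):
        assert glm.bh_fdr([], 0.05).tolist() == []

    def test_exhaustive_against_oracle(self):
        """All p-vectors of length <= 5 over a fixed grid match the hand step-up."""
        grid = [0.001, 0.011, 0.04, 0.06, 0.3, 1.0]
        for length in range(1, 6):
            for combo in itertools.product(grid, repeat=length):
                got = glm.bh_fdr(list(combo), 0.05).tolist()
                assert got == oracle_step_up(combo, 0.05), combo


class TestStepwise:
    def test_no_signal_gives_intercept_only(self, rng):
        n = 200
        cands = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        y = (rng.random(n) < 0.3).astype(int)
        m = glm.stepwise(cands, y, p_enter=1e-6, p_remove=1e-5)
        assert m.terms == [INTERCEPT]

    def test_strong_predictor_enters_first(self, rng):
        hits = 0
        reps = 40
        for _ in range(reps):
            n = 1000
            x = rng.standard_normal((n, 6))
            y = (rng.random(n) < expit(-1.0 + 1.5 * x[:, 0])).astype(int)
            cands = pd.DataFrame(x, columns=[f"v{i}" for i in range(6)])
            m = glm.stepwise(cands, y)
            if m.entry_order.get("v0") == 1:
                hits += 1
        assert hits / reps >= 0.95

    def test_duplicate_column_enters_once(self, rng):
        n = 400
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(x)).astype(int)
        cands = pd.DataFrame({"a": x, "b": x})
        m = glm.stepwise(cands, y)
        assert sorted(set(m.terms) & {"a", "b"}) == ["a"]

    def test_retained_terms_pass_removal_threshold(self, rng):
        """Self-consistency: every retained term's removal p <= p_remove."""
        n = 600
        x = rng.standard_normal((n, 5))
        y = (rng.random(n) < expit(-0.5 + 0.8 * x[:, 0] - 0.6 * x[:, 1])).astype(int)
        cands = pd.DataFrame(x, columns=[f"v{i}" for i in range(5)])
        m = glm.stepwise(cands, y)
        terms = [t for t in m.terms if t != INTERCEPT]
        for t in terms:
            rest = [u for u in terms if u != t]
            p = glm.lr_test(m, glm.fit_terms(cands, rest, y))
            assert p <= glm.P_REMOVE_DEFAULT + 1e-12

    def test_entry_order_is_permutation(self, rng):
        n = 800
        x = rng.standard_normal((n, 4))
        y = (rng.random(n) < expit(0.7 * x[:, 0] + 0.5 * x[:, 2])).astype(int)
        m = glm.stepwise(pd.DataFrame(x, columns=list("wxyz")), y)
        k = len(m.terms) - 1
        assert sorted(m.entry_order.values()) == list(range(1, k + 1))

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            glm.stepwise(pd.DataFrame({"a": [0.0, 1, 2, 3]}), [0, 1, 0, 1], p_enter=0.2, p_remove=0.1)


class TestVif:
    def test_orthogonal_columns_unity(self):
        d = pd.DataFrame({"a": [1.0, 1, -1, -1], "b": [1.0, -1, 1, -1]})
        assert glm.vif(d).to_numpy() == pytest.approx([1.0, 1.0])

    def test_near_copy_explodes(self, rng):
        x = rng.standard_normal(300)
        d = pd.DataFrame({"a": x, "b": x + 0.01 * rng.standard_normal(300)})
        assert (glm.vif(d) > 100).all()

    def test_two_column_closed_form(self, rng):
        # correlation 0.8 -> VIF = 1/(1-0.64) = 2.78
        n = 200000
        x = rng.standard_normal(n)
        z = 0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        got = glm.vif(pd.DataFrame({"a": x, "b": z}))
        assert got.to_numpy() == pytest.approx([1 / (1 - 0.64)] * 2, rel=0.02)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            glm.vif(pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]}))


class TestFitMetrics:
    def test_nagelkerke_null_is_zero(self, rng):
        X, y = simulate_logistic(rng, 100, 0.0, 0.0)
        m = glm.fit_logistic(X.iloc[:, :1], y)
        assert glm.nagelkerke_r2(m) == pytest.approx(0.0, abs=1e-10)

    def test_nagelkerke_worked_value(self):
        m = glm.FittedLogisticModel(
            terms=[INTERCEPT, "x"], beta=np.zeros(2), se=np.zeros(2), p_value=np.zeros(2),
            log_lik=-50.0, null_log_lik=-69.3147, n=100, n1=50, n0=50,
        )
        expect = (1 - np.exp(-0.386294)) / (1 - np.exp(-1.386294))
        assert glm.nagelkerke_r2(m) == pytest.approx(expect, abs=1e-6)
        # independent arithmetic: (1 - 0.25e)/0.75 with e = 2.718282
        assert expect == pytest.approx((1 - 0.25 * np.e) / 0.75, abs=1e-6)
        assert expect == pytest.approx(0.4272, abs=5e-4)

    def test_nagelkerke_row_duplication_invariant(self, rng):
        X, y = simulate_logistic(rng, 150, -0.5, 1.0)
        m1 = glm.fit_logistic(X, y)
        X2 = pd.concat([X, X], ignore_index=True)
        m2 = glm.fit_logistic(X2, np.concatenate([y, y]))
        assert glm.nagelkerke_r2(m1) == pytest.approx(glm.nagelkerke_r2(m2), abs=1e-8)

    def test_aic(self, rng):
        y = np.array([1] * 5 + [0] * 15)
        m = glm.fit_logistic(pd.DataFrame({INTERCEPT: np.ones(20)}), y)
        assert glm.aic(m) == pytest.approx(2 - 2 * (5 * np.log(0.25) + 15 * np.log(0.75)))
        m3 = glm.FittedLogisticModel(
            terms=[INTERCEPT, "a", "b"], beta=np.zeros(3), se=np.zeros(3), p_value=np.zeros(3),
            log_lik=-10.0, null_log_lik=-10.0, n=20, n1=5, n0=15,
        )
        assert glm.aic(m3) == pytest.approx(26.0)


def trapezoid_auc(scores, labels):
    """Independent oracle: area under the empirical ROC by trapezoids."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(scores))[::-1], [-np.inf]])
    tpr, fpr = [], []
    p = labels.sum()
    n = len(labels) - p
    for t in thresholds:
        pred = scores >= t
        tpr.append((pred & (labels == 1)).sum() / p)
        fpr.append((pred & (labels == 0)).sum() / n)
    return float(np.trapezoid(tpr, fpr))


class TestRocAuc:
    def test_perfect_separation(self):
        assert glm.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert glm.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_enumeration_example(self):
        assert glm.roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_equals_trapezoidal_formulation(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 60))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert glm.roc_auc(scores, labels) == pytest.approx(trapezoid_auc(scores, labels), abs=1e-12)


class TestConfusionMetrics:
    def test_perfect(self):
        assert glm.confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0], 0.5) == (1.0, 1.0, 1.0)

    def test_worked_table(self):
        s, sp, c = glm.confusion_metrics([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0], 0.5)
        assert (s, sp, c) == (0.5, 0.5, 0.5)

    def test_zero_threshold_all_positive(self):
        s, sp, _ = glm.confusion_metrics([0.3, 0.6, 0.2, 0.9], [1, 0, 1, 0], 0.0)
        assert (s, sp) == (1.0, 0.0)

    def test_threshold_boundary_is_positive(self):
        s, sp, c = glm.confusion_metrics([0.5, 0.4], [1, 0], 0.5)
        assert (s, sp, c) == (1.0, 1.0, 1.0)
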