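import math

import numpy as np
import pytest

from gcsurv.omics_io import SurvivalTable
from gcsurv.survival_risk import (
    RiskScores,
    breslow_neg_log_pl,
    concordance_index,
    fit_cox_en,
    km_curve,
    logrank_test,
    predict_risk,
    stratify_median,
    RiskModel,
    RiskGroups,
)


def _surv(times, events, prefix="s"):
    ids = [f"{prefix}{i}" for i in range(len(times))]
    return SurvivalTable(ids, times, events)


def _scores(risks, prefix="s"):
    return RiskScores([f"{prefix}{i}" for i in range(len(risks))], np.asarray(risks, float))


class TestCoxElasticNet:
    def _sim(self, n=60, p=4, seed=0, beta=None):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        beta = np.zeros(p) if beta is None else np.asarray(beta, float)
        eta = X @ beta
        T = rng.exponential(1.0 / (0.1 * np.exp(eta)))
        C = rng.uniform(0, np.quantile(T, 0.9), size=n)
        y = np.minimum(T, C)
        d = (T <= C).astype(int)
        return X, _surv(y, d)

    def test_huge_penalty_shrinks_to_zero(self):
        X, surv = self._sim(beta=[1.0, -0.5, 0, 0])
        model = fit_cox_en(X, surv, lambda_en=1e6, alpha_mix=0.5)
        assert np.abs(model.beta).max() < 1e-6

    def test_single_negative_time_covariate_positive_beta(self):
        # covariate = -survival time, no censoring: higher covariate -> earlier
        # event, so the partial-likelihood score at 0 is positive and beta > 0.
        # The unpenalized likelihood is monotone here (perfect concordance), so
        # a light ridge keeps the optimum finite for the grid comparison.
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        X = (-times)[:, None]
        surv = _surv(times, np.ones(6, dtype=int))
        lam = 0.5
        model = fit_cox_en(X, surv, lambda_en=lam, alpha_mix=0.0)
        assert model.beta[0] > 0
        # brute-force 1-D grid on the penalized objective
        grid = np.linspace(-2, 6, 1601)
        nll = [
            breslow_neg_log_pl(X[:, 0] * b, surv.time, surv.event) + lam * b * b / 2
            for b in grid
        ]
        b_grid = grid[int(np.argmin(nll))]
        assert model.beta[0] == pytest.approx(b_grid, abs=0.01)

    def test_unpenalized_matches_lifelines(self):
        from lifelines import CoxPHFitter
        import pandas as pd

        X, surv = self._sim(n=20, p=3, seed=3, beta=[0.8, -0.8, 0])
        model = fit_cox_en(X, surv, lambda_en=0.0)
        df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        df["T"] = surv.time
        df["E"] = surv.event
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        np.testing.assert_allclose(
            model.beta, cph.params_[["x0", "x1", "x2"]].to_numpy(), atol=1e-4
        )

    def test_ridge_never_exact_zero_lasso_sparsifies(self):
        X, surv = self._sim(n=80, p=6, seed=5, beta=[1, 0, 0, 0, 0, 0])
        ridge = fit_cox_en(X, surv, lambda_en=5.0, alpha_mix=0.0)
        assert (ridge.beta != 0).all()
        lasso = fit_cox_en(X, surv, lambda_en=20.0, alpha_mix=1.0)
        assert (lasso.beta == 0).any()

    def test_zero_events_errors(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        surv = _surv(np.arange(1.0, 11.0), np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            fit_cox_en(X, surv, lambda_en=1.0)

    def test_cv_lambda_selection_runs(self):
        X, surv = self._sim(n=100, p=5, seed=7, beta=[1.0, -1.0, 0, 0, 0])
        model = fit_cox_en(X, surv, seed=1)
        assert model.lambda_en > 0
        assert np.isfinite(model.beta).all()


class TestPredictAndStratify:
    def test_zero_beta_zero_risks(self):
        model = RiskModel(np.zeros(3), 1.0, 0.5, 10)
        Z = np.random.default_rng(0).normal(size=(5, 3))
        assert (predict_risk(model, Z).r == 0).all()

    def test_linearity_and_permutation(self):
        rng = np.random.default_rng(1)
        beta = rng.normal(size=4)
        Z = rng.normal(size=(6, 4))
        r1 = predict_risk(RiskModel(beta, 0, 0.5, 6), Z).r
        r2 = predict_risk(RiskModel(2 * beta, 0, 0.5, 6), Z).r
        np.testing.assert_allclose(r2, 2 * r1)
        perm = rng.permutation(6)
        rp = predict_risk(RiskModel(beta, 0, 0.5, 6), Z[perm]).r
        np.testing.assert_allclose(rp, r1[perm])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            predict_risk(RiskModel(np.ones(3), 0, 0.5, 5), np.ones((4, 2)))

    def test_median_split_even(self):
        g = stratify_median(_scores([1, 2, 3, 4]))
        assert g.label == ["low", "low", "high", "high"]

    def test_median_split_odd_tie_goes_low(self):
        g = stratify_median(_scores([1, 2, 3]))
        assert g.label == ["low", "low", "high"]
        assert g.label.count("low") == g.label.count("high") + 1

    def test_degenerate_risks_error(self):
        with pytest.raises(ValueError):
            stratify_median(_scores([2.0, 2.0, 2.0]))


class TestConcordance:
    def test_perfect_and_anti_and_ties(self):
        surv = _surv([1.0, 2.0, 3.0], [1, 1, 1])
        assert concordance_index(_scores([3, 2, 1]), surv)[0] == 1.0
        assert concordance_index(_scores([1, 2, 3]), surv)[0] == 0.0
        assert concordance_index(_scores([5, 5, 5]), surv)[0] == 0.5

    def test_no_censoring_all_pairs_comparable(self):
        rng = np.random.default_rng(0)
        n = 20
        surv = _surv(rng.uniform(1, 10, n), np.ones(n, dtype=int))
        _, n_pairs = concordance_index(_scores(rng.normal(size=n)), surv)
        assert n_pairs == n * (n - 1) // 2

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        times = rng.choice(np.arange(1.0, 12.0), size=n)  # force some ties
        events = rng.integers(0, 2, size=n)
        if events.sum() == 0:
            events[0] = 1
        risks = rng.choice(np.arange(-3.0, 4.0), size=n)
        surv = _surv(times, events)
        # literal pairwise oracle following the stated comparability rule
        num = den = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                ti, tj, ri, rj = times[i], times[j], risks[i], risks[j]
                di, dj = events[i], events[j]
                if ti == tj:
                    if di and dj and ri != rj:
                        num += 0.5
                        den += 1
                    continue
                a, b = (i, j) if ti < tj else (j, i)
                if events[a]:
                    den += 1
                    if risks[a] > risks[b]:
                        num += 1.0
                    elif risks[a] == risks[b]:
                        num += 0.5
        ci, n_pairs = concordance_index(_scores(risks), surv)
        assert n_pairs == int(den)
        assert ci == pytest.approx(num / den, abs=1e-12)

    def test_reversal_symmetry_without_ties(self):
        rng = np.random.default_rng(4)
        n = 30
        surv = _surv(rng.uniform(1, 100, n), rng.integers(0, 2, n) | 1)
        r = rng.normal(size=n)
        ci_fwd, _ = concordance_index(_scores(r), surv)
        ci_rev, _ = concordance_index(_scores(-r), surv)
        assert ci_fwd + ci_rev == pytest.approx(1.0, abs=1e-12)

    def test_random_risks_average_half(self):
        rng = np.random.default_rng(11)
        n = 200
        cis = []
        for _ in range(1000):
            times = rng.exponential(10, n)
            events = (rng.random(n) < 0.7).astype(int)
            surv = _surv(times, events)
            cis.append(concordance_index(_scores(rng.normal(size=n)), surv)[0])
        assert abs(np.mean(cis) - 0.5) < 0.02

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        n = 25
        surv = _surv(rng.uniform(1, 50, n), rng.integers(0, 2, n))
        r = rng.normal(size=n)
        ci1, _ = concordance_index(_scores(r), surv)
        ci2, _ = concordance_index(_scores(np.exp(2 * r) + 3), surv)
        assert ci1 == pytest.approx(ci2)


class TestLogrank:
    def test_identical_groups_p_one(self):
        times = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        events = np.array([1, 1, 0, 1, 1, 0])
        surv = _surv(times, events)
        groups = RiskGroups(surv.sample_ids, ["high"] * 3 + ["low"] * 3)
        p, alp = logrank_test(groups, surv)
        assert p == pytest.approx(1.0)
        assert alp == pytest.approx(0.0)

    def test_matches_hand_tabulation(self):
        # group A times {1,2,3} all events vs B {10,20,30} all events
        times = np.array([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        events = np.ones(6, dtype=int)
        surv = _surv(times, events)
        groups = RiskGroups(surv.sample_ids, ["high"] * 3 + ["low"] * 3)
        # hand tabulation over the 6 distinct event times
        o_minus_e = 0.0
        var = 0.0
        at_risk_a, at_risk_b = 3, 3
        for t in times:
            n = at_risk_a + at_risk_b
            d = 1
            in_a = 1 if t in (1.0, 2.0, 3.0) else 0
            e_a = d * at_risk_a / n
            o_minus_e += in_a - e_a
            if n > 1:
                var += d * (at_risk_a / n) * (1 - at_risk_a / n) * (n - d) / (n - 1)
            if in_a:
                at_risk_a -= 1
            else:
                at_risk_b -= 1
        chi2 = o_minus_e**2 / var
        from scipy import stats

        p_expected = stats.chi2.sf(chi2, df=1)
        p, _ = logrank_test(groups, surv)
        assert p == pytest.approx(p_expected, rel=1e-6)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        n = 40
        surv = _surv(rng.exponential(5, n), rng.integers(0, 2, n) | 1)
        labels = ["high" if i < 20 else "low" for i in range(n)]
        g1 = RiskGroups(surv.sample_ids, labels)
        g2 = RiskGroups(surv.sample_ids, ["low" if l == "high" else "high" for l in labels])
        assert logrank_test(g1, surv)[0] == pytest.approx(logrank_test(g2, surv)[0])

    def test_single_group_errors(self):
        surv = _surv([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            logrank_test(RiskGroups(surv.sample_ids, ["high", "high"]), surv)

    def test_null_p_values_uniform(self):
        # random group labels independent of survival -> p ~ Uniform(0,1)
        rng = np.random.default_rng(8)
        n = 60
        pvals = []
        for _ in range(2000):
            times = rng.exponential(5, n)
            events = (rng.random(n) < 0.8).astype(int)
            labels = np.where(rng.random(n) < 0.5, "high", "low")
            if len(set(labels)) < 2:
                continue
            surv = _surv(times, events)
            p, _ = logrank_test(RiskGroups(surv.sample_ids, list(labels)), surv)
            pvals.append(p)
        from scipy import stats

        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestKaplanMeier:
    def test_no_censoring_product_limit(self):
        surv = _surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        km = km_curve(surv)
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(0.75)
        assert lookup[2.0] == pytest.approx(0.5)
        assert lookup[3.0] == pytest.approx(0.25)
        assert lookup[4.0] == pytest.approx(0.0)

    def test_all_censored_flat_one(self):
        surv = _surv([1.0, 2.0, 3.0], [0, 0, 0])
        km = km_curve(surv)
        assert (km["survival"] == 1.0).all()

    def test_censoring_reduces_risk_set_without_step(self):
        # times {1, 2+, 3, 4}: S(1)=3/4, censoring at 2 shrinks the risk set to
        # 2 without a step, so S(3) = 3/4 * 1/2 = 0.375
        surv = _surv([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 1])
        km = km_curve(surv)
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(0.75)
        assert lookup[3.0] == pytest.approx(0.375)
        # independent product-limit oracle
        s = 1.0
        expected = {}
        at_risk = 4
        for t, d in [(1.0, 1), (2.0, 0), (3.0, 1), (4.0, 1)]:
            if d:
                s *= 1 - 1 / at_risk
            expected[t] = s
            at_risk -= 1
        assert lookup[3.0] == pytest.approx(expected[3.0])
        assert lookup[4.0] == pytest.approx(expected[4.0])
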