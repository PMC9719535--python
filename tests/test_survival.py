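import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from lncoop.errors import DegenerateFitError, ValidationError
from lncoop.survival import (
    RiskModel,
    km_logrank,
    median_split_survival,
    optimal_cutpoint,
    risk_score,
    stepwise_cox,
    univariate_cox,
    univariate_screen,
)


def simulate_cohort(n=300, beta=0.0, seed=0, censor_window=30.0, n_noise=0):
    """Exponential survival with log-hazard beta per sd of the covariate."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    lam = 0.1 * np.exp(beta * x)
    t_event = rng.exponential(1 / lam)
    c = rng.uniform(0, censor_window, size=n)
    samples = [f"s{i}" for i in range(n)]
    clinical = pd.DataFrame({
        "os_time": np.minimum(t_event, c),
        "os_event": (t_event <= c).astype(int),
    }, index=samples)
    expr = {"target": x}
    for j in range(n_noise):
        expr[f"noise{j}"] = rng.normal(size=n)
    return pd.DataFrame(expr, index=samples).T, clinical


class TestUnivariateCox:
    def test_null_covariate_unit_hr(self):
        errs = []
        for seed in range(10):
            expr, clin = simulate_cohort(n=300, beta=0.0, seed=seed)
            res = univariate_cox(expr.loc["target"], clin)
            errs.append(abs(res.log_hr))
        assert np.mean(errs) < 0.15

    def test_planted_hazard_recovered(self):
        expr, clin = simulate_cohort(n=500, beta=0.7, seed=1)
        res = univariate_cox(expr.loc["target"], clin)
        assert res.log_hr == pytest.approx(0.7, abs=0.15)
        assert res.ci_low < res.hr < res.ci_high

    def test_constant_covariate_errors(self):
        expr, clin = simulate_cohort(n=100, seed=2)
        const = pd.Series(1.0, index=expr.columns, name="flat")
        with pytest.raises(DegenerateFitError):
            univariate_cox(const, clin)

    def test_too_few_events_errors(self):
        expr, clin = simulate_cohort(n=50, seed=3)
        clin = clin.assign(os_event=0)
        with pytest.raises(DegenerateFitError):
            univariate_cox(expr.loc["target"], clin)


class TestStepwiseCox:
    def test_true_signal_selected_over_noise(self):
        selected = 0
        for seed in range(10):
            expr, clin = simulate_cohort(n=300, beta=0.8, seed=seed, n_noise=5)
            cands, _ = univariate_screen(expr, clin)
            model = stepwise_cox(expr, cands, clin)
            selected += "target" in model.lncrnas
        assert selected >= 9

    def test_all_noise_mostly_empty(self):
        sizes = []
        for seed in range(10):
            expr, clin = simulate_cohort(n=200, beta=0.0, seed=seed + 50,
                                         n_noise=4)
            cands, _ = univariate_screen(expr, clin)
            model = stepwise_cox(expr, cands, clin)
            sizes.append(len(model.lncrnas))
        assert np.mean(sizes) < 1.0

    def test_single_candidate_matches_univariate(self):
        expr, clin = simulate_cohort(n=300, beta=0.6, seed=4)
        uni = univariate_cox(expr.loc["target"], clin)
        model = stepwise_cox(expr, ["target"], clin)
        assert model.lncrnas == ["target"]
        assert model.betas["target"] == pytest.approx(uni.log_hr, abs=1e-3)


class TestRiskScore:
    def test_hand_arithmetic(self):
        model = RiskModel(lncrnas=["a", "b"], betas={"a": 0.5, "b": -1.0})
        expr = pd.DataFrame({"s1": [2.0, 1.0]}, index=["a", "b"])
        assert risk_score(model, expr)["s1"] == pytest.approx(0.0)

    def test_zero_coefficients(self):
        model = RiskModel(lncrnas=["a"], betas={"a": 0.0})
        expr = pd.DataFrame({"s1": [5.0], "s2": [7.0]}, index=["a"])
        assert (risk_score(model, expr) == 0).all()

    def test_linearity_in_coefficients(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 10)),
                            index=["a", "b"],
                            columns=[f"s{i}" for i in range(10)])
        m1 = RiskModel(lncrnas=["a", "b"], betas={"a": 0.3, "b": 0.7})
        m2 = RiskModel(lncrnas=["a", "b"], betas={"a": 0.6, "b": 1.4})
        np.testing.assert_allclose(2 * risk_score(m1, expr), risk_score(m2, expr))

    def test_missing_lncrna_named(self):
        model = RiskModel(lncrnas=["zz"], betas={"zz": 1.0})
        expr = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValidationError, match="zz"):
            risk_score(model, expr)


class TestKMLogrank:
    def test_identical_groups_p_one(self):
        t = [5.0, 8.0, 12.0, 20.0]
        e = [1, 1, 0, 1]
        clin = pd.DataFrame({"os_time": t + t, "os_event": e + e},
                            index=[f"s{i}" for i in range(8)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=clin.index)
        out = km_logrank(groups, clin)
        assert out["p"] == pytest.approx(1.0)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_invariance(self):
        expr, clin = simulate_cohort(n=100, beta=1.0, seed=5)
        groups = pd.Series(np.where(expr.loc["target"] > 0, "hi", "lo"),
                           index=clin.index)
        p1 = km_logrank(groups, clin)["p"]
        swapped = groups.map({"hi": "lo", "lo": "hi"})
        p2 = km_logrank(swapped, clin)["p"]
        assert p1 == pytest.approx(p2)

    def test_hand_computed_six_subject_logrank(self):
        """Observed-minus-expected tally computed by hand for 6 subjects:
        group A times (2, 4, 6) all events, group B times (1, 3, 5) all
        events. At each death the expected A-death is n_A/(n_A+n_B);
        O_A - E_A = 3 - (3/6+3/5+2/4+2/3+1/2+1) = -0.766...; the variance
        sum gives the chi-square below."""
        clin = pd.DataFrame({
            "os_time": [2.0, 4.0, 6.0, 1.0, 3.0, 5.0],
            "os_event": [1, 1, 1, 1, 1, 1],
        }, index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["A", "A", "A", "B", "B", "B"], index=clin.index)
        # hand tally (risk sets at death times 1..6):
        e_a = 3 / 6 + 3 / 5 + 2 / 4 + 2 / 3 + 1 / 2 + 1 / 1
        o_minus_e = 3 - e_a
        # variance terms: n_A*n_B/(n^2) at each single-death time
        var = (3 * 3 / 36) + (3 * 2 / 25) + (2 * 2 / 16) + (2 * 1 / 9) + (1 * 1 / 4) + 0
        chi2 = o_minus_e ** 2 / var
        out = km_logrank(groups, clin)
        assert out["statistic"] == pytest.approx(chi2, rel=1e-9)

    def test_zero_event_group_warns(self):
        clin = pd.DataFrame({"os_time": [1, 2, 3, 4.0],
                             "os_event": [1, 1, 0, 0]},
                            index=["a", "b", "c", "d"])
        groups = pd.Series(["x", "x", "y", "y"], index=clin.index)
        with pytest.warns(UserWarning, match="zero events"):
            km_logrank(groups, clin)


class TestOptimalCutpoint:
    def test_matches_exhaustive_scan_oracle(self):
        expr, clin = simulate_cohort(n=80, beta=1.0, seed=6)
        x = expr.loc["target"]
        out = optimal_cutpoint(x, clin)
        lo, hi = np.quantile(x, [0.1, 0.9])
        best = None
        for c in np.unique(x):
            if not (lo <= c <= hi) or not (x > c).any():
                continue
            high = x > c
            res = logrank_test(clin.os_time[high], clin.os_time[~high],
                               event_observed_A=clin.os_event[high],
                               event_observed_B=clin.os_event[~high])
            z = np.sqrt(res.test_statistic)
            if best is None or z > best[1]:
                best = (c, z)
        assert out["threshold"] == pytest.approx(best[0])
        assert out["statistic"] == pytest.approx(best[1])

    def test_bimodal_separating_threshold(self):
        rng = np.random.default_rng(7)
        n = 60
        x = np.r_[rng.normal(0, 0.3, n // 2), rng.normal(5, 0.3, n // 2)]
        t = np.r_[rng.exponential(2.0, n // 2), rng.exponential(20.0, n // 2)]
        clin = pd.DataFrame({"os_time": t, "os_event": 1},
                            index=[f"s{i}" for i in range(n)])
        xs = pd.Series(x, index=clin.index, name="x")
        with pytest.warns(UserWarning, match="selection-biased"):
            out = optimal_cutpoint(xs, clin)
        # the scan returns an observed value; perfect separation puts it in
        # the gap: at or above every low-mode value, below every high-mode one
        assert x[: n // 2].max() <= out["threshold"] < x[n // 2:].min()

    def test_monotone_transform_equivariance(self):
        expr, clin = simulate_cohort(n=60, beta=1.0, seed=8)
        x = expr.loc["target"]
        out1 = optimal_cutpoint(x, clin)
        out2 = optimal_cutpoint(np.exp(x).rename("ex"), clin)
        assert out2["threshold"] == pytest.approx(np.exp(out1["threshold"]))
        assert out2["statistic"] == pytest.approx(out1["statistic"])

    def test_constant_expression_errors(self):
        _, clin = simulate_cohort(n=40, seed=9)
        with pytest.raises(DegenerateFitError):
            optimal_cutpoint(pd.Series(2.0, index=clin.index), clin)


class TestMedianSplit:
    def test_even_split_distinct_scores(self):
        scores = pd.Series(np.arange(20, dtype=float),
                           index=[f"s{i}" for i in range(20)])
        _, clin = simulate_cohort(n=20, seed=10)
        clin.index = scores.index
        out = median_split_survival(scores, clin)
        assert out["groups"] == {"high": 10, "low": 10}

    def test_ties_go_low(self):
        scores = pd.Series([1.0] * 12 + [2.0] * 8,
                           index=[f"s{i}" for i in range(20)])
        _, clin = simulate_cohort(n=20, seed=11)
        clin.index = scores.index
        out = median_split_survival(scores, clin)
        assert out["groups"]["low"] == 12

    def test_planted_signature_orders_groups(self):
        correct = 0
        for seed in range(10):
            expr, clin = simulate_cohort(n=300, beta=0.8, seed=seed + 20)
            scores = 0.8 * expr.loc["target"]
            out = median_split_survival(scores, clin)
            km_high = out["curves"]["high"]
            km_low = out["curves"]["low"]
            grid = np.linspace(0.5, 10, 20)
            s_high = np.interp(grid, km_high.index, km_high.iloc[:, 0])
            s_low = np.interp(grid, km_low.index, km_low.iloc[:, 0])
            correct += (s_high <= s_low + 1e-9).mean() > 0.9
        assert correct >= 9
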