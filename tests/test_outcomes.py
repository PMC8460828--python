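"""Contingency construction, exact tests, response score, logistic factors."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import hypergeom

from ninep21.errors import AnalysisError
from ninep21.outcomes import (
    build_contingency,
    compute_response_score,
    derive_dcb,
    derive_score_weights,
    fisher_exact_2x2,
    fisher_exact_rxc,
    fit_logistic,
    lr_chisq_test,
    response_rates_compare,
    score_cohort,
)


class TestDcb:
    @pytest.mark.parametrize(
        "response,pfs,expected",
        [("CR", None, True), ("PR", 1.0, True), ("SD", 7.0, True),
         ("SD", 5.0, False), ("SD", 6.0, False), ("PD", 20.0, False)],
    )
    def test_rule(self, response, pfs, expected):
        assert derive_dcb(response, pfs) is expected

    def test_sd_without_pfs_is_na(self):
        assert pd.isna(derive_dcb("SD", None))


class TestContingency:
    def test_resectable_melanoma_counts(self):
        # 4 hi_hi (3 responders) and 5 lo_lo (0 responders)
        strata = pd.Series(["hi_hi"] * 4 + ["lo_lo"] * 5,
                           index=[f"P{i}" for i in range(9)])
        resp = pd.Series(["R", "R", "R", "N", "N", "N", "N", "N", "N"],
                         index=strata.index)
        t = build_contingency(strata, resp)
        assert t.loc["hi_hi"].tolist() == [1, 3]
        assert t.loc["lo_lo"].tolist() == [5, 0]

    def test_matches_loop_counting_oracle(self, rng):
        ids = [f"P{i}" for i in range(80)]
        a = pd.Series(rng.choice(["x", "y", "z"], 80), index=ids)
        b = pd.Series(rng.choice(["u", "v"], 80), index=ids)
        t = build_contingency(a, b)
        for ai in ["x", "y", "z"]:
            for bi in ["u", "v"]:
                assert t.loc[ai, bi] == sum(
                    (a[i] == ai) and (b[i] == bi) for i in ids
                )

    def test_disjoint_ids_error(self):
        a = pd.Series(["x"], index=["P1"])
        b = pd.Series(["u"], index=["P2"])
        with pytest.raises(AnalysisError):
            build_contingency(a, b)

    def test_na_dropped_with_report(self):
        ids = ["P1", "P2", "P3"]
        a = pd.Series(["x", None, "y"], index=ids)
        b = pd.Series(["u", "v", "u"], index=ids)
        with pytest.warns(UserWarning, match="1 sample"):
            t = build_contingency(a, b)
        assert t.to_numpy().sum() == 2


def fisher_oracle(table):
    """Two-sided p by explicit hypergeometric enumeration over the support."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = {x: hypergeom.pmf(x, n, r1, c1) for x in support}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


class TestFisher2x2:
    @pytest.mark.parametrize(
        "table,expected",
        [([[3, 1], [0, 5]], 0.048), ([[4, 6], [1, 8]], 0.30),
         ([[8, 22], [1, 24]], 0.03)],
    )
    def test_printed_cohort_values(self, table, expected):
        assert fisher_exact_2x2(table).p == pytest.approx(expected, abs=5e-3)

    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            t = rng.integers(0, 15, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert fisher_exact_2x2(t).p == pytest.approx(fisher_oracle(t), rel=1e-9)

    def test_transposition_and_swap_invariance(self, rng):
        t = np.array([[7, 2], [3, 9]])
        p = fisher_exact_2x2(t).p
        assert fisher_exact_2x2(t.T).p == pytest.approx(p)
        assert fisher_exact_2x2(t[::-1, ::-1]).p == pytest.approx(p)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2([[0, 5], [0, 7]]).p == 1.0


def freeman_halton_oracle(table):
    """Exhaustive enumeration over all margin-preserving r x c tables."""
    table = np.asarray(table)
    rs, cs = table.sum(1), table.sum(0)

    def logp(t):
        return (gammaln(rs + 1).sum() + gammaln(cs + 1).sum()
                - gammaln(t.sum() + 1) - gammaln(t + 1).sum())

    lp_obs = logp(table)
    total = 0.0
    ranges = [range(min(rs[i], cs[j]) + 1)
              for i in range(len(rs) - 1) for j in range(len(cs) - 1)]
    shape = (len(rs) - 1, len(cs) - 1)
    for cells in itertools.product(*ranges):
        free = np.array(cells).reshape(shape)
        t = np.zeros((len(rs), len(cs)), dtype=int)
        t[:-1, :-1] = free
        t[:-1, -1] = rs[:-1] - free.sum(1)
        t[-1, :-1] = cs[:-1] - free.sum(0)
        t[-1, -1] = rs[-1] - t[-1, :-1].sum()
        if (t < 0).any():
            continue
        lp = logp(t)
        if lp <= lp_obs + np.log1p(1e-7):
            total += np.exp(lp)
    return total


class TestFisherRxc:
    def test_2x2_consistency(self, rng):
        for _ in range(20):
            t = rng.integers(1, 12, size=(2, 2))
            assert fisher_exact_rxc(t).p == pytest.approx(
                fisher_exact_2x2(t).p, rel=1e-9
            )

    def test_2x3_toy_matches_exhaustive_oracle(self):
        t = np.array([[2, 0], [0, 2], [1, 1]])
        assert fisher_exact_rxc(t).p == pytest.approx(
            freeman_halton_oracle(t), rel=1e-9
        )

    def test_random_3x3_matches_oracle(self, rng):
        for _ in range(5):
            t = rng.integers(1, 5, size=(3, 3))
            assert fisher_exact_rxc(t).p == pytest.approx(
                freeman_halton_oracle(t), rel=1e-9
            )

    def test_monte_carlo_agrees_with_enumeration(self):
        t = np.array([[8, 3], [2, 9], [5, 5]])
        exact = fisher_exact_rxc(t).p
        mc = fisher_exact_rxc(t, monte_carlo=True, n_draws=40000, seed=11).p
        assert mc == pytest.approx(exact, abs=0.01)

    def test_too_large_enumeration_suggests_monte_carlo(self):
        big = np.full((4, 4), 40)
        with pytest.raises(AnalysisError, match="monte_carlo"):
            fisher_exact_rxc(big, max_tables=1e3)


class TestLikelihoodRatio:
    def test_nsclc_dcb_table(self):
        # 40/137 vs 1/14 durable-benefit counts
        res = lr_chisq_test([[40, 97], [1, 13]])
        assert res.p == pytest.approx(0.048, abs=2e-3)

    def test_equal_proportions_give_zero(self):
        res = lr_chisq_test([[10, 20], [5, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_statistic_matches_direct_summation(self, rng):
        for _ in range(20):
            t = rng.integers(1, 30, size=(2, 3))
            res = lr_chisq_test(t)
            e = np.outer(t.sum(1), t.sum(0)) / t.sum()
            g2 = 2 * sum(
                t[i, j] * np.log(t[i, j] / e[i, j])
                for i in range(2) for j in range(3) if t[i, j] > 0
            )
            assert res.statistic == pytest.approx(g2, abs=1e-9)


class TestRateComparison:
    def test_combined_melanoma_rates(self):
        ids = [f"P{i}" for i in range(86)]
        outcomes = pd.Series([True] * 27 + [False] * 18 + [True] * 9 + [False] * 32,
                             index=ids, dtype=object)
        strata = pd.Series(["hi_hi"] * 45 + ["lo_lo"] * 41, index=ids)
        res = response_rates_compare(outcomes, strata, ("hi_hi", "lo_lo"))
        assert res.set_index("stratum").loc["hi_hi", "rate"] == pytest.approx(0.60)
        assert res.set_index("stratum").loc["lo_lo", "rate"] == pytest.approx(0.2195, abs=1e-3)
        assert res["rate_ratio"].iloc[0] == pytest.approx(2.7, abs=0.05)
        assert res["p"].iloc[0] == pytest.approx(0.0004, abs=2e-4)

    def test_identical_strata_ratio_one(self):
        ids = [f"P{i}" for i in range(20)]
        outcomes = pd.Series([True, False] * 10, index=ids, dtype=object)
        strata = pd.Series((["x"] * 2 + ["y"] * 2) * 5, index=ids)
        res = response_rates_compare(outcomes, strata, ("x", "y"))
        assert res["rate_ratio"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] == 1.0

    def test_imvigor_rates(self):
        ids = [f"P{i}" for i in range(251)]
        outcomes = pd.Series([True] * 40 + [False] * 84 + [True] * 15 + [False] * 112,
                             index=ids, dtype=object)
        strata = pd.Series(["hi_hi"] * 124 + ["lo_lo"] * 127, index=ids)
        res = response_rates_compare(outcomes, strata, ("hi_hi", "lo_lo")).set_index("stratum")
        assert res.loc["hi_hi", "rate"] == pytest.approx(0.3226, abs=1e-3)
        assert res.loc["lo_lo", "rate"] == pytest.approx(0.1181, abs=1e-3)


class TestResponseScore:
    @pytest.mark.parametrize(
        "tmb,surrogate,pdl1,points,tier",
        [(30.0, "hi_hi", "IC2+", 4, "high"),
         (1.0, "lo_lo", "IC0", 0, "low"),
         (30.0, "mixed", "IC1", 2, "intermediate"),
         (1.0, "hi_hi", "IC2+", 2, "intermediate"),
         (30.0, "hi_hi", "IC0", 3, "high")],
    )
    def test_additive_rule(self, tmb, surrogate, pdl1, points, tier):
        s = compute_response_score(tmb, 10.0, surrogate, pdl1)
        assert s["points"] == points
        assert s["tier"] == tier

    def test_tie_at_median_is_low(self):
        assert compute_response_score(10.0, 10.0, "mixed", "IC0")["points"] == 0

    def test_na_component_excluded(self):
        with pytest.raises(AnalysisError):
            compute_response_score(np.nan, 10.0, "hi_hi", "IC2+")

    def test_cohort_scoring_excludes_incomplete(self, clinical):
        surrogate = pd.Series(
            ["hi_hi", "lo_lo", "mixed", "hi_hi", "hi_hi", "lo_lo"],
            index=clinical.data.index,
        )
        with pytest.warns(UserWarning, match="excluded"):
            scores = score_cohort(clinical.data, surrogate)
        # S4 lacks TMB, S5 lacks PD-L1
        assert set(scores.index) == {"S0", "S1", "S2", "S3"}
        assert scores["points"].between(0, 4).all()


class TestLogistic:
    def test_null_covariate(self):
        rng = np.random.default_rng(3)
        n = 500
        x = pd.DataFrame({"x": rng.normal(size=n)}, index=range(n))
        y = pd.Series(rng.random(n) < 0.4, index=range(n))
        fit = fit_logistic(y, x)
        assert abs(fit.loc["x", "coef"]) < 0.2
        assert fit.loc["x", "p"] > 0.05

    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        n = 2000
        beta = np.array([0.7, 0.35, 0.35])
        X = pd.DataFrame(rng.integers(0, 2, size=(n, 3)).astype(float),
                         columns=["tmb", "surr", "pdl1"], index=range(n))
        logit = -0.5 + X.to_numpy() @ beta
        y = pd.Series(rng.random(n) < 1 / (1 + np.exp(-logit)), index=range(n))
        fit = fit_logistic(y, X)
        np.testing.assert_allclose(fit["coef"], beta, atol=0.15)

    def test_single_class_rejected(self):
        x = pd.DataFrame({"x": np.arange(20.0)}, index=range(20))
        y = pd.Series([True] * 20, index=range(20))
        with pytest.raises(AnalysisError, match="single class"):
            fit_logistic(y, x)


class TestScoreWeights:
    @pytest.mark.parametrize(
        "betas,expected",
        [([0.70, 0.35, 0.36], [2, 1, 1]),
         ([0.5, 0.5], [1, 1]),
         ([0.9, 0.3, 0.3], [3, 1, 1])],
    )
    def test_rounding_rule(self, betas, expected):
        w = derive_score_weights(pd.Series(betas))
        assert w.tolist() == expected

    def test_zero_coefficient_rejected(self):
        with pytest.raises(AnalysisError):
            derive_score_weights(pd.Series([0.5, 0.0]))
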