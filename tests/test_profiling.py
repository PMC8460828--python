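"""Immune abundance scoring, ssGSEA, TCR diversity, differential abundance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from ninep21.errors import AnalysisError
from ninep21.io import ExpressionMatrix, GeneSetCollection
from ninep21.profiling import (
    ScoreMatrix,
    differential_abundance,
    marker_abundance_scores,
    ssgsea_scores,
    tcr_diversity,
)
from ninep21.screen import wilcoxon_rank_sum


def _expr(vals, genes=None, samples=None):
    vals = np.asarray(vals, dtype=float)
    genes = genes or [f"G{i}" for i in range(vals.shape[0])]
    samples = samples or [f"S{i}" for i in range(vals.shape[1])]
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))


class TestMarkerScores:
    def test_mean_of_two_markers(self):
        em = _expr([[2.0, 1.0], [4.0, 5.0]], genes=["A", "B"])
        gs = GeneSetCollection({"feat": ["A", "B"]})
        sm = marker_abundance_scores(em, gs)
        assert sm.scores.loc["feat", "S0"] == pytest.approx(3.0)

    def test_single_marker_is_identity(self):
        em = _expr([[2.5, 7.0], [0.0, 1.0]], genes=["A", "B"])
        sm = marker_abundance_scores(em, GeneSetCollection({"f": ["A"]}))
        assert sm.scores.loc["f"].tolist() == [2.5, 7.0]

    def test_matches_loop_oracle(self, rng):
        genes = [f"G{i}" for i in range(50)]
        em = _expr(rng.normal(size=(50, 12)), genes=genes)
        sets = {
            f"set{k}": list(rng.choice(genes, size=rng.integers(2, 9), replace=False))
            for k in range(5)
        }
        sm = marker_abundance_scores(em, GeneSetCollection(sets))
        for name, members in sets.items():
            for s in em.sample_ids:
                expect = np.mean([em.values.loc[g, s] for g in members])
                assert sm.scores.loc[name, s] == pytest.approx(expect, abs=1e-12)

    def test_monotone_in_marker_expression(self, rng):
        em = _expr(rng.normal(size=(5, 6)))
        gs = GeneSetCollection({"f": ["G0", "G1"]})
        base = marker_abundance_scores(em, gs).scores.loc["f", "S0"]
        em.values.loc["G0", "S0"] += 1.0
        assert marker_abundance_scores(em, gs).scores.loc["f", "S0"] > base

    def test_all_sets_absent_is_error(self, small_expr):
        with pytest.raises(AnalysisError):
            marker_abundance_scores(small_expr, GeneSetCollection({"f": ["NOPE"]}))


def ssgsea_oracle(values, in_set, alpha):
    """Direct running-sum evaluation of the weighted ECDF difference."""
    n = len(values)
    ranks = rankdata(values, method="average")
    order = np.argsort(-np.asarray(values), kind="stable")
    w_total = sum(ranks[i] ** alpha for i in order if in_set[i])
    n_out = n - sum(in_set)
    score, p_in, p_out = 0.0, 0.0, 0.0
    for i in order:
        if in_set[i]:
            p_in += ranks[i] ** alpha / w_total
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score


class TestSsgsea:
    def test_five_gene_toy_matches_running_sum_oracle(self):
        vals = [9.0, 4.0, 7.0, 1.0, 2.0]
        in_set = [True, False, True, False, False]  # top gene + one mid gene
        em = _expr(np.column_stack([vals, vals]))
        gs = GeneSetCollection({"s": ["G0", "G2"]})
        sm = ssgsea_scores(em, gs, alpha=0.25, normalize=False)
        expect = ssgsea_oracle(vals, in_set, 0.25)
        assert sm.scores.loc["s", "S0"] == pytest.approx(expect, abs=1e-12)

    def test_random_toys_match_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 15))
            vals = rng.normal(size=n)
            k = int(rng.integers(2, n - 1))
            members = rng.choice(n, size=k, replace=False)
            in_set = np.isin(np.arange(n), members)
            em = _expr(np.column_stack([vals, vals]))
            gs = GeneSetCollection({"s": [f"G{i}" for i in members]})
            got = ssgsea_scores(em, gs, normalize=False).scores.loc["s", "S0"]
            assert got == pytest.approx(ssgsea_oracle(vals, in_set, 0.25), abs=1e-10)

    def test_identical_rank_order_gives_identical_scores(self):
        a = [5.0, 3.0, 2.0, 1.0, 0.5]
        b = [50.0, 30.0, 20.0, 10.0, 5.0]  # same ordering
        em = _expr(np.column_stack([a, b]))
        gs = GeneSetCollection({"s": ["G0", "G3"]})
        sm = ssgsea_scores(em, gs, normalize=False)
        assert sm.scores.loc["s", "S0"] == pytest.approx(sm.scores.loc["s", "S1"])

    def test_shift_invariance_within_sample(self, rng):
        vals = rng.normal(size=8)
        em = _expr(np.column_stack([vals, vals + 100.0]))
        gs = GeneSetCollection({"s": ["G1", "G4", "G6"]})
        sm = ssgsea_scores(em, gs, normalize=False)
        assert sm.scores.loc["s", "S0"] == pytest.approx(sm.scores.loc["s", "S1"])

    def test_set_covering_all_genes_rejected(self, rng):
        em = _expr(rng.normal(size=(3, 2)))
        with pytest.raises(AnalysisError, match="complement"):
            ssgsea_scores(em, GeneSetCollection({"s": ["G0", "G1", "G2"]}))


class TestTcrDiversity:
    def test_single_clonotype(self):
        t = pd.DataFrame({"S1": [10, 0]}, index=["c1", "c2"])
        res = tcr_diversity(t)
        assert res.loc["S1", "richness"] == 1
        assert res.loc["S1", "shannon"] == 0.0

    def test_uniform_maximum(self):
        t = pd.DataFrame({"S1": [5, 5, 5, 5]}, index=list("abcd"))
        assert tcr_diversity(t).loc["S1", "shannon"] == pytest.approx(np.log(4))

    def test_direct_formula(self):
        t = pd.DataFrame({"S1": [2, 1, 1]}, index=list("abc"))
        assert tcr_diversity(t).loc["S1", "shannon"] == pytest.approx(1.0397, abs=1e-4)

    def test_bits_rescaling(self):
        t = pd.DataFrame({"S1": [1, 1, 1, 1]}, index=list("abcd"))
        assert tcr_diversity(t, base="bits").loc["S1", "shannon"] == pytest.approx(2.0)

    def test_entropy_bounds_random_tables(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 20))
            counts = rng.integers(1, 100, size=k)
            t = pd.DataFrame({"S": counts}, index=[f"c{i}" for i in range(k)])
            res = tcr_diversity(t)
            h, r = res.loc["S", "shannon"], res.loc["S", "richness"]
            assert 0.0 <= h <= np.log(r) + 1e-12

    def test_all_zero_sample_is_na_with_warning(self):
        t = pd.DataFrame({"S1": [0, 0], "S2": [1, 1]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="S1"):
            res = tcr_diversity(t)
        assert np.isnan(res.loc["S1", "shannon"])


class TestDifferentialAbundance:
    def _scores(self, a_vals, b_vals):
        vals = np.array(a_vals + b_vals, dtype=float).reshape(1, -1)
        cols = [f"A{i}" for i in range(len(a_vals))] + [f"B{i}" for i in range(len(b_vals))]
        sm = ScoreMatrix(pd.DataFrame(vals, index=["feat"], columns=cols), "marker-mean")
        groups = pd.Series(["a"] * len(a_vals) + ["b"] * len(b_vals), index=cols)
        return sm, groups

    def test_identical_groups_null(self):
        sm, groups = self._scores([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        res = differential_abundance(sm, groups, ("a", "b"))
        assert res["p"].iloc[0] >= 0.99
        assert res["log2_fc"].iloc[0] == 0.0

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(2.0, 0.5, 10).tolist()
        b = rng.normal(0.0, 0.5, 10).tolist()
        sm, groups = self._scores(a, b)
        res = differential_abundance(sm, groups, ("a", "b"))
        assert res["q"].iloc[0] < 0.05
        assert res["log2_fc"].iloc[0] > 1.0

    def test_exact_p_matches_rank_enumeration(self, rng):
        a = rng.normal(size=4)
        b = rng.normal(size=5)
        p = wilcoxon_rank_sum(a, b)
        # enumerate all 126 rank assignments of group a
        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        obs_u = ranks[:4].sum() - 4 * 5 / 2
        us = np.array([
            ranks[list(c)].sum() - 10.0
            for c in itertools.combinations(range(9), 4)
        ])
        expect = min(1.0, 2 * min((us <= obs_u).mean(), (us >= obs_u).mean()))
        assert p == pytest.approx(expect, abs=1e-12)

    def test_null_calibration_under_permutation(self, rng):
        """With permuted labels, about 5% of features reject at alpha=0.05."""
        n = 30
        cols = [f"S{i}" for i in range(n)]
        hits = 0
        trials = 200
        base_groups = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        for _ in range(trials):
            vals = rng.normal(size=(1, n))
            sm = ScoreMatrix(pd.DataFrame(vals, index=["f"], columns=cols), "x")
            groups = pd.Series(rng.permutation(base_groups), index=cols)
            res = differential_abundance(sm, groups, ("a", "b"))
            hits += res["p"].iloc[0] < 0.05
        # binomial 99.9% interval around 0.05 with 200 trials
        assert hits / trials < 0.05 + 3.3 * np.sqrt(0.05 * 0.95 / trials)

    def test_absent_group_rejected(self):
        sm, groups = self._scores([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        with pytest.raises(AnalysisError):
            differential_abundance(sm, groups, ("a", "zzz"))
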