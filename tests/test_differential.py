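"""Differential testing under H1/H2/H3, BH adjustment, confusion metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from siteocc.exceptions import DataError
from siteocc.differential import ConfusionSummary, adjust_bh, confusion
from siteocc.differential import test_h1 as h1_test
from siteocc.differential import test_h2 as h2_test
from siteocc.differential import test_h3 as h3_test
from siteocc.inference import FormAbundance
from siteocc.occupancy import OccupancyEstimate


def _occ(p, se, df=4.0, form="F", cond="A", site="S"):
    return OccupancyEstimate(site, form, cond, p, se, max(0, p - 2 * se),
                             min(1, p + 2 * se), df)


def _ab(mu, se, df=4.0, form="F", cond="A", site="S"):
    return FormAbundance(site, form, cond, mu, se, df, 3)


class TestH1:
    def test_identical_estimates_give_p_one(self):
        r = h1_test(_occ(0.2, 0.02, cond="A"), _occ(0.2, 0.02, cond="B"))
        assert r.delta_hat == 0.0 and r.p_value == pytest.approx(1.0)

    def test_worked_example_against_t_cdf(self):
        # delta=0.20, se=sqrt(2)*0.02, t=7.0711, Satterthwaite df=8
        r = h1_test(_occ(0.25, 0.02, df=4, cond="A"),
                    _occ(0.05, 0.02, df=4, cond="B"))
        t_expected = 0.20 / math.sqrt(2 * 0.02 ** 2)
        assert r.t_stat == pytest.approx(t_expected)
        assert r.df == pytest.approx(8.0)
        assert r.p_value == pytest.approx(2 * stats.t.sf(t_expected, 8), rel=1e-12)

    def test_symmetric_under_condition_swap(self):
        a, b = _occ(0.3, 0.03, df=5, cond="A"), _occ(0.22, 0.05, df=3, cond="B")
        r1, r2 = h1_test(a, b), h1_test(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.delta_hat == -r2.delta_hat
        assert {r1.direction, r2.direction} == {"increased", "decreased"}

    def test_zero_se_degenerate_cases(self):
        same = h1_test(_occ(0.2, 0.0), _occ(0.2, 0.0, cond="B"))
        assert same.p_value == 1.0
        diff = h1_test(_occ(0.3, 0.0), _occ(0.2, 0.0, cond="B"))
        assert diff.p_value == 0.0


class TestH2H3:
    def test_equal_abundances_give_p_one(self):
        assert h2_test(_ab(25.0, 0.1), _ab(25.0, 0.1, cond="B")).p_value == pytest.approx(1.0)

    def test_twofold_change_worked_example(self):
        r = h2_test(_ab(26.0, 0.1, df=4), _ab(25.0, 0.1, df=4, cond="B"))
        assert r.t_stat == pytest.approx(1.0 / math.sqrt(0.02))
        assert r.df == pytest.approx(8.0)
        assert r.p_value == pytest.approx(
            2 * stats.t.sf(1.0 / math.sqrt(0.02), 8), rel=1e-12)

    def test_h3_with_constant_reference_matches_h2_delta(self):
        a, b = _ab(26.0, 0.1), _ab(25.0, 0.1, cond="B")
        ref_a, ref_b = _ab(20.0, 0.0, df=4, form="ref"), _ab(20.0, 0.0, df=4, form="ref", cond="B")
        h2, h3 = h2_test(a, b), h3_test(a, b, ref_a, ref_b)
        assert h3.delta_hat == pytest.approx(h2.delta_hat)
        assert h3.p_value == pytest.approx(h2.p_value)

    def test_h3_cancels_global_run_shift_h2_does_not(self):
        shift = 1.5
        a, b = _ab(25.0 + shift, 0.1), _ab(25.0, 0.1, cond="B")
        ref_a = _ab(20.0 + shift, 0.1, form="ref")
        ref_b = _ab(20.0, 0.1, form="ref", cond="B")
        assert h2_test(a, b).delta_hat == pytest.approx(shift)
        assert h3_test(a, b, ref_a, ref_b).delta_hat == pytest.approx(0.0)

    def test_h3_missing_reference_names_condition(self):
        with pytest.raises(DataError, match="B"):
            h3_test(_ab(25.0, 0.1), _ab(25.0, 0.1, cond="B"),
                    _ab(20.0, 0.1, form="ref"), None)

    def test_null_rejection_rate_near_nominal(self):
        """With independent per-side variance estimates (the combiner's
        assumption) the H2 test reduces to Welch and holds its level."""
        rng = np.random.default_rng(7)
        n, reps, alpha = 4, 2000, 0.05
        rejections = 0
        for _ in range(reps):
            a, b = rng.normal(25, 0.2, n), rng.normal(25, 0.2, n)
            ab_a = _ab(a.mean(), a.std(ddof=1) / math.sqrt(n), df=n - 1)
            ab_b = _ab(b.mean(), b.std(ddof=1) / math.sqrt(n), df=n - 1, cond="B")
            rejections += h2_test(ab_a, ab_b).p_value < alpha
        # binomial 99% band around 0.05 at 2000 reps
        assert 0.038 <= rejections / reps <= 0.063


class TestAdjustBH:
    def test_single_test_unchanged(self):
        r = adjust_bh([h2_test(_ab(26.0, 0.1), _ab(25.0, 0.1, cond="B"))])
        assert r[0].p_adj == pytest.approx(r[0].p_value)

    def test_stepup_worked_example(self):
        results = []
        for i, (mu_a, se) in enumerate([(26, 0.1)] * 4):
            results.append(h2_test(_ab(float(mu_a), se, form=f"f{i}"),
                                   _ab(25.0, se, form=f"f{i}", cond="B")))
        # overwrite p-values with the textbook example via dataclasses.replace
        import dataclasses
        ps = [0.01, 0.02, 0.03, 0.04]
        results = [dataclasses.replace(r, p_value=p) for r, p in zip(results, ps)]
        adj = adjust_bh(results)
        assert [r.p_adj for r in adj] == pytest.approx([0.04] * 4)

    def test_all_ones_stay_one(self):
        import dataclasses
        base = h2_test(_ab(25.0, 0.1), _ab(25.0, 0.1, cond="B"))
        adj = adjust_bh([dataclasses.replace(base, p_value=1.0)] * 3)
        assert all(r.p_adj == 1.0 for r in adj)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_adjusted_at_least_raw_and_rank_monotone(self, ps):
        import dataclasses
        base = h2_test(_ab(25.0, 0.1), _ab(25.0, 0.1, cond="B"))
        adj = adjust_bh([dataclasses.replace(base, p_value=p) for p in ps])
        for r in adj:
            assert r.p_adj >= r.p_value - 1e-12 and r.p_adj <= 1.0
        order = np.argsort(ps)
        sorted_adj = np.array([adj[i].p_adj for i in order])
        assert (np.diff(sorted_adj) >= -1e-12).all()


class TestConfusion:
    def test_printed_count_ratios(self):
        # 28 TP / 6 FN / 5 FP / 56 TN  ->  0.824 / 0.918 / 0.848
        c = ConfusionSummary(28, 6, 5, 56)
        assert c.sensitivity == pytest.approx(0.824, abs=5e-4)
        assert c.specificity == pytest.approx(0.918, abs=5e-4)
        assert c.ppv == pytest.approx(0.848, abs=5e-4)
        # 13 FP / 49 TN  ->  specificity 0.790
        assert ConfusionSummary(28, 6, 13, 49).specificity == pytest.approx(0.790, abs=5e-4)

    def test_counts_from_adjusted_calls(self):
        import dataclasses
        base = h2_test(_ab(26.0, 0.1), _ab(25.0, 0.1, cond="B"))
        results = [dataclasses.replace(base, form_id=f, p_value=p)
                   for f, p in [("a", 0.001), ("b", 0.5), ("c", 0.002), ("d", 0.9)]]
        adj = adjust_bh(results)
        truth = {("S", "a"): True, ("S", "b"): True,
                 ("S", "c"): False, ("S", "d"): False}
        c = confusion(adj, truth, fdr_cutoff=0.05)
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 1, 1)

    def test_all_correct_gives_perfect_ratios(self):
        import dataclasses
        base = h2_test(_ab(26.0, 0.1), _ab(25.0, 0.1, cond="B"))
        results = adjust_bh([
            dataclasses.replace(base, form_id="hit", p_value=1e-8),
            dataclasses.replace(base, form_id="null", p_value=0.99)])
        c = confusion(results, {("S", "hit"): True, ("S", "null"): False})
        assert c.sensitivity == 1.0 and c.specificity == 1.0 and c.ppv == 1.0

    def test_unlabeled_form_raises(self):
        base = adjust_bh([h2_test(_ab(26.0, 0.1), _ab(25.0, 0.1, cond="B"))])
        with pytest.raises(DataError, match="truth"):
            confusion(base, {})
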