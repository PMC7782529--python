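"""Enrichment, prioritization, cohort t-tests, 2^-ddCt and correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metallonet.core_io import CohortTable, SummaryStats
from metallonet.downstream_stats import (
    ddct,
    hypergeom_enrich,
    interdependency_matrix,
    prioritize_candidates,
    summarize,
    ttest_from_summary,
)
from metallonet.synthetic_data import (
    REFERENCE_METAL_SUMMARIES,
    SynthesisConfig,
    gen_cohort,
)


def exhaustive_tail_p(M, K, n, k):
    """Enumeration oracle: P(overlap >= k) summed over all draw outcomes."""
    total = math.comb(M, n)
    return sum(math.comb(K, j) * math.comb(M - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


class TestEnrichment:
    def test_full_set_overlap_is_unique_most_extreme_table(self):
        universe = {f"G{i}" for i in range(100)}
        target = {f"G{i}" for i in range(10)}
        rows = hypergeom_enrich(target, {"S": target}, universe)
        assert rows[0].p == pytest.approx(1 / math.comb(100, 10), rel=1e-9)

    def test_zero_overlap_large_universe_p_near_one(self):
        universe = {f"G{i}" for i in range(500)}
        query = {f"G{i}" for i in range(490, 500)}
        small = {f"G{i}" for i in range(5)}
        rows = hypergeom_enrich(query, {"S": small}, universe)
        assert rows[0].p > 0.85

    def test_tail_matches_enumeration_oracle_for_small_urns(self):
        universe = {f"G{i}" for i in range(20)}
        for K, n, k in [(5, 5, 3), (8, 6, 4), (4, 10, 2), (10, 3, 1)]:
            gene_set = {f"G{i}" for i in range(K)}
            query = set(list(gene_set)[:k]) | {f"G{i}" for i in range(K, K + n - k)}
            assert len(query) == n and len(query & gene_set) == k
            rows = hypergeom_enrich(query, {"S": gene_set}, universe)
            assert rows[0].p == pytest.approx(exhaustive_tail_p(20, K, n, k),
                                              rel=1e-9)

    def test_exhaustive_oracle_value_m20_k5_n5_k3(self):
        # frozen from the enumeration oracle: 1126 / 15504
        assert exhaustive_tail_p(20, 5, 5, 3) == pytest.approx(1126 / 15504)

    def test_bh_q_values_monotone_in_rank(self):
        universe = {f"G{i}" for i in range(50)}
        sets = {f"S{j}": {f"G{i}" for i in range(j, j + 8)} for j in range(10)}
        query = {f"G{i}" for i in range(6)}
        rows = hypergeom_enrich(query, sets, universe)
        ordered = sorted(rows, key=lambda r: r.p)
        qs = [r.q for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(r.q >= r.p - 1e-12 for r in rows)

    def test_query_outside_universe_dropped(self):
        universe = {"A", "B"}
        rows = hypergeom_enrich({"A", "ZZZ"}, {"S": {"A"}}, universe)
        assert rows[0].query_size == 1


class TestPrioritizer:
    ANNOT = {
        "S1": {"T1", "T2", "C_GOOD"},
        "S2": {"T1", "C_GOOD", "C_HALF"},
        "S3": {"T2", "C_HALF"},
        "S4": {"C_LONE"},
    }

    def test_fully_co_annotated_candidate_ranks_first(self):
        ranked = prioritize_candidates({"T1", "T2"},
                                       {"C_GOOD", "C_HALF", "C_LONE"},
                                       self.ANNOT)
        assert ranked[0][0] == "C_GOOD"

    def test_disjoint_candidate_scores_zero(self):
        ranked = dict(prioritize_candidates({"T1"}, {"C_LONE"}, self.ANNOT))
        assert ranked["C_LONE"] == 0.0

    def test_hand_computed_jaccards(self):
        # training T1 has profile {S1, S2}; C_GOOD {S1, S2} -> J=1;
        # C_HALF {S2, S3} -> J=1/3; C_LONE {S4} -> J=0
        ranked = prioritize_candidates({"T1"}, {"C_GOOD", "C_HALF", "C_LONE"},
                                       self.ANNOT)
        assert ranked == [("C_GOOD", pytest.approx(1.0)),
                          ("C_HALF", pytest.approx(1 / 3)),
                          ("C_LONE", 0.0)]

    def test_unannotated_candidate_flagged_zero_not_error(self):
        ranked = dict(prioritize_candidates({"T1"}, {"GHOST"}, self.ANNOT))
        assert ranked["GHOST"] == 0.0

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            prioritize_candidates(set(), {"C_GOOD"}, self.ANNOT)


class TestSummaryTTest:
    def test_equal_means_give_t0_p1(self):
        s = SummaryStats(10.0, 2.0, 20)
        t, _, p = ttest_from_summary(s, s)
        assert t == 0.0 and p == 1.0

    def test_textbook_arithmetic(self):
        a = SummaryStats(10.0, 2.0, 16)
        b = SummaryStats(12.0, 2.0, 16)
        t, df, p = ttest_from_summary(a, b, variant="pooled")
        assert t == pytest.approx(-2.828, abs=1e-3)
        assert df == 30
        assert p == pytest.approx(0.0082, abs=2e-4)

    def test_published_serum_copper_row(self):
        a = REFERENCE_METAL_SUMMARIES["serum_copper"].control
        b = REFERENCE_METAL_SUMMARIES["serum_copper"].case
        t, _, p = ttest_from_summary(a, b)
        assert abs(t) == pytest.approx(5.80, abs=0.01)
        assert p < 0.001

    @pytest.mark.parametrize("variant,exact", [("pooled", True), ("welch", False)])
    def test_matches_raw_data_ttest(self, variant, exact):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.5, 2, 30)
        t_ref, p_ref = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
        t, _, p = ttest_from_summary(summarize(x), summarize(y), variant=variant)
        tol = dict(rel=1e-12) if exact else dict(rel=1e-9)
        assert t == pytest.approx(t_ref, **tol)
        assert p == pytest.approx(p_ref, **tol)

    def test_zero_variance_equal_means_convention(self):
        s = SummaryStats(5.0, 0.0, 4)
        _, _, p = ttest_from_summary(s, s)
        assert p == 1.0


def toy_ct_cohort():
    """4 + 4 subjects with hand-set Ct values: ddCt = -1.5."""
    rows = []
    for i in range(4):
        rows.append({"group": "control", "ct_ACTB": 18.0, "ct_B2M": 24.0 + 0.1 * i})
    for i in range(4):
        rows.append({"group": "PD", "ct_ACTB": 18.0, "ct_B2M": 22.5 + 0.1 * i})
    return CohortTable(pd.DataFrame(rows))


class TestDdct:
    def test_identical_groups_fold_one(self):
        rows = [{"group": g, "ct_ACTB": 18.0, "ct_B2M": 24.0 + 0.2 * i}
                for g in ("control", "PD") for i in range(4)]
        res = ddct(CohortTable(pd.DataFrame(rows)), "B2M")
        assert res.ddct == pytest.approx(0.0)
        assert res.fold_change == pytest.approx(1.0)

    def test_minus_one_cycle_doubles_expression(self):
        rows = [{"group": "control", "ct_ACTB": 18.0, "ct_B2M": 24.0 + 0.1 * i}
                for i in range(4)]
        rows += [{"group": "PD", "ct_ACTB": 18.0, "ct_B2M": 23.0 + 0.1 * i}
                 for i in range(4)]
        res = ddct(CohortTable(pd.DataFrame(rows)), "B2M")
        assert res.ddct == pytest.approx(-1.0)
        assert res.fold_change == pytest.approx(2.0)

    def test_hand_computed_toy_table(self):
        res = ddct(toy_ct_cohort(), "B2M")
        assert res.ddct == pytest.approx(-1.5)
        assert res.fold_change == pytest.approx(2 ** 1.5)
        assert res.p < 0.01

    def test_missing_ct_samples_excluded(self):
        df = toy_ct_cohort().data.copy()
        df.loc[0, "ct_B2M"] = np.nan
        res = ddct(CohortTable(df), "B2M")
        assert res.n_control == 3 and res.n_case == 4

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="ct_GHOST"):
            ddct(toy_ct_cohort(), "GHOST")


class TestInterdependency:
    def _cohort(self, x, y):
        df = pd.DataFrame({"group": ["control"] * len(x),
                           "serum_a": x, "serum_b": y})
        return CohortTable(df)

    def test_self_correlation_is_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        cells = interdependency_matrix(self._cohort(x, x), [("serum_a", "serum_b")])
        assert cells[0].r == pytest.approx(1.0)

    def test_negated_variable_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({"group": ["control"] * 4, "serum_a": x, "ct_X": 30 - x})
        cells = interdependency_matrix(CohortTable(df), [("serum_a", "ct_X")])
        assert cells[0].r == pytest.approx(-1.0)

    def test_copula_linked_pair_recovered(self):
        cfg = SynthesisConfig(seed=12, correlations=(
            ("serum_copper", "ct_B2M", -0.7),))
        cohort = gen_cohort(cfg)
        cells = interdependency_matrix(cohort, [("serum_copper", "ct_B2M")],
                                       group="control")
        assert cells[0].n == 87
        assert -0.85 < cells[0].r < -0.5

    def test_too_few_pairs_reported_not_computable(self):
        df = pd.DataFrame({"group": ["control"] * 4,
                           "serum_a": [1.0, 2.0, np.nan, np.nan],
                           "serum_b": [1.0, np.nan, 2.0, np.nan]})
        cells = interdependency_matrix(CohortTable(df), [("serum_a", "serum_b")])
        assert not cells[0].computable

    def test_spearman_available(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        cells = interdependency_matrix(self._cohort(x, x**3),
                                       [("serum_a", "serum_b")],
                                       method="spearman")
        assert cells[0].r == pytest.approx(1.0)
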