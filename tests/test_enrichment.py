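"""Hypergeometric tails, BH adjustment, collection enrichment, calibration.

The tail engine is checked against an independent brute-force oracle that
enumerates every possible draw of the query from a small universe.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathcrosstalk.enrichment import (
    EnrichmentError,
    UniverseSpec,
    bh_adjust,
    calibrate_universe,
    enrich_collection,
    fit_effective_m,
    hypergeom_tail,
    log10_hypergeom_tail,
    select_top,
)
from pathcrosstalk.geneset_io import GeneSet, GeneSetCollection, make_query


def enumeration_tail(k: int, K: int, n: int, N: int) -> float:
    """Brute-force oracle: enumerate every C(N, n) query draw and count the
    fraction overlapping the first K universe elements in >= k genes."""
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if sum(1 for g in draw if g < K) >= k
    )
    return hits / math.comb(N, n)


class TestHypergeomTail:
    def test_zero_overlap_tail_is_one(self):
        assert hypergeom_tail(0, 5, 3, 10) == 1.0
        assert hypergeom_tail(0, 0, 0, 1) == 1.0

    def test_small_case_exact_third(self):
        # enumeration over all C(10,3)=120 draws gives 40 with >=2 hits
        assert hypergeom_tail(2, 4, 3, 10) == pytest.approx(1 / 3, rel=1e-12)
        assert enumeration_tail(2, 4, 3, 10) == pytest.approx(1 / 3, rel=1e-12)

    def test_matches_enumeration_on_sample_of_small_universes(self):
        for N in (5, 8, 11):
            for n in range(N + 1):
                for K in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_tail(k, K, n, N) == pytest.approx(
                            enumeration_tail(k, K, n, N), rel=1e-10, abs=1e-12
                        )

    def test_parameter_order_violations_rejected(self):
        with pytest.raises(EnrichmentError):
            hypergeom_tail(3, 2, 5, 10)  # k > K
        with pytest.raises(EnrichmentError):
            hypergeom_tail(1, 11, 5, 10)  # K > N
        with pytest.raises(EnrichmentError):
            hypergeom_tail(1, 5, 11, 10)  # n > N

    @given(
        st.integers(min_value=2, max_value=60),
        st.integers(min_value=1, max_value=60),
        st.integers(min_value=1, max_value=60),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_in_unit_interval_and_decreasing_in_k(self, N, K, n):
        K, n = min(K, N), min(n, N)
        tails = [hypergeom_tail(k, K, n, N) for k in range(min(K, n) + 1)]
        assert all(0.0 < t <= 1.0 for t in tails)
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        # strictly decreasing once the overlap is no longer forced by
        # pigeonhole (tail == 1 exactly for k <= K + n - N)
        free = tails[max(0, K + n - N):]
        assert all(a > b for a, b in zip(free, free[1:]))

    def test_log_tail_tracks_linear_tail(self):
        assert log10_hypergeom_tail(30, 123, 659, 45_956) == pytest.approx(
            np.log10(hypergeom_tail(30, 123, 659, 45_956)), abs=1e-9
        )

    def test_extreme_tail_stays_finite_in_log_space(self):
        # far below the double underflow limit: only the log form is usable
        assert log10_hypergeom_tail(900, 1000, 1000, 40_000) < -300


class TestBhAdjust:
    def test_single_test_unchanged(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.04], m=3) == pytest.approx([0.03, 0.03, 0.04])

    def test_output_order_matches_input_order(self):
        q = bh_adjust([0.04, 0.01, 0.02], m=3)
        assert q == pytest.approx([0.04, 0.03, 0.03])

    def test_external_m_scales_q(self):
        # retaining the top rows of a larger screen: q uses the full m
        assert bh_adjust([0.001], m=100) == pytest.approx([0.1])

    def test_m_below_length_rejected(self):
        with pytest.raises(EnrichmentError):
            bh_adjust([0.1, 0.2], m=1)

    def test_matches_statsmodels_for_full_screens(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(p.tolist()) == pytest.approx(expected.tolist())

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_q_at_least_p_at_most_one_and_monotone(self, p):
        q = bh_adjust(p)
        assert all(qi >= pi - 1e-15 and qi <= 1.0 for pi, qi in zip(p, q))
        order = np.argsort(p, kind="stable")
        q_sorted = np.asarray(q)[order]
        assert all(a <= b + 1e-15 for a, b in zip(q_sorted, q_sorted[1:]))


def toy_collection():
    return GeneSetCollection(
        "toy",
        [
            GeneSet("S1", "", frozenset({"A", "B", "C", "D"})),
            GeneSet("S2", "", frozenset({"E", "F"})),
            GeneSet("S3", "", frozenset({"A", "E", "G"})),
        ],
    )


class TestEnrichCollection:
    def test_disjoint_query_all_null(self):
        q = make_query(["X", "Y", "Z"])
        table = enrich_collection(q, toy_collection(), UniverseSpec(N=100))
        assert all(r.k == 0 and r.p_value == 1.0 for r in table)

    def test_row_count_and_overlap_conservation(self):
        q = make_query(["A", "E", "X"])
        coll = toy_collection()
        table = enrich_collection(q, coll, UniverseSpec(N=50))
        assert len(table) == len(coll)
        total = sum(len(q.as_set() & s.members) for s in coll)
        assert sum(r.k for r in table) == total
        assert [r.rank for r in table] == [1, 2, 3]
        assert all(r.p_value <= r.q_value <= 1.0 for r in table)

    def test_sorted_by_p_then_name(self):
        q = make_query(["A", "B", "E", "F"])
        table = enrich_collection(q, toy_collection(), UniverseSpec(N=1000))
        ps = [r.p_value for r in table]
        assert ps == sorted(ps)

    def test_planted_enriched_set_ranks_first(self):
        rng = np.random.default_rng(11)
        universe = [f"G{i}" for i in range(2000)]
        planted = frozenset(universe[:60])
        sets = [GeneSet("PLANTED", "", planted)] + [
            GeneSet(f"BG{i}", "", frozenset(rng.choice(universe, 60, replace=False)))
            for i in range(9)
        ]
        # query: half from the planted set (5x the uniform rate), half uniform
        query = make_query(
            list(rng.choice(sorted(planted), 30, replace=False))
            + list(rng.choice(universe[60:], 70, replace=False))
        )
        table = enrich_collection(
            query, GeneSetCollection("sim", sets), UniverseSpec(N=2000)
        )
        assert table[0].set_name == "PLANTED"

    def test_empty_collection_rejected(self):
        with pytest.raises(EnrichmentError):
            enrich_collection(make_query(["A"]), GeneSetCollection("e", []), UniverseSpec(N=10))


class TestSelectTop:
    def test_truncates_to_top_k(self):
        from pathcrosstalk.enrichment import EnrichmentRow, EnrichmentTable

        rows = [
            EnrichmentRow(f"S{i:02d}", 10, 5, 100, 1000, p_value=1e-6 * (i + 1),
                          q_value=1e-4, rank=i + 1)
            for i in range(60)
        ]
        out = select_top(EnrichmentTable(rows=rows, m=60), top_k=50, fdr_threshold=0.05)
        assert len(out) == 50
        assert out.rows[0].set_name == "S00"

    def test_fewer_passing_than_top_k(self):
        from pathcrosstalk.enrichment import EnrichmentRow, EnrichmentTable

        rows = [
            EnrichmentRow("A", 10, 5, 100, 1000, 1e-6, q_value=0.001, rank=1),
            EnrichmentRow("B", 10, 4, 100, 1000, 1e-4, q_value=0.01, rank=2),
            EnrichmentRow("C", 10, 3, 100, 1000, 1e-2, q_value=0.04, rank=3),
            EnrichmentRow("D", 10, 1, 100, 1000, 0.5, q_value=0.6, rank=4),
        ]
        out = select_top(EnrichmentTable(rows=rows, m=4), top_k=50, fdr_threshold=0.05)
        assert out.set_names() == ["A", "B", "C"]

    def test_ties_at_cut_resolved_by_name(self):
        q = make_query(["A", "B"])
        coll = GeneSetCollection(
            "ties",
            [
                GeneSet("ZED", "", frozenset({"A", "X"})),
                GeneSet("ALPHA", "", frozenset({"B", "Y"})),
            ],
        )
        table = enrich_collection(q, coll, UniverseSpec(N=100))
        out = select_top(table, top_k=1, fdr_threshold=1.0)
        assert out.set_names() == ["ALPHA"]  # equal p; name breaks the tie


class TestCalibrateUniverse:
    def test_self_consistency_recovers_planted_universe(self):
        N_true = 20_000
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(10):
            K = int(rng.integers(100, 1500))
            k = int(rng.integers(10, 60))
            rows.append((K, k, hypergeom_tail(k, K, 500, N_true)))
        result = calibrate_universe(rows, n=500, search_range=(10_000, 30_000))
        assert result.universe.N == N_true
        assert not result.poor_fit
        assert all(abs(r) < 1e-6 for r in result.residuals)

    def test_single_row_flagged_ambiguous(self):
        p = hypergeom_tail(20, 300, 500, 20_000)
        result = calibrate_universe([(300, 20, p)], n=500, search_range=(15_000, 25_000))
        assert result.ambiguous
        lo, hi = result.candidates
        assert lo < hi

    def test_requires_a_row(self):
        with pytest.raises(EnrichmentError):
            calibrate_universe([], n=100)


class TestFitEffectiveM:
    def test_recovers_known_m(self):
        m_true = 500
        ps = [1e-8, 3e-7, 2e-6, 9e-6]
        ranks = [1, 2, 3, 4]
        qs = [m_true * p / r for p, r in zip(ps, ranks)]
        assert fit_effective_m(ps, qs, ranks) == m_true
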