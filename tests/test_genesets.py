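"""Gene-set library construction: merging, enrichment, FDR, redundancy, size."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigbridge.genesets import (
    GeneSetLibrary,
    TermRecord,
    bh_adjust,
    build_library,
    hypergeometric_enrichment,
    kappa_similarity,
    merge_terms,
    redundancy_filter,
    size_filter,
)

UNIVERSE = [f"g{i}" for i in range(100)]


def term(tid, genes, **kw):
    return TermRecord(term_id=tid, genes=frozenset(genes), **kw)


class TestMergeTerms:
    def test_union_of_overlapping_terms(self):
        lib = merge_terms([term("A", ["x", "y"]), term("B", ["y", "z"])])
        assert lib.n_unique_genes == 3

    def test_duplicate_term_kept_once(self):
        lib = merge_terms([term("A", ["x"]), term("A", ["x"])])
        assert len(lib) == 1

    def test_empty_input_and_empty_term_rejected(self):
        with pytest.raises(ValueError):
            merge_terms([])
        with pytest.raises(ValueError, match="T9"):
            merge_terms([term("T9", [])])

    def test_unique_count_bounded_by_sum_of_sizes(self):
        # sizes follow the 16-term signaling table; union <= the column sum 859
        sizes = [65, 13, 14, 48, 55, 7, 43, 105, 18, 38, 10, 87, 20, 157, 167, 12]
        assert sum(sizes) == 859
        rng = np.random.default_rng(0)
        pool = [f"g{i}" for i in range(700)]
        terms = [
            term(f"D{i+1}", rng.choice(pool, size=s, replace=False)) for i, s in enumerate(sizes)
        ]
        lib = merge_terms(terms)
        assert lib.n_unique_genes <= 859


class TestHypergeometric:
    def test_zero_overlap_gives_p_one(self):
        lib = merge_terms([term("T", ["a", "b"])], universe=["a", "b", "c", "d"])
        t = hypergeometric_enrichment(["c", "d"], lib)
        assert t.loc[0, "p"] == 1.0

    def test_full_overlap_matches_exact_tail(self):
        # N=20, K=5, n=5, k=5 -> p = 1/C(20,5)
        lib = merge_terms([term("T", UNIVERSE[:5])], universe=UNIVERSE[:20])
        t = hypergeometric_enrichment(UNIVERSE[:5], lib)
        assert t.loc[0, "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_partial_overlap_matches_hand_computed_tail(self):
        # N=10, K=4, n=5, k=3 -> (C(4,3)C(6,2)+C(4,4)C(6,1))/C(10,5) = 66/252
        lib = merge_terms([term("T", UNIVERSE[:4])], universe=UNIVERSE[:10])
        query = UNIVERSE[:3] + UNIVERSE[4:6]
        t = hypergeometric_enrichment(query, lib)
        assert t.loc[0, "p"] == pytest.approx(66 / 252, rel=1e-9)

    def test_empty_query_after_intersection_rejected(self):
        lib = merge_terms([term("T", ["a"])], universe=["a", "b"])
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["zzz"], lib)

    @given(st.integers(5, 30), st.data())
    @settings(max_examples=30, deadline=None)
    def test_pmf_sums_to_one_over_support(self, N, data):
        from scipy.stats import hypergeom

        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        ks = np.arange(max(0, n + K - N), min(K, n) + 1)
        assert hypergeom.pmf(ks, N, K, n).sum() == pytest.approx(1.0, abs=1e-12)


def step_up_reference(p):
    """Independent BH step-up implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_independent_step_up_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 30))
            np.testing.assert_allclose(bh_adjust(p), step_up_reference(p), atol=1e-12)


class TestRedundancyFilter:
    def test_identical_terms_collapse(self):
        lib = merge_terms([term("A", UNIVERSE[:10]), term("B", UNIVERSE[:10])], universe=UNIVERSE)
        out, dropped = redundancy_filter(lib)
        assert len(out) == 1 and len(dropped) == 1

    def test_disjoint_terms_survive(self):
        lib = merge_terms([term("A", UNIVERSE[:20]), term("B", UNIVERSE[20:40])], universe=UNIVERSE)
        out, dropped = redundancy_filter(lib)
        assert len(out) == 2 and not dropped

    def test_kappa_against_brute_force_oracle(self):
        # |A|=|B|=20, |A&B|=15 over a 100-gene universe
        A = frozenset(UNIVERSE[:20])
        B = frozenset(UNIVERSE[5:25])
        a, b, c = 15, 5, 5
        d = 100 - 25
        po = (a + d) / 100
        pe = ((a + b) * (a + c) + (c + d) * (b + d)) / 100**2
        expected = (po - pe) / (1 - pe)
        assert kappa_similarity(A, B, 100) == pytest.approx(expected, rel=1e-12)
        lib = merge_terms([term("A", A), term("B", B)], universe=UNIVERSE)
        out, dropped = redundancy_filter(lib, cutoff=0.5)
        assert (len(out) == 1) == (expected > 0.5)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        terms = [term(f"T{i}", rng.choice(UNIVERSE, size=15, replace=False)) for i in range(12)]
        lib = merge_terms(terms, universe=UNIVERSE)
        once, _ = redundancy_filter(lib)
        twice, dropped = redundancy_filter(once)
        assert once.term_ids == twice.term_ids and not dropped

    def test_bad_cutoff_rejected(self):
        lib = merge_terms([term("A", ["g1"])], universe=UNIVERSE)
        with pytest.raises(ValueError):
            redundancy_filter(lib, cutoff=1.5)


class TestSizeFilter:
    def test_inclusive_boundary_at_ten(self):
        lib = merge_terms(
            [term("nine", UNIVERSE[:9]), term("ten", UNIVERSE[:10])], universe=UNIVERSE
        )
        out = size_filter(lib, min_size=10)
        assert out.term_ids == ["ten"]

    def test_empty_result_allowed(self):
        lib = merge_terms([term("small", UNIVERSE[:3])], universe=UNIVERSE)
        assert len(size_filter(lib, min_size=10)) == 0


def test_build_library_pipeline_order():
    """enrich -> FDR filter -> redundancy -> size reproduces the narrative order."""
    rng = np.random.default_rng(3)
    enriched = term("hit", UNIVERSE[:15])
    shadow = term("hit_copy", UNIVERSE[:15] + UNIVERSE[15:16])  # redundant with `hit`
    tiny = term("tiny_hit", UNIVERSE[:5])  # enriched but below min size
    noise = [term(f"bg{i}", rng.choice(UNIVERSE, 15, replace=False)) for i in range(5)]
    lib, table = build_library(
        [enriched, shadow, tiny] + noise, query=UNIVERSE[:15], universe=UNIVERSE
    )
    assert table is not None
    assert "hit" in lib.term_ids
    assert "hit_copy" not in lib.term_ids  # dropped by redundancy
    assert "tiny_hit" not in lib.term_ids  # dropped by size filter
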