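import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from hmannot.enrichment import (
    EnrichmentFilters,
    cluster_terms,
    enrich,
    enrichment_factor,
    export_network,
    hypergeom_pvalue,
    kappa_matrix,
    kappa_similarity,
    select_representatives,
)
from hmannot.io_formats import TermDatabase


def db(**terms):
    """TermDatabase from term_id=members keyword pairs (all GO_BP)."""
    return TermDatabase(terms={tid: (tid, "GO_BP", frozenset(members)) for tid, members in terms.items()})


def exhaustive_upper_tail(k, m, K, N):
    """P(X >= k) by enumerating all C(N, m) draws."""
    population = list(range(N))
    annotated = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(population, m):
        total += 1
        if len(annotated & set(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeomPvalue:
    @pytest.mark.parametrize(
        "k,m,K,N,expected",
        [
            (4, 5, 4, 10, 6 / 252),
            (2, 5, 4, 10, 186 / 252),
            (0, 5, 4, 10, 1.0),
            (3, 4, 5, 20, 155 / 4845),
        ],
    )
    def test_known_tail_sums(self, k, m, K, N, expected):
        assert hypergeom_pvalue(k, m, K, N) == pytest.approx(expected, rel=1e-12)

    def test_matches_exhaustive_enumeration(self, rng):
        """Upper tail equals brute-force enumeration over all draws, N <= 12."""
        for _ in range(60):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(1, N + 1))
            m = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(m, K) + 1))
            assert hypergeom_pvalue(k, m, K, N) == pytest.approx(
                exhaustive_upper_tail(k, m, K, N), rel=1e-10
            )

    def test_pmf_sums_to_one(self, rng):
        for _ in range(20):
            N = int(rng.integers(2, 200))
            K = int(rng.integers(1, N + 1))
            m = int(rng.integers(1, N + 1))
            kmax = min(m, K)
            total = sum(
                hypergeom_pvalue(k, m, K, N) - (hypergeom_pvalue(k + 1, m, K, N) if k < kmax else 0.0)
                for k in range(0, kmax + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(5, 4, 10, 20)
        with pytest.raises(ValueError):
            hypergeom_pvalue(1, 25, 10, 20)


class TestEnrichmentFactor:
    def test_direct_arithmetic(self):
        assert enrichment_factor(4, 5, 4, 10) == pytest.approx(2.0)
        assert enrichment_factor(0, 5, 4, 10) == 0.0
        assert enrichment_factor(2, 4, 5, 10) == pytest.approx(1.0)

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            enrichment_factor(0, 0, 4, 10)


class TestEnrich:
    BACKGROUND = [f"At{i}" for i in range(20)]

    def test_filters_applied_as_specified(self):
        terms = db(T1=["At0", "At1", "At2", "At3", "At4"])
        records = enrich(["At0", "At1", "At2", "At19"], terms, self.BACKGROUND)
        (rec,) = records
        assert rec.k == 3 and rec.K == 5 and rec.m == 4 and rec.N == 20
        assert rec.enrichment_factor == pytest.approx(3.0)
        assert rec.p_value == pytest.approx(155 / 4845)
        assert not rec.passed_filters  # p = 0.032 >= 0.01

    def test_overlap_below_three_fails_filters(self):
        terms = db(T1=["At0", "At1", "At2", "At3"])
        records = enrich(["At0", "At1", "At18", "At19"], terms, self.BACKGROUND)
        (rec,) = records
        assert rec.k == 2
        assert not rec.passed_filters

    def test_zero_overlap_terms_not_reported(self):
        terms = db(T1=["At5"], T2=["At0"])
        records = enrich(["At0"], terms, self.BACKGROUND)
        assert [r.term_id for r in records] == ["T2"]

    def test_genes_outside_background_dropped(self):
        terms = db(T1=["At0", "At1", "At2"])
        records = enrich(["At0", "At1", "ghost"], terms, self.BACKGROUND)
        assert records[0].m == 2

    def test_disjoint_list_is_error(self):
        with pytest.raises(ValueError):
            enrich(["ghost"], db(T1=["At0"]), self.BACKGROUND)

    def test_bh_fdr_within_category(self):
        terms = TermDatabase(
            terms={
                "T1": ("a", "GO_BP", frozenset({"At0", "At1", "At2"})),
                "T2": ("b", "GO_BP", frozenset({"At0", "At1", "At2", "At3", "At4", "At5"})),
                "K1": ("c", "KEGG", frozenset({"At0", "At1", "At2"})),
            }
        )
        records = enrich(["At0", "At1", "At2"], terms, self.BACKGROUND)
        by_id = {r.term_id: r for r in records}
        # KEGG category has a single test: FDR equals its raw p
        assert by_id["K1"].fdr == pytest.approx(by_id["K1"].p_value)
        # within GO_BP, BH: sorted p, q_i = min over j>=i of p_j * n / j
        ps = sorted([by_id["T1"].p_value, by_id["T2"].p_value])
        qs = [min(ps[0] * 2 / 1, ps[1] * 2 / 2), ps[1] * 2 / 2]
        got = sorted([by_id["T1"].fdr, by_id["T2"].fdr])
        assert got == pytest.approx(sorted(qs))


class TestKappaSimilarity:
    def test_identical_sets(self):
        assert kappa_similarity({"g1", "g2"}, {"g1", "g2"}, 10) == 1.0

    def test_complementary_halves(self):
        A = {f"g{i}" for i in range(5)}
        B = {f"g{i}" for i in range(5, 10)}
        assert kappa_similarity(A, B, 10) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        got = kappa_similarity({"g1", "g2", "g3"}, {"g2", "g3", "g4"}, 10)
        assert got == pytest.approx(0.22 / 0.42)

    def test_member_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            kappa_similarity({"g1"}, {"g2"}, ["g1"])

    def test_degenerate_full_agreement(self):
        universe = ["g1", "g2"]
        assert kappa_similarity(set(universe), set(universe), universe) == 1.0
        assert kappa_similarity(set(), set(), 5) == 1.0

    def test_matches_cohen_kappa_on_random_pairs(self, rng):
        """Set-based formula equals Cohen's kappa of the indicator vectors."""
        checked = 0
        for _ in range(100):
            N = int(rng.integers(4, 40))
            A = {int(i) for i in rng.choice(N, size=int(rng.integers(1, N)), replace=False)}
            B = {int(i) for i in rng.choice(N, size=int(rng.integers(1, N)), replace=False)}
            va = np.array([i in A for i in range(N)], dtype=int)
            vb = np.array([i in B for i in range(N)], dtype=int)
            if va.min() == va.max() or vb.min() == vb.max():
                continue  # sklearn's kappa is undefined for constant labelings
            expected = cohen_kappa_score(va, vb)
            assert kappa_similarity(A, B, N) == pytest.approx(expected, abs=1e-12)
            checked += 1
        assert checked > 50

    def test_symmetry(self, rng):
        for _ in range(20):
            N = int(rng.integers(3, 30))
            A = {int(i) for i in rng.choice(N, size=int(rng.integers(0, N)), replace=False)}
            B = {int(i) for i in rng.choice(N, size=int(rng.integers(0, N)), replace=False)}
            assert kappa_similarity(A, B, N) == kappa_similarity(B, A, N)


def _passing_records(terms, gene_list, background):
    records = enrich(gene_list, terms, background, EnrichmentFilters(min_overlap=1, min_factor=0, max_p=1.1))
    return records


class TestClusterTerms:
    BACKGROUND = [f"g{i}" for i in range(100)]

    def test_identical_membership_terms_cluster_together(self):
        members = ["g0", "g1", "g2", "g3"]
        terms = db(T1=members, T2=members, T3=["g50", "g51", "g52", "g53"])
        records = _passing_records(terms, members + ["g50", "g51", "g52", "g53"], self.BACKGROUND)
        clustered = cluster_terms(records, terms, self.BACKGROUND)
        by_id = {r.term_id: r.cluster_id for r in clustered}
        assert by_id["T1"] == by_id["T2"]
        assert by_id["T3"] != by_id["T1"]

    def test_disjoint_terms_stay_separate(self):
        terms = db(T1=["g0", "g1"], T2=["g10", "g11"])
        records = _passing_records(terms, ["g0", "g1", "g10", "g11"], self.BACKGROUND)
        clustered = cluster_terms(records, terms, self.BACKGROUND)
        assert clustered[0].cluster_id != clustered[1].cluster_id

    def test_invariant_to_input_order(self, rng):
        terms = db(
            **{
                f"T{i}": [f"g{int(j)}" for j in rng.choice(40, size=8, replace=False)]
                for i in range(8)
            }
        )
        gene_list = [f"g{i}" for i in range(40)]
        records = _passing_records(terms, gene_list, self.BACKGROUND)
        base = {r.term_id: r.cluster_id for r in cluster_terms(records, terms, self.BACKGROUND)}
        for _ in range(5):
            perm = [records[i] for i in rng.permutation(len(records))]
            got = {r.term_id: r.cluster_id for r in cluster_terms(perm, terms, self.BACKGROUND)}
            assert got == base


class TestRepresentativesAndNetwork:
    def _clustered(self, n_clusters, terms_per_cluster):
        """Synthetic pre-clustered records with distinct p-values."""
        from hmannot.enrichment import EnrichmentRecord

        records = []
        p = 1e-30
        for c in range(1, n_clusters + 1):
            for t in range(terms_per_cluster):
                records.append(
                    EnrichmentRecord(
                        term_id=f"T{c:02d}_{t:02d}",
                        category="GO_BP",
                        name="",
                        k=3,
                        m=10,
                        K=10,
                        N=100,
                        enrichment_factor=3.0,
                        p_value=p,
                        passed_filters=True,
                        cluster_id=c,
                    )
                )
                p *= 1.7
        return records

    def test_cluster_cap(self):
        records = select_representatives(self._clustered(25, 1))
        assert sum(r.is_representative for r in records) == 20

    def test_terms_per_cluster_cap(self):
        records = select_representatives(self._clustered(1, 12))
        assert sum(r.is_representative for r in records) == 10

    def test_small_input_all_flagged(self):
        records = select_representatives(self._clustered(3, 2))
        assert all(r.is_representative for r in records)

    def test_network_edges_strictly_above_threshold(self):
        records = select_representatives(self._clustered(3, 1))
        ids = [r.term_id for r in records]
        kappa = {
            (ids[0], ids[1]): 0.5,
            (ids[0], ids[2]): 0.3,  # boundary: excluded
            (ids[1], ids[2]): -0.2,
        }
        nodes, edges = export_network(records, kappa)
        assert len(nodes) == 3
        assert [(e["source"], e["target"], e["weight"]) for e in edges] == [(ids[0], ids[1], 0.5)]
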