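"""Over-representation analysis with kappa-similarity term clustering.

The test is the upper-tail hypergeometric (one-sided Fisher): for a gene
list of size m drawn from a background of N genes, a term with K annotated
genes and k of them in the list scores P(X >= k). Filters follow the
Metascape convention: overlap k >= 3, enrichment factor (k/m)/(K/N) > 1.5,
p < 0.01, with Benjamini-Hochberg FDR computed per ontology category over
all tested terms. Passing terms are clustered by Cohen's kappa over their
binary gene-membership vectors (average linkage, tree cut at kappa 0.3),
up to 10 representative terms from each of the 20 best clusters are
flagged, and the representatives export as a node/edge network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from hmannot.io_formats import TermDatabase

__all__ = [
    "EnrichmentRecord",
    "EnrichmentFilters",
    "hypergeom_pvalue",
    "enrichment_factor",
    "enrich",
    "kappa_similarity",
    "cluster_terms",
    "select_representatives",
    "export_network",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentFilters:
    """Metascape-style reporting filters."""

    min_overlap: int = 3
    min_factor: float = 1.5
    max_p: float = 0.01


@dataclass
class EnrichmentRecord:
    term_id: str
    category: str
    name: str
    k: int  # overlap with the gene list
    m: int  # gene-list size (within background)
    K: int  # term size (within background)
    N: int  # background size
    enrichment_factor: float
    p_value: float
    fdr: float = float("nan")
    passed_filters: bool = False
    cluster_id: int | None = None
    is_representative: bool = False
    members_in_list: frozenset[str] = frozenset()


def _check_counts(k: int, m: int, K: int, N: int) -> None:
    if not (0 <= k <= min(m, K)):
        raise ValueError(f"inconsistent counts: k={k} must satisfy 0 <= k <= min(m={m}, K={K})")
    if m > N or K > N:
        raise ValueError(f"inconsistent counts: m={m} and K={K} must be <= N={N}")


def hypergeom_pvalue(k: int, m: int, K: int, N: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, m)."""
    _check_counts(k, m, K, N)
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, m))


def enrichment_factor(k: int, m: int, K: int, N: int) -> float:
    """Observed over expected overlap fraction: (k/m) / (K/N)."""
    _check_counts(k, m, K, N)
    if m == 0 or K == 0:
        raise ValueError("enrichment factor undefined for empty list or term")
    return (k / m) / (K / N)


def enrich(
    gene_list: Iterable[str],
    terms: TermDatabase,
    background: Iterable[str],
    filters: EnrichmentFilters = EnrichmentFilters(),
) -> list[EnrichmentRecord]:
    """Test every term with non-zero overlap against the gene list.

    Genes outside the background are dropped with a warning. BH FDR is
    computed within each ontology category across all tested (k >= 1)
    terms. Records return sorted by p-value, then term id.
    """
    bg = frozenset(background)
    genes = set(gene_list)
    outside = genes - bg
    if outside:
        log.warning("%d gene(s) outside the background dropped from the list", len(outside))
        genes &= bg
    if not genes:
        raise ValueError("gene list has no overlap with the background")
    N, m = len(bg), len(genes)

    records: list[EnrichmentRecord] = []
    for term_id, (name, category, members) in terms.terms.items():
        members_bg = members & bg
        K = len(members_bg)
        if K == 0:
            continue
        overlap = members_bg & genes
        k = len(overlap)
        if k == 0:
            continue
        p = hypergeom_pvalue(k, m, K, N)
        factor = enrichment_factor(k, m, K, N)
        records.append(
            EnrichmentRecord(
                term_id=term_id,
                category=category,
                name=name,
                k=k,
                m=m,
                K=K,
                N=N,
                enrichment_factor=factor,
                p_value=p,
                passed_filters=(k >= filters.min_overlap and factor > filters.min_factor and p < filters.max_p),
                members_in_list=frozenset(overlap),
            )
        )

    # BH step-up within each category
    for category in {r.category for r in records}:
        idx = [i for i, r in enumerate(records) if r.category == category]
        pvals = [records[i].p_value for i in idx]
        _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
        for i, q in zip(idx, fdrs):
            records[i] = replace(records[i], fdr=float(q))

    records.sort(key=lambda r: (r.p_value, r.term_id))
    return records


def kappa_similarity(
    members_a: Iterable[str],
    members_b: Iterable[str],
    universe: int | Iterable[str],
) -> float:
    """Cohen's kappa between two terms' binary gene-membership vectors.

    With a = |A∩B|, b = |A\\B|, c = |B\\A|, d = N - |A∪B|:
    po = (a+d)/N, pe = ((a+b)(a+c) + (c+d)(b+d)) / N², and
    kappa = (po - pe) / (1 - pe); the degenerate pe = 1 case (both sets
    empty or both the full universe) is defined as complete agreement, 1.0.
    """
    A, B = set(members_a), set(members_b)
    if isinstance(universe, int):
        N = universe
        if len(A | B) > N:
            raise ValueError("member sets exceed the stated universe size")
    else:
        uni = set(universe)
        if (A | B) - uni:
            raise ValueError("member gene outside the universe")
        N = len(uni)
    if N < 1:
        raise ValueError("universe must contain at least one gene")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = N - len(A | B)
    po = (a + d) / N
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
    if pe == 1.0:
        log.debug("degenerate kappa (pe=1) treated as complete agreement")
        return 1.0
    return (po - pe) / (1.0 - pe)


def kappa_matrix(
    records: Sequence[EnrichmentRecord],
    terms: TermDatabase,
    background: Iterable[str],
) -> np.ndarray:
    """Pairwise kappa similarities between records' term memberships.

    Memberships are taken within the background universe. Rows follow
    the order of ``records``.
    """
    bg = frozenset(background)
    n = len(records)
    member_sets = [terms.members(r.term_id) & bg for r in records]
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            kap = kappa_similarity(member_sets[i], member_sets[j], len(bg))
            mat[i, j] = mat[j, i] = kap
    return mat


def cluster_terms(
    records: Sequence[EnrichmentRecord],
    terms: TermDatabase,
    background: Iterable[str],
    kappa_threshold: float = 0.3,
) -> list[EnrichmentRecord]:
    """Cluster filtered terms by membership similarity.

    Average-linkage hierarchical clustering on distance 1 - kappa; the tree
    is cut so members merge only when linkage kappa >= ``kappa_threshold``.
    Cluster ids are assigned 1, 2, ... in order of best (minimum) member
    p-value. Input order does not matter: records are canonically sorted by
    term id before the linkage is computed.
    """
    if not records:
        raise ValueError("no records to cluster")
    order = sorted(range(len(records)), key=lambda i: records[i].term_id)
    ordered = [records[i] for i in order]
    if len(ordered) == 1:
        return [replace(records[0], cluster_id=1)]
    mat = kappa_matrix(ordered, terms, background)
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)  # kappa can be < 0; distances stay >= 0
    condensed = squareform(dist, checks=False)
    link = average(condensed)
    labels = fcluster(link, t=1.0 - kappa_threshold, criterion="distance")

    # rank clusters by their best member p-value (then term id for stability)
    best: dict[int, tuple[float, str]] = {}
    for lab, rec in zip(labels, ordered):
        key = (rec.p_value, rec.term_id)
        if lab not in best or key < best[lab]:
            best[lab] = key
    rank = {lab: i + 1 for i, (lab, _) in enumerate(sorted(best.items(), key=lambda kv: kv[1]))}

    out = list(records)
    for pos, lab in zip(order, labels):
        out[pos] = replace(records[pos], cluster_id=rank[lab])
    return out


def select_representatives(
    records: Sequence[EnrichmentRecord],
    max_clusters: int = 20,
    max_terms_per_cluster: int = 10,
) -> list[EnrichmentRecord]:
    """Flag up to ``max_terms_per_cluster`` terms in the best clusters.

    Clusters rank by score (minimum member p, best first); only the top
    ``max_clusters`` keep representatives. Within a cluster terms are taken
    by p-value, ties by term id.
    """
    clusters: dict[int, list[EnrichmentRecord]] = {}
    for r in records:
        if r.cluster_id is None:
            raise ValueError(f"record {r.term_id} has no cluster id; run cluster_terms first")
        clusters.setdefault(r.cluster_id, []).append(r)
    scored = sorted(clusters.items(), key=lambda kv: (min((r.p_value, r.term_id) for r in kv[1]), kv[0]))
    keep = {cid for cid, _ in scored[:max_clusters]}

    flagged: dict[str, bool] = {}
    for cid, members in clusters.items():
        members_sorted = sorted(members, key=lambda r: (r.p_value, r.term_id))
        for i, r in enumerate(members_sorted):
            flagged[r.term_id] = cid in keep and i < max_terms_per_cluster
    return [replace(r, is_representative=flagged[r.term_id]) for r in records]


def export_network(
    records: Sequence[EnrichmentRecord],
    kappa: Mapping[tuple[str, str], float] | np.ndarray,
    edge_threshold: float = 0.3,
    sources: Mapping[str, str] | None = None,
) -> tuple[list[dict], list[dict]]:
    """Node and edge tables of the representative-term similarity network.

    Nodes are representative records (attributes: p, overlap k, cluster,
    source group). Undirected edges connect term pairs with kappa strictly
    above ``edge_threshold``; weight = kappa; no self edges. ``kappa`` is
    either a mapping keyed by (term_id, term_id) pairs or a square matrix
    aligned with ``records``.
    """
    reps = [r for r in records if r.is_representative]
    nodes = [
        {
            "node_id": r.term_id,
            "name": r.name,
            "category": r.category,
            "p_value": r.p_value,
            "k": r.k,
            "cluster_id": r.cluster_id,
            "source": (sources or {}).get(r.term_id, ""),
        }
        for r in reps
    ]

    def get_kappa(i: int, j: int) -> float:
        if isinstance(kappa, np.ndarray):
            all_ids = [r.term_id for r in records]
            return float(kappa[all_ids.index(reps[i].term_id), all_ids.index(reps[j].term_id)])
        key = (reps[i].term_id, reps[j].term_id)
        rkey = (reps[j].term_id, reps[i].term_id)
        return float(kappa.get(key, kappa.get(rkey, 0.0)))

    edges = []
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            w = get_kappa(i, j)
            if w > edge_threshold:
                edges.append({"source": reps[i].term_id, "target": reps[j].term_id, "weight": w})
    return nodes, edges


def write_enrichment_tsv(records: Sequence[EnrichmentRecord], path) -> None:
    with open(path, "wt") as handle:
        handle.write(
            "term_id\tcategory\tname\tk\tm\tK\tN\tenrichment_factor\tp_value\tfdr\t"
            "passed_filters\tcluster_id\tis_representative\n"
        )
        for r in records:
            handle.write(
                f"{r.term_id}\t{r.category}\t{r.name}\t{r.k}\t{r.m}\t{r.K}\t{r.N}\t"
                f"{r.enrichment_factor:.6g}\t{r.p_value:.6g}\t{r.fdr:.6g}\t"
                f"{int(r.passed_filters)}\t{'' if r.cluster_id is None else r.cluster_id}\t{int(r.is_representative)}\n"
            )


def write_network_tsv(nodes: Sequence[dict], edges: Sequence[dict], node_path, edge_path) -> None:
    with open(node_path, "wt") as handle:
        handle.write("node_id\tname\tcategory\tp_value\tk\tcluster_id\tsource\n")
        for nd in nodes:
            handle.write(
                f"{nd['node_id']}\t{nd['name']}\t{nd['category']}\t{nd['p_value']:.6g}\t"
                f"{nd['k']}\t{nd['cluster_id']}\t{nd['source']}\n"
            )
    with open(edge_path, "wt") as handle:
        handle.write("source\ttarget\tweight\n")
        for e in edges:
            handle.write(f"{e['source']}\t{e['target']}\t{e['weight']:.6g}\n")
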