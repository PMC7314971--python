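"""Cutoff-filtered annotation of species genes against a reference proteome.

Each species gene receives at most one reference-gene annotation: its best
surviving hit (minimum E-value, ties by maximum bit score, then smallest
subject id). Many species genes may share one reference gene. A second
reference species allows a concordance check: the fraction of genes whose
two annotations form a known between-reference ortholog pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from hmannot.io_formats import BlastHit

__all__ = ["AnnotationMap", "apply_cutoff", "assign_annotations", "concordance_rate"]


@dataclass
class AnnotationMap:
    """Per-sample species gene -> reference gene assignments."""

    sample_id: str
    assignments: dict[str, str] = field(default_factory=dict)
    #: best surviving hit per species gene, for reporting
    best_hits: dict[str, BlastHit] = field(default_factory=dict)

    @property
    def matched_reference(self) -> frozenset[str]:
        """Reference genes with at least one assignment."""
        return frozenset(self.assignments.values())

    def write_tsv(self, path) -> None:
        with open(path, "wt") as handle:
            handle.write("sample_id\tspecies_gene\treference_gene\tevalue\tbit_score\n")
            for gene in sorted(self.assignments):
                hit = self.best_hits.get(gene)
                ev = f"{hit.evalue:.17g}" if hit else ""
                bs = f"{hit.bit_score:.17g}" if hit else ""
                handle.write(f"{self.sample_id}\t{gene}\t{self.assignments[gene]}\t{ev}\t{bs}\n")


def apply_cutoff(hits: Iterable[BlastHit], cutoff: float) -> list[BlastHit]:
    """Hits with E-value <= cutoff (inclusive, so calibration pairs survive)."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    return [h for h in hits if h.evalue <= cutoff]


def assign_annotations(filtered_hits: Iterable[BlastHit], sample_id: str = "") -> AnnotationMap:
    """Best-hit assignment per species gene from cutoff-filtered hits.

    Best = minimum E-value; ties by maximum bit score; remaining ties by
    lexicographically smallest subject id.
    """
    best: dict[str, BlastHit] = {}
    for hit in filtered_hits:
        incumbent = best.get(hit.query_id)
        if incumbent is None or _hit_key(hit) < _hit_key(incumbent):
            best[hit.query_id] = hit
    return AnnotationMap(
        sample_id=sample_id,
        assignments={gene: hit.subject_id for gene, hit in best.items()},
        best_hits=best,
    )


def _hit_key(hit: BlastHit) -> tuple[float, float, str]:
    return (hit.evalue, -hit.bit_score, hit.subject_id)


def concordance_rate(
    map_ref_a: AnnotationMap,
    map_ref_b: AnnotationMap,
    bridge: Mapping[str, str] | Iterable[tuple[str, str]],
) -> tuple[float | None, int]:
    """Dual-reference annotation agreement for one sample.

    ``bridge`` holds ortholog pairs (reference-A gene, reference-B gene)
    from a best-hit search between the two reference proteomes. Over species
    genes annotated in both maps, returns the fraction whose (A, B)
    assignment is a bridge pair, together with the denominator. An empty
    intersection yields ``(None, 0)`` rather than zero.
    """
    if isinstance(bridge, Mapping):
        bridge_pairs = set(bridge.items())
    else:
        bridge_pairs = set(bridge)
    both = set(map_ref_a.assignments) & set(map_ref_b.assignments)
    if not both:
        return None, 0
    agree = sum(
        1 for gene in both if (map_ref_a.assignments[gene], map_ref_b.assignments[gene]) in bridge_pairs
    )
    return agree / len(both), len(both)
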