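"""Per-species E-value cutoff calibration from single-copy ortholog pairs.

A species gene and a reference gene classified into the same single-copy
(category C) ortholog set form a confirmed gene pair. Collecting the
default-parameter homology-search E-values of those pairs and taking the
per-species maximum yields the species-specific cutoff: the weakest E-value
at which a confirmed ortholog was still found. Distant species therefore get
looser cutoffs, close relatives stricter ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from hmannot.io_formats import BlastHit, OrthologAssignment

__all__ = [
    "GenePair",
    "CutoffTable",
    "CalibrationError",
    "busco_gene_pairs",
    "calibrate_cutoff",
    "neg_log10_evalue",
]

log = logging.getLogger(__name__)

#: Floor applied to zero E-values before the log transform only.
DEFAULT_ZERO_FLOOR = 1e-180


class CalibrationError(RuntimeError):
    """Raised when a species cannot be calibrated or single-copy is violated."""


@dataclass(frozen=True)
class GenePair:
    """A confirmed ortholog pair linking a species gene to a reference gene."""

    sample_id: str
    species_gene: str
    reference_gene: str
    busco_set: str

    def __post_init__(self) -> None:
        if not self.species_gene or not self.reference_gene:
            raise ValueError("gene pair requires non-empty gene ids")


@dataclass
class CutoffTable:
    """Per-sample E-value cutoffs with their log-scale form."""

    cutoffs: dict[str, float] = field(default_factory=dict)
    neg_log10: dict[str, float] = field(default_factory=dict)
    n_pairs_used: dict[str, int] = field(default_factory=dict)

    def add(self, sample_id: str, cutoff: float, n_pairs: int, zero_floor: float = DEFAULT_ZERO_FLOOR) -> None:
        self.cutoffs[sample_id] = cutoff
        self.neg_log10[sample_id] = neg_log10_evalue(cutoff, zero_floor)
        self.n_pairs_used[sample_id] = n_pairs

    def write_tsv(self, path) -> None:
        with open(path, "wt") as handle:
            handle.write("sample_id\tevalue_cutoff\tneg_log10\tn_pairs_used\n")
            for sid in self.cutoffs:
                handle.write(
                    f"{sid}\t{self.cutoffs[sid]:.17g}\t{self.neg_log10[sid]:.17g}\t{self.n_pairs_used[sid]}\n"
                )


def busco_gene_pairs(
    species_assignments: Iterable[OrthologAssignment],
    reference_assignments: Mapping[str, str],
    sample_id: str = "",
) -> list[GenePair]:
    """Form gene pairs from category-C assignments sharing an ortholog set.

    ``reference_assignments`` maps ortholog set id -> reference gene id.
    Only category C (complete single-copy) species assignments pair; D, F
    and M contribute nothing. Two category-C species genes in the same set
    violate the single-copy premise and raise :class:`CalibrationError`.
    """
    c_by_set: dict[str, str] = {}
    for a in species_assignments:
        if a.category != "C":
            continue
        if a.busco_set in c_by_set and c_by_set[a.busco_set] != a.gene_id:
            raise CalibrationError(
                f"sample {sample_id!r}: ortholog set {a.busco_set!r} has two category-C genes "
                f"({c_by_set[a.busco_set]!r}, {a.gene_id!r}); single-copy violated"
            )
        c_by_set[a.busco_set] = a.gene_id
    pairs = [
        GenePair(sample_id=sample_id, species_gene=gene, reference_gene=reference_assignments[bset], busco_set=bset)
        for bset, gene in sorted(c_by_set.items())
        if bset in reference_assignments
    ]
    return pairs


def calibrate_cutoff(
    pairs: Iterable[GenePair],
    default_hits: Iterable[BlastHit],
    sample_id: str = "",
) -> tuple[float, int]:
    """E-value cutoff for one sample: max over pair-matching hit E-values.

    A hit matches a pair when its (query, subject) equals the pair's
    (species gene, reference gene). A pair hit by several rows (multiple
    HSPs) enters at its best (minimum) E-value; the cutoff is the maximum of
    those per-pair values. Pairs with no hit are dropped from the
    calibration (counted in the log); no pair hitting at all is an error.

    Returns ``(cutoff, n_pairs_used)``.
    """
    wanted = {(p.species_gene, p.reference_gene) for p in pairs}
    if not wanted:
        raise CalibrationError(f"sample {sample_id!r}: no gene pairs to calibrate from")
    best_per_pair: dict[tuple[str, str], float] = {}
    for hit in default_hits:
        key = (hit.query_id, hit.subject_id)
        if key in wanted:
            prev = best_per_pair.get(key)
            if prev is None or hit.evalue < prev:
                best_per_pair[key] = hit.evalue
    if not best_per_pair:
        raise CalibrationError(f"sample {sample_id!r}: no homology-search hit matches any ortholog pair")
    dropped = len(wanted) - len(best_per_pair)
    if dropped:
        log.info("sample %s: %d of %d calibration pairs had no hit (dropped)", sample_id, dropped, len(wanted))
    return max(best_per_pair.values()), len(best_per_pair)


def neg_log10_evalue(e: float, zero_floor: float = DEFAULT_ZERO_FLOOR) -> float:
    """-log10 of an E-value, flooring exact zeros at ``zero_floor``.

    The floor affects only the log transform; the raw cutoff keeps 0.0 for
    filtering. Summary tables round the result to integers.
    """
    if e < 0:
        raise ValueError(f"negative E-value {e}")
    return -math.log10(max(e, zero_floor))
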