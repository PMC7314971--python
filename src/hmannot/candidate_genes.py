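"""Stage 1 screening: expressed-gene selection and ORF-based protein calling.

Genes are kept when their abundance exceeds a TPM threshold (strictly
greater than 1 by default), then each retained transcript is scanned in all
six reading frames for the longest complete open reading frame
(ATG ... in-frame stop) and translated into a candidate protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import Seq

from hmannot.io_formats import ExpressionTable

__all__ = [
    "CandidateProtein",
    "filter_expressed",
    "extract_candidate_protein",
    "longest_per_locus",
    "locus_id",
    "candidate_proteins",
]

log = logging.getLogger(__name__)

#: Frame labels in scan (and tie-break) order.
FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

_STOPS = {"TAA", "TAG", "TGA"}
_MAX_X_FRACTION = 0.20  # reject candidates dominated by ambiguous residues


@dataclass(frozen=True)
class CandidateProtein:
    """A complete ORF translated from one transcript.

    ``orf_start``/``orf_end`` are 0-based half-open nucleotide coordinates on
    the forward strand and include the stop codon; their span is divisible
    by 3. The protein excludes the stop symbol and begins with M.
    """

    gene_id: str
    protein: str
    source_frame: str  # one of FRAMES
    orf_start: int
    orf_end: int
    has_start: bool = True
    has_stop: bool = True

    def __post_init__(self) -> None:
        if (self.orf_end - self.orf_start) % 3 != 0:
            raise ValueError("ORF span not divisible by 3")
        if self.protein and not self.protein.startswith("M"):
            raise ValueError("candidate protein must begin with M")


def filter_expressed(expr: ExpressionTable, threshold: float = 1.0) -> set[str]:
    """Genes with TPM strictly greater than ``threshold``.

    The strict inequality means a gene at exactly the threshold is excluded.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    for gene, tpm in expr.entries.items():
        if tpm < 0:
            raise ValueError(f"negative TPM {tpm} for gene {gene!r}")
    return {gene for gene, tpm in expr.entries.items() if tpm > threshold}


def _translate_codons(codons: list[str]) -> str:
    out = []
    for codon in codons:
        if "N" in codon:
            out.append("X")
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)


def extract_candidate_protein(transcript: str, min_aa: int = 50, gene_id: str = "") -> CandidateProtein | None:
    """Longest complete ORF over all six frames, or None.

    Scans each frame for ATG ... next in-frame stop; among qualifying ORFs
    (protein length >= ``min_aa`` codons, excluding the stop) the longest
    wins; length ties resolve by frame order +1,+2,+3,-1,-2,-3 and then by
    smaller forward-strand start. Codons containing N translate to X;
    candidates with more than 20% X are rejected.
    """
    if not transcript:
        raise ValueError("empty transcript sequence")
    seq = transcript.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError(f"invalid nucleotides in transcript {gene_id!r}")
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())

    best: tuple[int, int, int] | None = None  # (-length, frame_index, fwd_start)
    best_payload: CandidateProtein | None = None

    for frame_index, frame in enumerate(FRAMES):
        strand_seq = seq if frame.startswith("+") else rc
        offset = int(frame[1]) - 1
        codons = [strand_seq[i : i + 3] for i in range(offset, len(strand_seq) - 2, 3)]
        i = 0
        while i < len(codons):
            if codons[i] == "ATG":
                # find the next in-frame stop
                j = i + 1
                while j < len(codons) and codons[j] not in _STOPS:
                    j += 1
                if j < len(codons):
                    length = j - i  # codons excluding the stop
                    if length >= min_aa:
                        # nucleotide coords on scanned strand, incl. stop codon
                        s = offset + 3 * i
                        e = offset + 3 * (j + 1)
                        if frame.startswith("+"):
                            fwd_start, fwd_end = s, e
                        else:
                            fwd_start, fwd_end = n - e, n - s
                        key = (-length, frame_index, fwd_start)
                        if best is None or key < best:
                            protein = _translate_codons(codons[i:j])
                            if protein.count("X") <= _MAX_X_FRACTION * len(protein):
                                best = key
                                best_payload = CandidateProtein(
                                    gene_id=gene_id,
                                    protein=protein,
                                    source_frame=frame,
                                    orf_start=fwd_start,
                                    orf_end=fwd_end,
                                )
                            else:
                                # a later ATG in this window may still yield an
                                # acceptable (lower-X) candidate: keep scanning
                                log.debug("rejected high-X ORF in %s frame %s", gene_id, frame)
                                i += 1
                                continue
                    # any ATG between i and the stop yields a strictly shorter
                    # ORF ending at the same stop; resume after the stop
                    i = j + 1
                    continue
            i += 1
    return best_payload


def locus_id(transcript_id: str, isoform_sep: str = "_i") -> str:
    """Locus part of an assembler-style ``gene_isoform`` transcript id."""
    if isoform_sep in transcript_id:
        return transcript_id.rsplit(isoform_sep, 1)[0]
    return transcript_id


def longest_per_locus(
    candidates: Iterable[CandidateProtein], isoform_sep: str = "_i"
) -> dict[str, CandidateProtein]:
    """One candidate per locus: the longest protein, ties by transcript id."""
    by_locus: dict[str, CandidateProtein] = {}
    for cand in candidates:
        loc = locus_id(cand.gene_id, isoform_sep)
        incumbent = by_locus.get(loc)
        if (
            incumbent is None
            or len(cand.protein) > len(incumbent.protein)
            or (len(cand.protein) == len(incumbent.protein) and cand.gene_id < incumbent.gene_id)
        ):
            by_locus[loc] = cand
    return by_locus


def candidate_proteins(
    transcripts: Mapping[str, str],
    expr: ExpressionTable,
    tpm_threshold: float = 1.0,
    min_aa: int = 50,
    isoform_sep: str = "_i",
) -> dict[str, CandidateProtein]:
    """Expression filter, ORF extraction and per-locus selection combined.

    Expression is keyed at the locus level; transcripts of unexpressed loci
    are skipped before ORF scanning.
    """
    expressed = filter_expressed(expr, tpm_threshold)
    found: list[CandidateProtein] = []
    for tid, seq in transcripts.items():
        if locus_id(tid, isoform_sep) not in expressed:
            continue
        cand = extract_candidate_protein(seq, min_aa=min_aa, gene_id=tid)
        if cand is not None:
            found.append(cand)
    result = longest_per_locus(found, isoform_sep)
    log.info(
        "candidates for %s: %d expressed loci, %d with a complete ORF",
        expr.sample_id,
        len(expressed),
        len(result),
    )
    return result
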