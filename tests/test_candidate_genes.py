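import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from hmannot.candidate_genes import (
    FRAMES,
    CandidateProtein,
    extract_candidate_protein,
    filter_expressed,
    longest_per_locus,
)
from hmannot.io_formats import ExpressionTable

_STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orf(seq: str, min_aa: int):
    """Enumerate every (frame, ATG, next in-frame stop) triple independently."""
    seq = seq.upper()
    rc = str(Seq(seq).reverse_complement())
    n = len(seq)
    best = None
    for frame_index, frame in enumerate(FRAMES):
        strand = seq if frame.startswith("+") else rc
        offset = int(frame[1]) - 1
        for start in range(offset, len(strand) - 2, 3):
            if strand[start : start + 3] != "ATG":
                continue
            stop = None
            for p in range(start + 3, len(strand) - 2, 3):
                if strand[p : p + 3] in _STOPS:
                    stop = p
                    break
            if stop is None:
                continue
            length = (stop - start) // 3
            if length < min_aa:
                continue
            codons = [strand[i : i + 3] for i in range(start, stop, 3)]
            protein = "".join("X" if "N" in c else str(Seq(c).translate()) for c in codons)
            if protein.count("X") > 0.20 * len(protein):
                continue
            if frame.startswith("+"):
                fwd_start = start
            else:
                fwd_start = n - (stop + 3)
            key = (-length, frame_index, fwd_start)
            if best is None or key < best[0]:
                best = (key, protein, frame, fwd_start)
    return best


class TestFilterExpressed:
    def test_strict_threshold(self):
        expr = ExpressionTable("s", {"a": 0.5, "b": 1.0, "c": 2.3})
        assert filter_expressed(expr, 1.0) == {"c"}

    def test_empty_and_zero_boundary(self):
        assert filter_expressed(ExpressionTable("s", {}), 1.0) == set()
        assert filter_expressed(ExpressionTable("s", {"a": 0.0}), 0.0) == set()

    @given(
        st.dictionaries(st.text("ab", min_size=1, max_size=3), st.floats(0, 100), max_size=20),
        st.floats(0, 50),
        st.floats(0, 50),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_threshold(self, entries, t1, t2):
        expr = ExpressionTable("s", entries)
        lo, hi = sorted([t1, t2])
        assert filter_expressed(expr, hi) <= filter_expressed(expr, lo)


class TestExtractCandidateProtein:
    def test_minimal_orf(self):
        cand = extract_candidate_protein("ATGAAATAA", min_aa=1)
        assert cand.protein == "MK"
        assert cand.source_frame == "+1"
        assert cand.has_start and cand.has_stop

    def test_frame_offset(self):
        cand = extract_candidate_protein("CCATGAAATAACC", min_aa=1)
        assert cand.protein == "MK"
        assert cand.source_frame == "+3"

    def test_reverse_strand(self):
        # revcomp of ATGAAATAA
        cand = extract_candidate_protein("TTATTTCAT", min_aa=1)
        assert cand.protein == "MK"
        assert cand.source_frame.startswith("-")

    def test_no_orf_returns_none(self):
        assert extract_candidate_protein("AAATTTGGG", min_aa=1) is None

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            extract_candidate_protein("", min_aa=1)

    def test_n_codons_translate_to_x(self):
        cand = extract_candidate_protein("ATGAANAAAAAAAAATAA", min_aa=1)
        assert cand.protein == "MXKKK"

    def test_mostly_ambiguous_orf_rejected(self):
        # 2 of 3 residues would be X (> 20%): the quality guard drops it
        assert extract_candidate_protein("ATGAANAANTAA", min_aa=1) is None

    def test_coordinates_are_forward_strand_and_in_frame(self, rng):
        for _ in range(50):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
            cand = extract_candidate_protein(seq, min_aa=10)
            if cand is None:
                continue
            assert (cand.orf_end - cand.orf_start) % 3 == 0
            assert 0 <= cand.orf_start < cand.orf_end <= len(seq)
            assert cand.protein.startswith("M")
            assert "*" not in cand.protein

    def test_matches_brute_force_on_random_sequences(self, rng):
        """Six-frame scan equals exhaustive (frame, ATG, stop) enumeration."""
        n_checked = 0
        for i in range(500):
            length = int(rng.integers(30, 2001)) if i % 10 == 0 else int(rng.integers(30, 500))
            seq = "".join("ACGTN"[j] for j in rng.choice(5, size=length, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            min_aa = int(rng.integers(1, 30))
            expected = brute_force_orf(seq, min_aa)
            got = extract_candidate_protein(seq, min_aa=min_aa)
            if expected is None:
                assert got is None
            else:
                _, protein, frame, fwd_start = expected
                assert got is not None
                assert got.protein == protein
                assert got.source_frame == frame
                assert got.orf_start == fwd_start
                n_checked += 1
        assert n_checked > 50  # the generator must exercise real ORFs


class TestLongestPerLocus:
    def _cand(self, tid, length):
        return CandidateProtein(
            gene_id=tid, protein="M" + "A" * (length - 1), source_frame="+1", orf_start=0, orf_end=3 * (length + 1)
        )

    def test_longest_wins(self):
        chosen = longest_per_locus([self._cand("L_i1", 100), self._cand("L_i2", 250)])
        assert chosen["L"].gene_id == "L_i2"

    def test_tie_breaks_lexicographically(self):
        chosen = longest_per_locus([self._cand("L_i2", 100), self._cand("L_i1", 100)])
        assert chosen["L"].gene_id == "L_i1"

    def test_empty_input(self):
        assert longest_per_locus([]) == {}
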