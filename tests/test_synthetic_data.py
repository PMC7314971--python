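import filecmp

import numpy as np
import pytest
from Bio.Seq import Seq

from hmannot.synthetic_data import (
    PanelDesign,
    simulate_panel,
    simulate_reference,
    truth_report,
    write_panel,
)


def small_design(**kw):
    base = dict(
        n_ref_genes=120,
        n_terms=15,
        term_size_range=(5, 15),
        n_cold=3,
        n_hot=3,
        n_planted_cold=8,
        n_planted_hot=6,
        n_enriched_terms=2,
        seed=7,
    )
    base.update(kw)
    return PanelDesign(**base)


@pytest.fixture(scope="module")
def small_panel():
    design = small_design()
    reference, terms = simulate_reference(design)
    return simulate_panel(reference, terms, design)


class TestSimulateReference:
    def test_seeded_determinism(self):
        d = small_design(n_ref_genes=100, n_terms=10)
        assert simulate_reference(d) == simulate_reference(d)

    def test_fixed_term_size(self):
        d = small_design(term_size_range=(5, 5), n_enriched_terms=0)
        _, terms = simulate_reference(d)
        assert all(len(m) == 5 for _, _, m in terms.terms.values())

    def test_oversized_terms_rejected(self):
        with pytest.raises(ValueError, match="term_size_range"):
            simulate_reference(small_design(n_ref_genes=40, term_size_range=(50, 60)))

    def test_proteins_start_with_m_and_in_length_range(self):
        ref, _ = simulate_reference(small_design())
        assert all(p.startswith("M") and 80 <= len(p) <= 400 for p in ref.values())


class TestSimulatePanel:
    def test_zero_sigma_evalues_follow_linear_model(self):
        design = small_design(
            n_cold=1,
            n_hot=1,
            divergence={"cold1": 0.1, "hot1": 0.9},
            evalue_model=(100.0, 90.0, 0.0),
            spurious_hit_rate=0.0,
            conserved_fraction=1.0,
        )
        ref, terms = simulate_reference(design)
        panel = simulate_panel(ref, terms, design)
        for sid, expected in (("cold1", 91.0), ("hot1", 19.0)):
            xs = [-np.log10(h.evalue) for h in panel.blast_hits[sid]]
            assert xs == pytest.approx([expected] * len(xs))
            # one true hit per conserved gene; the other group's planted
            # genes have no ortholog here
            other_planted = design.n_planted_hot if sid == "cold1" else design.n_planted_cold
            assert len(xs) == design.n_ref_genes - other_planted

    def test_same_seed_byte_identical_files(self, tmp_path):
        design = small_design(n_cold=2, n_hot=2)
        for run in ("a", "b"):
            ref, terms = simulate_reference(design)
            write_panel(simulate_panel(ref, terms, design), tmp_path / run)
        cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")

        def assert_equal(c):
            assert not c.diff_files and not c.left_only and not c.right_only
            for sub in c.subdirs.values():
                assert_equal(sub)

        assert_equal(cmp)

    def test_planted_genes_confined_to_their_group(self, small_panel):
        truth = small_panel.truth
        for sid in truth.divergence:
            prop = "cold" if sid.startswith("cold") else "hot"
            refs = {truth.ortholog_map[k] for k in truth.ortholog_map if k[0] == sid}
            foreign = truth.planted_hot if prop == "cold" else truth.planted_cold
            own = truth.planted_cold if prop == "cold" else truth.planted_hot
            assert not (refs & foreign)
            assert own <= refs
            # planted genes are always expressed
            loci = {k[1] for k in truth.ortholog_map if k[0] == sid and truth.ortholog_map[k] in own}
            assert loci <= truth.expressed[sid]

    def test_embedded_orf_translates_back_to_source_protein(self, small_panel):
        checked = 0
        for (sid, tid), (strand, start, end) in small_panel.truth.orf_coords.items():
            seq = small_panel.transcripts[sid][tid][start:end]
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
            protein = str(Seq(seq).translate())
            assert protein.endswith("*")
            locus = tid.rsplit("_i", 1)[0]
            ref_gene = small_panel.truth.ortholog_map[(sid, locus)]
            assert protein[:-1] == small_panel.reference_proteome[ref_gene]
            checked += 1
            if checked >= 80:
                break

    def test_mean_neg_log10_evalue_decreases_with_divergence(self):
        """True-hit E-value magnitudes worsen with evolutionary distance."""
        design = small_design(
            n_cold=4, n_hot=4, n_ref_genes=300, n_planted_cold=5, n_planted_hot=5, spurious_hit_rate=0.0
        )
        ref, terms = simulate_reference(design)
        panel = simulate_panel(ref, terms, design)
        order = sorted(design.divergence, key=design.divergence.get)
        means = []
        for sid in order:
            xs = [-np.log10(h.evalue) for h in panel.blast_hits[sid]]
            assert len(xs) >= 200
            means.append(np.mean(xs))
        # one-sided tolerance: half the model sigma
        tol = design.evalue_model[2] / 2
        assert all(means[i] >= means[i + 1] - tol for i in range(len(means) - 1))

    def test_too_many_planted_rejected(self):
        design = small_design(conserved_fraction=0.1, n_planted_cold=10, n_planted_hot=10)
        ref, terms = simulate_reference(design)
        with pytest.raises(ValueError, match="planted"):
            simulate_panel(ref, terms, design)


class TestTruthReport:
    def test_sample_mismatch_is_error(self, small_panel):
        from hmannot.annotation import AnnotationMap

        with pytest.raises(ValueError, match="sample ids"):
            truth_report(small_panel.truth, {"bogus": AnnotationMap("bogus")})

    def test_empty_planted_sets_report_none_not_zero(self):
        design = small_design(n_planted_cold=1, n_planted_hot=1, n_enriched_terms=0)
        ref, terms = simulate_reference(design)
        panel = simulate_panel(ref, terms, design)
        from hmannot.annotation import AnnotationMap

        truth = panel.truth
        truth.planted_cold = frozenset()
        truth.planted_hot = frozenset()
        truth.enriched_terms = frozenset()
        annotations = {sid: AnnotationMap(sid) for sid in truth.divergence}
        report = truth_report(truth, annotations, {"cold": frozenset(), "hot": frozenset()}, [])
        assert report["cold_specific_recall"] is None
        assert report["hot_specific_recall"] is None
        assert report["enriched_term_recall"] is None
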