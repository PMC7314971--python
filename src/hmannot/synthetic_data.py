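"""Synthetic study panels with known ground truth.

Generates a reference proteome with a flat term database, a panel of
cold/hot species at graded evolutionary divergence, and every input the
annotation pipeline consumes: transcript FASTA (each protein's ORF embedded
on a random strand inside random UTR padding), gene-level TPM tables with a
sub-threshold fraction, BUSCO-style classification tables, and tabular
homology-search hits whose E-values worsen with divergence
(-log10 E ~ Normal(a - b*d, sigma), truncated at 0). Property-specific
reference genes are planted (present and expressed only in one group) along
with terms concentrated in the planted genes, so recovery of the group
comparison can be scored exactly.

Defaults mirror the study design: 10 cold and 10 hot samples spanning
divergences that put the closest species' cutoff near -log10(E) = 114 and
the farthest near 16.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from hmannot.annotation import AnnotationMap
from hmannot.io_formats import (
    BlastHit,
    ExpressionTable,
    OrthologAssignment,
    SampleRecord,
    TermDatabase,
    write_blast_tabular,
    write_expression_table,
    write_fasta,
    write_gene_sets,
)

__all__ = [
    "PanelDesign",
    "PanelTruth",
    "PanelData",
    "simulate_reference",
    "simulate_panel",
    "write_panel",
    "truth_report",
]

log = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"

# standard genetic code, inverted: amino acid -> codons
_CODONS: dict[str, list[str]] = {}
_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "AGT": "S", "AGC": "S", "CCT": "P", "CCC": "P",
    "CCA": "P", "CCG": "P", "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
for codon, aa in _TABLE.items():
    _CODONS.setdefault(aa, []).append(codon)
_STOP_CODONS = ["TAA", "TAG", "TGA"]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PanelDesign:
    """Parameters of a synthetic study panel.

    ``evalue_model`` is (a, b, sigma): true-ortholog hits draw
    -log10(E) from Normal(a - b*d, sigma) truncated at 0, where d is the
    species' divergence from the reference in [0, 1].
    """

    n_ref_genes: int = 1000
    n_terms: int = 100
    term_size_range: tuple[int, int] = (10, 50)
    n_cold: int = 10
    n_hot: int = 10
    divergence: dict[str, float] | None = None
    conserved_fraction: float = 0.85
    expressed_fraction: float = 0.9
    busco_c_fraction: float = 0.3
    evalue_model: tuple[float, float, float] = (120.0, 100.0, 8.0)
    spurious_hit_rate: float = 0.5
    n_planted_cold: int = 40
    n_planted_hot: int = 25
    n_enriched_terms: int = 4
    dual_reference: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("conserved_fraction", "expressed_fraction", "busco_c_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_ref_genes", "n_terms", "n_cold", "n_hot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.spurious_hit_rate < 0:
            raise ValueError("spurious_hit_rate must be non-negative")
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi:
            raise ValueError("term_size_range must satisfy 1 <= min <= max")
        if self.divergence is None:
            self.divergence = self._default_divergence()
        if set(self.divergence) != set(self.sample_ids):
            raise ValueError("divergence must map exactly the panel's sample ids")
        a, b, _ = self.evalue_model
        if a - b * max(self.divergence.values()) <= 0:
            warnings.warn(
                "a - b*max(d) <= 0: the farthest species' expected -log10(E) is non-positive",
                stacklevel=2,
            )

    @property
    def sample_ids(self) -> list[str]:
        return [f"cold{i + 1}" for i in range(self.n_cold)] + [f"hot{i + 1}" for i in range(self.n_hot)]

    def _default_divergence(self) -> dict[str, float]:
        """Divergences alternate between groups so both span the gradient."""
        n = self.n_cold + self.n_hot
        grid = np.linspace(0.06, 1.0, n)
        cold = [f"cold{i + 1}" for i in range(self.n_cold)]
        hot = [f"hot{i + 1}" for i in range(self.n_hot)]
        out: dict[str, float] = {}
        ci = hi = 0
        for pos, d in enumerate(grid):
            if (pos % 2 == 0 and ci < len(cold)) or hi >= len(hot):
                out[cold[ci]] = float(d)
                ci += 1
            else:
                out[hot[hi]] = float(d)
                hi += 1
        return out

    def noiseless(self) -> "PanelDesign":
        """Copy with all stochastic degradations switched off."""
        return replace(
            self,
            divergence=dict(self.divergence or {}),
            conserved_fraction=1.0,
            expressed_fraction=1.0,
            busco_c_fraction=1.0,
            evalue_model=(self.evalue_model[0], self.evalue_model[1], 0.0),
            spurious_hit_rate=0.0,
        )


@dataclass
class PanelTruth:
    """Ground truth of a generated panel."""

    ortholog_map: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_cold: frozenset[str] = frozenset()
    planted_hot: frozenset[str] = frozenset()
    enriched_terms: frozenset[str] = frozenset()
    divergence: dict[str, float] = field(default_factory=dict)
    #: per-sample species genes with TPM above the expression threshold
    expressed: dict[str, frozenset[str]] = field(default_factory=dict)
    #: (sample_id, transcript_id) -> (strand, orf_start, orf_end) forward coords
    orf_coords: dict[tuple[str, str], tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.planted_cold & self.planted_hot:
            raise ValueError("planted cold and hot gene sets must be disjoint")


@dataclass
class PanelData:
    """In-memory panel: all pipeline inputs plus the truth."""

    design: PanelDesign
    samples: list[SampleRecord]
    reference_proteome: dict[str, str]
    terms: TermDatabase
    reference_busco: dict[str, str]  # ortholog set -> reference gene
    transcripts: dict[str, dict[str, str]]  # sample -> transcript id -> seq
    expression: dict[str, ExpressionTable]
    busco_tables: dict[str, list[OrthologAssignment]]
    blast_hits: dict[str, list[BlastHit]]
    #: hits against the second reference (empty when dual_reference is off)
    blast_hits_b: dict[str, list[BlastHit]]
    #: primary-reference gene -> second-reference gene ortholog bridge
    bridge: dict[str, str]
    truth: PanelTruth


def _ref_gene_ids(design: PanelDesign) -> list[str]:
    return [f"REF{i:05d}" for i in range(design.n_ref_genes)]


def _plant(design: PanelDesign) -> tuple[frozenset[str], frozenset[str]]:
    """Deterministic selection of the planted property-specific genes."""
    rng = np.random.default_rng([design.seed, 1])
    genes = _ref_gene_ids(design)
    n_plant = design.n_planted_cold + design.n_planted_hot
    if n_plant > design.n_ref_genes:
        raise ValueError("more planted genes than reference genes")
    picked = rng.choice(len(genes), size=n_plant, replace=False)
    cold = frozenset(genes[i] for i in picked[: design.n_planted_cold])
    hot = frozenset(genes[i] for i in picked[design.n_planted_cold :])
    return cold, hot


def _enriched_term_plan(design: PanelDesign) -> list[str]:
    """Ids of the planted enriched terms (first alternating cold/hot)."""
    return [f"T{i:04d}" for i in range(design.n_enriched_terms)]


def simulate_reference(design: PanelDesign) -> tuple[dict[str, str], TermDatabase]:
    """Random reference proteome and term database, deterministic per seed.

    Proteins are 80-400 residues starting with M. The first
    ``n_enriched_terms`` terms concentrate (80% of their members) in the
    planted property-specific genes, alternating cold/hot; remaining terms
    sample members uniformly from the gene universe.
    """
    lo, hi = design.term_size_range
    if hi > design.n_ref_genes:
        raise ValueError("term_size_range max exceeds the number of reference genes")
    if design.n_enriched_terms > design.n_terms:
        raise ValueError("n_enriched_terms exceeds n_terms")
    rng = np.random.default_rng([design.seed, 0])
    genes = _ref_gene_ids(design)
    proteome: dict[str, str] = {}
    for gene in genes:
        length = int(rng.integers(80, 401))
        body = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length - 1))
        proteome[gene] = "M" + body

    planted_cold, planted_hot = _plant(design)
    rng_terms = np.random.default_rng([design.seed, 3])
    categories = ["GO_BP", "GO_MF", "GO_CC", "KEGG"]
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    for t in range(design.n_terms):
        term_id = f"T{t:04d}"
        size = int(rng_terms.integers(lo, hi + 1))
        if t < design.n_enriched_terms:
            planted = sorted(planted_cold if t % 2 == 0 else planted_hot)
            n_core = max(1, min(len(planted), int(round(0.8 * size))))
            core = [planted[i] for i in rng_terms.choice(len(planted), size=n_core, replace=False)]
            rest_pool = sorted(set(genes) - set(core))
            n_rest = size - n_core
            rest = [rest_pool[i] for i in rng_terms.choice(len(rest_pool), size=n_rest, replace=False)]
            members = frozenset(core + rest)
            category = "GO_BP"
            name = f"planted {'cold' if t % 2 == 0 else 'hot'} module {t}"
        else:
            members = frozenset(genes[i] for i in rng_terms.choice(len(genes), size=size, replace=False))
            category = categories[t % len(categories)]
            name = f"synthetic term {t}"
        terms[term_id] = (name, category, members)
    return proteome, TermDatabase(terms=terms)


def _truncnorm_neg_log10(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    """Draws from Normal(mean, sigma) truncated at 0 (rejection sampling)."""
    if sigma == 0:
        return np.full(size, max(mean, 0.0))
    out = rng.normal(mean, sigma, size=size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sigma, size=int(bad.sum()))
        bad = out < 0
    return out


def _embed_orf(rng: np.random.Generator, protein: str) -> tuple[str, str, int, int]:
    """Transcript embedding the protein's ORF on a random strand.

    Returns (sequence, strand, orf_start, orf_end) with 0-based half-open
    forward-strand coordinates including the stop codon.
    """
    codons = ["ATG"]
    for aa in protein[1:]:
        choices = _CODONS[aa]
        codons.append(choices[int(rng.integers(0, len(choices)))])
    codons.append(_STOP_CODONS[int(rng.integers(0, 3))])
    orf = "".join(codons)
    utr5 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(5, 61))))
    utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(5, 61))))
    fwd = utr5 + orf + utr3
    start, end = len(utr5), len(utr5) + len(orf)
    if rng.integers(0, 2) == 1:
        n = len(fwd)
        return _revcomp(fwd), "-", n - end, n - start
    return fwd, "+", start, end


def simulate_panel(
    reference: Mapping[str, str],
    terms: TermDatabase,
    design: PanelDesign,
) -> PanelData:
    """Generate every per-sample input artifact with known ground truth.

    Per sample, ``conserved_fraction`` of the reference genes receive a
    species ortholog (planted genes only in their own group's samples);
    each true ortholog yields a homology hit with E-value 10**(-x),
    x ~ TruncNormal(a - b*d, sigma, >= 0), plus Poisson-distributed spurious
    hits with E-values in [1e-3, 10] against other subjects; a
    ``busco_c_fraction`` subset of the conserved, expressed genes appears as
    category-C rows pairing species gene and reference gene through shared
    ortholog sets.
    """
    genes = _ref_gene_ids(design)
    if set(reference) != set(genes):
        raise ValueError("reference proteome does not match the design's gene universe")
    planted_cold, planted_hot = _plant(design)
    conserved_target = int(round(design.conserved_fraction * design.n_ref_genes))
    if design.n_planted_cold + design.n_planted_hot > conserved_target:
        raise ValueError("planted genes exceed the conserved gene count")

    a, b, sigma = design.evalue_model
    gene_index = {g: i for i, g in enumerate(genes)}
    reference_busco = {f"B{i + 1:05d}": g for i, g in enumerate(genes)}
    set_of_gene = {g: s for s, g in reference_busco.items()}
    bridge = {g: g.replace("REF", "OSJ") for g in genes}

    samples: list[SampleRecord] = []
    transcripts: dict[str, dict[str, str]] = {}
    expression: dict[str, ExpressionTable] = {}
    busco_tables: dict[str, list[OrthologAssignment]] = {}
    blast_hits: dict[str, list[BlastHit]] = {}
    blast_hits_b: dict[str, list[BlastHit]] = {}
    truth = PanelTruth(
        planted_cold=planted_cold,
        planted_hot=planted_hot,
        enriched_terms=frozenset(_enriched_term_plan(design)),
        divergence=dict(design.divergence or {}),
    )

    organs = ["root", "stem", "leaf", "flower"]
    non_planted = [g for g in genes if g not in planted_cold and g not in planted_hot]

    for s_index, sample_id in enumerate(design.sample_ids):
        prop = "cold" if sample_id.startswith("cold") else "hot"
        rng = np.random.default_rng([design.seed, 2, s_index])
        d = design.divergence[sample_id]

        group_planted = sorted(planted_cold if prop == "cold" else planted_hot)
        n_extra = conserved_target - len(group_planted)
        extra = [non_planted[i] for i in rng.choice(len(non_planted), size=min(n_extra, len(non_planted)), replace=False)]
        conserved = group_planted + sorted(extra)
        conserved.sort(key=gene_index.__getitem__)

        locus_of: dict[str, str] = {}
        sample_tx: dict[str, str] = {}
        tpm: dict[str, float] = {}
        expressed: set[str] = set()
        for j, ref_gene in enumerate(conserved):
            locus = f"{sample_id}_g{j:05d}"
            tid = f"{locus}_i1"
            locus_of[ref_gene] = locus
            seq, strand, orf_s, orf_e = _embed_orf(rng, reference[ref_gene])
            sample_tx[tid] = seq
            truth.orf_coords[(sample_id, tid)] = (strand, orf_s, orf_e)
            truth.ortholog_map[(sample_id, locus)] = ref_gene
            planted_here = ref_gene in planted_cold or ref_gene in planted_hot
            if planted_here or rng.random() < design.expressed_fraction:
                tpm[locus] = float(10 ** rng.uniform(0.05, 3.0))
                expressed.add(locus)
            else:
                tpm[locus] = float(10 ** rng.uniform(-2.0, -0.02))
        truth.expressed[sample_id] = frozenset(expressed)

        # BUSCO table: category-C rows for a subset of conserved expressed
        # genes; remaining sets of conserved genes are Fragmented, all
        # other sets Missing.
        expressed_conserved = [g for g in conserved if locus_of[g] in expressed]
        n_c = int(round(design.busco_c_fraction * len(expressed_conserved)))
        c_pick = sorted(
            (expressed_conserved[i] for i in rng.choice(len(expressed_conserved), size=n_c, replace=False)),
            key=gene_index.__getitem__,
        )
        c_set = set(c_pick)
        rows: list[OrthologAssignment] = []
        for ref_gene in conserved:
            bset = set_of_gene[ref_gene]
            if ref_gene in c_set:
                rows.append(OrthologAssignment(gene_id=locus_of[ref_gene], busco_set=bset, category="C"))
            elif rng.random() < 0.05:
                rows.append(OrthologAssignment(gene_id=locus_of[ref_gene], busco_set=bset, category="F"))
            else:
                rows.append(OrthologAssignment(gene_id="", busco_set=bset, category="M"))
        for ref_gene in genes:
            if ref_gene not in locus_of:
                rows.append(OrthologAssignment(gene_id="", busco_set=set_of_gene[ref_gene], category="M"))
        busco_tables[sample_id] = rows

        # homology hits: one true hit per conserved gene plus spurious noise
        xs = _truncnorm_neg_log10(rng, a - b * d, sigma, len(conserved))
        hits: list[BlastHit] = []
        hits_b: list[BlastHit] = []
        for ref_gene, x in zip(conserved, xs):
            aln = len(reference[ref_gene])
            pid = float(np.clip(98.0 - 40.0 * d, 20.0, 100.0))
            mism = int(round(aln * (1 - pid / 100.0)))
            true_hit = BlastHit(
                query_id=locus_of[ref_gene],
                subject_id=ref_gene,
                pct_identity=pid,
                aln_length=aln,
                mismatches=mism,
                gap_opens=0,
                q_start=1,
                q_end=aln,
                s_start=1,
                s_end=aln,
                evalue=float(10.0 ** (-x)),
                bit_score=float(2.0 * x + 40.0),
            )
            hits.append(true_hit)
            hits_b.append(replace(true_hit, subject_id=bridge[ref_gene]))
            n_spurious = int(rng.poisson(design.spurious_hit_rate))
            for _ in range(n_spurious):
                subject = genes[int(rng.integers(0, len(genes)))]
                if subject == ref_gene:
                    continue  # spurious hits never collide with the true subject
                ev = float(10.0 ** rng.uniform(-3.0, 1.0))
                sp = BlastHit(
                    query_id=locus_of[ref_gene],
                    subject_id=subject,
                    pct_identity=float(rng.uniform(20.0, 40.0)),
                    aln_length=max(30, aln // 4),
                    mismatches=max(30, aln // 4) // 2,
                    gap_opens=1,
                    q_start=1,
                    q_end=max(30, aln // 4),
                    s_start=1,
                    s_end=max(30, aln // 4),
                    evalue=ev,
                    bit_score=float(rng.uniform(20.0, 40.0)),
                )
                hits.append(sp)
                hits_b.append(replace(sp, subject_id=bridge[subject]))
        blast_hits[sample_id] = hits
        blast_hits_b[sample_id] = hits_b if design.dual_reference else []

        transcripts[sample_id] = sample_tx
        expression[sample_id] = ExpressionTable(sample_id=sample_id, entries=tpm)
        group_pos = int(sample_id.replace(prop, ""))
        samples.append(
            SampleRecord(
                sample_id=sample_id,
                species=f"Synthetica {sample_id}",
                property=prop,
                organ=organs[s_index % len(organs)],
                clade="non_dicot" if prop == "hot" and group_pos % 2 == 1 else "dicot",
                accession="",
            )
        )

    log.info(
        "panel: %d samples, %d reference genes, %d conserved per sample, %d planted (cold %d / hot %d)",
        len(samples),
        design.n_ref_genes,
        conserved_target,
        design.n_planted_cold + design.n_planted_hot,
        design.n_planted_cold,
        design.n_planted_hot,
    )
    return PanelData(
        design=design,
        samples=samples,
        reference_proteome=dict(reference),
        terms=terms,
        reference_busco=reference_busco,
        transcripts=transcripts,
        expression=expression,
        busco_tables=busco_tables,
        blast_hits=blast_hits,
        blast_hits_b=blast_hits_b,
        bridge=bridge,
        truth=truth,
    )


def write_panel(panel: PanelData, outdir: str | Path) -> Path:
    """Persist every panel artifact as plain text; returns the manifest path.

    Output is byte-identical for identical designs (sorted, fixed formats).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(panel.reference_proteome, outdir / "reference_proteome.faa")
    write_gene_sets(panel.terms, outdir / "terms.gmt")
    with open(outdir / "reference_busco.tsv", "wt") as handle:
        handle.write("# busco_set\tstatus\tgene_id\n")
        for bset in sorted(panel.reference_busco):
            handle.write(f"{bset}\tComplete\t{panel.reference_busco[bset]}\n")
    with open(outdir / "samples.tsv", "wt") as handle:
        handle.write("sample_id\tspecies\tproperty\torgan\tclade\taccession\n")
        for rec in panel.samples:
            handle.write(
                f"{rec.sample_id}\t{rec.species}\t{rec.property}\t{rec.organ}\t{rec.clade}\t{rec.accession}\n"
            )
    with open(outdir / "bridge.tsv", "wt") as handle:
        handle.write("reference_gene\tsecondary_gene\n")
        for g in sorted(panel.bridge):
            handle.write(f"{g}\t{panel.bridge[g]}\n")

    manifest: dict = {
        "seed": panel.design.seed,
        "samples": {},
        "reference_proteome": "reference_proteome.faa",
        "terms": "terms.gmt",
        "reference_busco": "reference_busco.tsv",
        "sample_table": "samples.tsv",
        "bridge": "bridge.tsv",
    }
    for rec in panel.samples:
        sid = rec.sample_id
        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)
        write_fasta(panel.transcripts[sid], sdir / "transcripts.fasta")
        write_expression_table(panel.expression[sid], sdir / "expression.tsv")
        with open(sdir / "busco_full_table.tsv", "wt") as handle:
            handle.write("# busco_set\tstatus\tgene_id\n")
            status_of = {"C": "Complete", "D": "Duplicated", "F": "Fragmented", "M": "Missing"}
            for row in panel.busco_tables[sid]:
                gene = f"\t{row.gene_id}" if row.gene_id else ""
                handle.write(f"{row.busco_set}\t{status_of[row.category]}{gene}\n")
        write_blast_tabular(panel.blast_hits[sid], sdir / "blast_default.tsv")
        entry = {
            "transcripts": f"{sid}/transcripts.fasta",
            "expression": f"{sid}/expression.tsv",
            "busco": f"{sid}/busco_full_table.tsv",
            "blast": f"{sid}/blast_default.tsv",
        }
        if panel.blast_hits_b[sid]:
            write_blast_tabular(panel.blast_hits_b[sid], sdir / "blast_default_refB.tsv")
            entry["blast_b"] = f"{sid}/blast_default_refB.tsv"
        manifest["samples"][sid] = entry
    manifest_path = outdir / "panel_manifest.yaml"
    with open(manifest_path, "wt") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)
    return manifest_path


def _precision_recall(found: frozenset[str] | set[str], truth_set: frozenset[str]) -> tuple[float | None, float | None]:
    precision = len(set(found) & truth_set) / len(found) if found else None
    recall = len(set(found) & truth_set) / len(truth_set) if truth_set else None
    return precision, recall


def truth_report(
    truth: PanelTruth,
    annotations: Mapping[str, AnnotationMap],
    specific: Mapping[str, frozenset[str] | set[str]] | None = None,
    significant_terms: Sequence[str] | None = None,
) -> dict:
    """Score pipeline outputs against the planted ground truth.

    ``annotations`` maps sample_id -> AnnotationMap; ``specific`` maps group
    label (cold/hot) -> recovered specific gene set; ``significant_terms``
    lists term ids called significant. Metrics are fractions in [0, 1] with
    exact counts alongside; undefined ratios (empty truth sets) report None.
    """
    truth_samples = set(truth.divergence)
    if set(annotations) != truth_samples:
        raise ValueError(
            f"sample ids do not match the truth: got {sorted(annotations)}, expected {sorted(truth_samples)}"
        )
    n_correct = n_assigned = 0
    for sid, amap in annotations.items():
        for gene, ref in amap.assignments.items():
            n_assigned += 1
            if truth.ortholog_map.get((sid, gene)) == ref:
                n_correct += 1
    n_truth_expressed = sum(
        1 for (sid, gene) in truth.ortholog_map if gene in truth.expressed.get(sid, frozenset())
    )
    n_recovered = sum(
        1
        for (sid, gene), ref in truth.ortholog_map.items()
        if gene in truth.expressed.get(sid, frozenset()) and annotations[sid].assignments.get(gene) == ref
    )
    report: dict = {
        "annotation_accuracy": (n_correct / n_assigned) if n_assigned else None,
        "annotation_recall": (n_recovered / n_truth_expressed) if n_truth_expressed else None,
        "n_assigned": n_assigned,
        "n_correct": n_correct,
        "n_truth_expressed": n_truth_expressed,
    }
    if specific is not None:
        for group, truth_set in (("cold", truth.planted_cold), ("hot", truth.planted_hot)):
            found = frozenset(specific.get(group, frozenset()))
            precision, recall = _precision_recall(found, truth_set)
            report[f"{group}_specific_precision"] = precision
            report[f"{group}_specific_recall"] = recall
            report[f"n_{group}_specific_found"] = len(found)
            report[f"n_{group}_planted"] = len(truth_set)
    if significant_terms is not None:
        if truth.enriched_terms:
            hit = truth.enriched_terms & set(significant_terms)
            report["enriched_term_recall"] = len(hit) / len(truth.enriched_terms)
        else:
            report["enriched_term_recall"] = None
        report["n_enriched_terms_planted"] = len(truth.enriched_terms)
        report["n_significant_terms"] = len(set(significant_terms))
    return report
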