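"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: FASTA, BLAST tabular (outfmt 6, 12 columns), BUSCO-style full-table
TSV, GMT gene sets, sample metadata TSV, and two-column expression TSV.
All readers validate eagerly and raise :class:`FormatError` with the
offending line number where the format allows it.
"""

from __future__ import annotations

import gzip
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "FormatError",
    "SampleRecord",
    "BlastHit",
    "ExpressionTable",
    "OrthologAssignment",
    "TermDatabase",
    "read_fasta",
    "write_fasta",
    "read_blast_tabular",
    "write_blast_tabular",
    "read_busco_table",
    "read_sample_table",
    "read_expression_table",
    "write_expression_table",
    "read_gene_sets",
    "table1_fixture_path",
    "PROPERTY_ALIASES",
    "ORGAN_ALIASES",
]


class FormatError(ValueError):
    """A file violated the expected plain-text format."""


#: Property vocabulary normalization: the four traditional natures collapse
#: onto the binary cold/hot axis (cool is a mild cold, warm a mild hot).
PROPERTY_ALIASES: dict[str, str] = {
    "cold": "cold",
    "cool": "cold",
    "hot": "hot",
    "warm": "hot",
}

#: Organ normalization onto the four-class vocabulary used for grouping.
#: Rhizomes, tubers and shoot tips are modified stems; petals are flower parts.
ORGAN_ALIASES: dict[str, str] = {
    "root": "root",
    "roots": "root",
    "stem": "stem",
    "stems": "stem",
    "rhizome": "stem",
    "rhizomes": "stem",
    "tuber": "stem",
    "tubers": "stem",
    "shoot tip": "stem",
    "shoot tips": "stem",
    "leaf": "leaf",
    "leaves": "leaf",
    "flower": "flower",
    "flowers": "flower",
    "petal": "flower",
    "petals": "flower",
    "other": "other",
}

VALID_ORGANS = frozenset({"root", "stem", "leaf", "flower", "other"})
VALID_CLADES = frozenset({"dicot", "non_dicot"})
VALID_TERM_CATEGORIES = frozenset({"GO_BP", "GO_MF", "GO_CC", "KEGG"})

_BUSCO_STATUS = {
    "Complete": "C",
    "Duplicated": "D",
    "Fragmented": "F",
    "Missing": "M",
}


@dataclass(frozen=True)
class SampleRecord:
    """One herbal-medicine sample: species, property group, organ, clade."""

    sample_id: str
    species: str
    property: str  # "cold" | "hot"
    organ: str  # normalized: root/stem/leaf/flower/other
    clade: str  # "dicot" | "non_dicot"
    accession: str = ""

    def __post_init__(self) -> None:
        if self.property not in ("cold", "hot"):
            raise ValueError(f"invalid property {self.property!r} for sample {self.sample_id!r}")
        if self.organ not in VALID_ORGANS:
            raise ValueError(f"invalid organ {self.organ!r} for sample {self.sample_id!r}")
        if self.clade not in VALID_CLADES:
            raise ValueError(f"invalid clade {self.clade!r} for sample {self.sample_id!r}")


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column tabular homology-search output."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue} for hit {self.query_id}->{self.subject_id}")
        if self.aln_length < 1:
            raise ValueError(f"alignment length {self.aln_length} < 1")
        for name in ("q_start", "q_end", "s_start", "s_end"):
            if getattr(self, name) < 1:
                raise ValueError(f"coordinate {name} must be positive")


@dataclass
class ExpressionTable:
    """Per-sample gene-level expression in transcripts per million."""

    sample_id: str
    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, tpm in self.entries.items():
            if tpm < 0:
                raise ValueError(f"negative TPM {tpm} for gene {gene!r} in sample {self.sample_id!r}")


@dataclass(frozen=True)
class OrthologAssignment:
    """A gene's membership in a single-copy-ortholog set, with its category.

    ``category`` is one of C (complete single-copy), D (duplicated),
    F (fragmented), M (missing; ``gene_id`` empty).
    """

    gene_id: str
    busco_set: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in ("C", "D", "F", "M"):
            raise ValueError(f"invalid category {self.category!r}")


@dataclass
class TermDatabase:
    """Flat functional-term database: term id -> (name, category, members)."""

    terms: dict[str, tuple[str, str, frozenset[str]]] = field(default_factory=dict)

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][2]

    def category(self, term_id: str) -> str:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, _, members in self.terms.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercase sequence mapping.

    The id is the first whitespace-delimited token of the header line.
    Duplicate ids and sequence data before the first header are errors.
    """
    out: dict[str, str] = {}
    with _open_text(path) as handle:
        # SimpleFastaParser silently skips leading junk; enforce header-first.
        pos = handle.tell()
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}: line {lineno}: sequence data before first FASTA header")
            break
        handle.seek(pos)
        for header, seq in SimpleFastaParser(handle):
            seq_id = header.split()[0] if header.split() else ""
            if not seq_id:
                raise FormatError(f"{path}: empty FASTA header")
            if seq_id in out:
                raise FormatError(f"{path}: duplicate FASTA id {seq_id!r}")
            out[seq_id] = seq.upper()
    return out


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences in input order, wrapping at ``width`` columns."""
    with open(path, "wt") as handle:
        for seq_id, seq in records.items():
            handle.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)


def read_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Parse standard 12-column tabular homology-search output."""
    hits: list[BlastHit] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}")
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_tabular(hits: Iterable[BlastHit], path: str | Path) -> None:
    """Serialize hits back to 12-column tabular text.

    E-values are written with 17 significant digits so that read/write
    round-trips are lossless at double precision.
    """
    with open(path, "wt") as handle:
        for h in hits:
            handle.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.17g}",
                        f"{h.bit_score:.17g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BUSCO-style full table


def read_busco_table(path: str | Path) -> list[OrthologAssignment]:
    """Read a BUSCO-style classification table.

    Expected columns: busco_set_id, status, gene_id (gene absent for
    ``Missing`` rows). ``#`` lines are comments. Statuses map onto the
    single-letter categories C/D/F/M.
    """
    out: list[OrthologAssignment] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected at least 2 columns")
            busco_set, status = fields[0], fields[1]
            if status not in _BUSCO_STATUS:
                raise FormatError(f"{path}: line {lineno}: unknown status {status!r}")
            category = _BUSCO_STATUS[status]
            gene_id = fields[2] if len(fields) > 2 and category != "M" else ""
            if category != "M" and not gene_id:
                raise FormatError(f"{path}: line {lineno}: status {status!r} requires a gene id")
            out.append(OrthologAssignment(gene_id=gene_id, busco_set=busco_set, category=category))
    return out


# ---------------------------------------------------------------------------
# Sample metadata


def read_sample_table(
    path: str | Path,
    *,
    strict: bool = False,
    organ_aliases: Mapping[str, str] | None = None,
) -> list[SampleRecord]:
    """Read a tab-separated sample metadata table with a header row.

    Required columns: sample_id, species, property, organ, clade;
    optional: accession. Property values warm/cool normalize to hot/cold and
    organ synonyms (rhizomes, tubers, shoot tip, petals, ...) normalize onto
    the four-class vocabulary, unless ``strict`` is set, in which case only
    already-normalized values are accepted.
    """
    aliases = dict(ORGAN_ALIASES if organ_aliases is None else organ_aliases)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        header_line = handle.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file")
        header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
        required = {"sample_id", "species", "property", "organ", "clade"}
        missing = required - set(header)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        idx = {name: header.index(name) for name in header}
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise FormatError(f"{path}: line {lineno}: expected {len(header)} columns")

            def get(col: str) -> str:
                return fields[idx[col]].strip()

            sample_id = get("sample_id")
            if not sample_id:
                raise FormatError(f"{path}: line {lineno}: empty sample_id")
            if sample_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate sample_id {sample_id!r}")
            seen.add(sample_id)

            raw_prop = get("property").lower()
            if strict:
                if raw_prop not in ("cold", "hot"):
                    raise FormatError(f"{path}: line {lineno}: unknown property {raw_prop!r} (strict mode)")
                prop = raw_prop
            else:
                if raw_prop not in PROPERTY_ALIASES:
                    raise FormatError(f"{path}: line {lineno}: unknown property {raw_prop!r}")
                prop = PROPERTY_ALIASES[raw_prop]

            raw_organ = get("organ").lower()
            if strict:
                if raw_organ not in VALID_ORGANS:
                    raise FormatError(f"{path}: line {lineno}: unknown organ {raw_organ!r} (strict mode)")
                organ = raw_organ
            else:
                if raw_organ not in aliases:
                    raise FormatError(f"{path}: line {lineno}: unknown organ {raw_organ!r}")
                organ = aliases[raw_organ]

            clade = get("clade").lower().replace("-", "_")
            if clade not in VALID_CLADES:
                raise FormatError(f"{path}: line {lineno}: unknown clade {clade!r}")

            accession = get("accession") if "accession" in idx else ""
            try:
                records.append(
                    SampleRecord(
                        sample_id=sample_id,
                        species=get("species"),
                        property=prop,
                        organ=organ,
                        clade=clade,
                        accession=accession,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def table1_fixture_path() -> Path:
    """Path to the bundled 20-sample study metadata table."""
    return Path(str(importlib.resources.files("hmannot").joinpath("data/table1_samples.tsv")))


# ---------------------------------------------------------------------------
# Expression TSV


def read_expression_table(path: str | Path, sample_id: str | None = None) -> ExpressionTable:
    """Read a two-column ``gene_id<TAB>tpm`` table with a header row."""
    entries: dict[str, float] = {}
    with _open_text(path) as handle:
        header = handle.readline()
        if not header:
            raise FormatError(f"{path}: empty file")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            gene, raw_tpm = fields
            if gene in entries:
                raise FormatError(f"{path}: line {lineno}: duplicate gene id {gene!r}")
            try:
                tpm = float(raw_tpm)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad TPM value {raw_tpm!r}") from exc
            if tpm < 0:
                raise FormatError(f"{path}: line {lineno}: negative TPM {tpm}")
            entries[gene] = tpm
    if sample_id is None:
        sample_id = Path(path).stem
    return ExpressionTable(sample_id=sample_id, entries=entries)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    with open(path, "wt") as handle:
        handle.write("gene_id\ttpm\n")
        for gene, tpm in table.entries.items():
            handle.write(f"{gene}\t{tpm:.17g}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path: str | Path) -> TermDatabase:
    """Read a GMT file (term_id, description, members...).

    The description carries the ontology category as a ``CATEGORY|name``
    prefix, e.g. ``GO_BP|lipid modification``; a bare description defaults
    to GO_BP. Terms must have at least one member and unique ids.
    """
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise FormatError(f"{path}: line {lineno}: term with zero members")
            term_id, desc = fields[0], fields[1]
            if term_id in terms:
                raise FormatError(f"{path}: line {lineno}: duplicate term id {term_id!r}")
            if "|" in desc:
                category, name = desc.split("|", 1)
            else:
                category, name = "GO_BP", desc
            if category not in VALID_TERM_CATEGORIES:
                raise FormatError(f"{path}: line {lineno}: unknown term category {category!r}")
            members = frozenset(f.strip() for f in fields[2:] if f.strip())
            terms[term_id] = (name, category, members)
    return TermDatabase(terms=terms)


def write_gene_sets(db: TermDatabase, path: str | Path) -> None:
    with open(path, "wt") as handle:
        for term_id, (name, category, members) in db.terms.items():
            handle.write("\t".join([term_id, f"{category}|{name}", *sorted(members)]) + "\n")
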