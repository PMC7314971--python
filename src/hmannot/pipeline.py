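"""End-to-end orchestration: candidates -> calibration -> annotation ->
group sets -> enrichment -> between-group statistics.

Each stage reads its inputs from disk and persists its outputs as TSV under
the configured output directory, so downstream stages can be re-run from
intermediates and the whole run is auditable through a YAML manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

import hmannot
from hmannot import annotation as ann
from hmannot import calibration as cal
from hmannot import candidate_genes as cand
from hmannot import enrichment as enr
from hmannot import group_sets as gs
from hmannot import group_stats as gstat
from hmannot import io_formats as io
from hmannot import synthetic_data as syn

__all__ = ["PipelineConfig", "run_pipeline", "run_synthetic"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    sample_table: Path
    reference_fasta: Path
    reference_busco: Path
    term_gmt: Path
    #: sample_id -> {"transcripts": ..., "expression": ..., "busco": ...,
    #: "blast": ..., optional "blast_b": ...}
    per_sample: dict[str, dict[str, Path]]
    outdir: Path
    bridge: Path | None = None
    tpm_threshold: float = 1.0
    min_aa: int = 50
    isoform_sep: str = "_i"
    kappa_threshold: float = 0.3
    min_overlap: int = 3
    min_factor: float = 1.5
    max_p: float = 0.01
    fdr_alpha: float = 0.05
    zero_floor: float = 1e-180
    seed: int | None = None

    def __post_init__(self) -> None:
        self.sample_table = Path(self.sample_table)
        self.reference_fasta = Path(self.reference_fasta)
        self.reference_busco = Path(self.reference_busco)
        self.term_gmt = Path(self.term_gmt)
        self.outdir = Path(self.outdir)
        if self.bridge is not None:
            self.bridge = Path(self.bridge)
        self.per_sample = {
            sid: {k: Path(v) for k, v in entry.items()} for sid, entry in self.per_sample.items()
        }

    def validate(self) -> None:
        """Check every referenced input path before any computation."""
        missing = []
        for p in [self.sample_table, self.reference_fasta, self.reference_busco, self.term_gmt]:
            if not p.exists():
                missing.append(str(p))
        if self.bridge is not None and not self.bridge.exists():
            missing.append(str(self.bridge))
        for sid, entry in self.per_sample.items():
            for key in ("transcripts", "expression", "busco", "blast"):
                if key not in entry:
                    raise ValueError(f"sample {sid!r}: missing input kind {key!r}")
            for p in entry.values():
                if not p.exists():
                    missing.append(str(p))
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        per_sample = {
            sid: {k: resolve(v) for k, v in entry.items()} for sid, entry in raw.pop("samples").items()
        }
        paths = {k: resolve(raw.pop(k)) for k in ("sample_table", "reference_fasta", "reference_busco", "term_gmt")}
        bridge = raw.pop("bridge", None)
        outdir = resolve(raw.pop("outdir"))
        return cls(
            per_sample=per_sample,
            bridge=resolve(bridge) if bridge else None,
            outdir=outdir,
            **paths,
            **raw,
        )

    def to_yaml(self, path: str | Path) -> None:
        base = Path(path).parent

        def rel(p: Path | None):
            if p is None:
                return None
            try:
                return str(p.relative_to(base))
            except ValueError:
                return str(p)

        raw = {
            "sample_table": rel(self.sample_table),
            "reference_fasta": rel(self.reference_fasta),
            "reference_busco": rel(self.reference_busco),
            "term_gmt": rel(self.term_gmt),
            "outdir": rel(self.outdir),
            "samples": {
                sid: {k: rel(v) for k, v in entry.items()} for sid, entry in self.per_sample.items()
            },
            "tpm_threshold": self.tpm_threshold,
            "min_aa": self.min_aa,
            "isoform_sep": self.isoform_sep,
            "kappa_threshold": self.kappa_threshold,
            "min_overlap": self.min_overlap,
            "min_factor": self.min_factor,
            "max_p": self.max_p,
            "fdr_alpha": self.fdr_alpha,
            "zero_floor": self.zero_floor,
        }
        if self.bridge is not None:
            raw["bridge"] = rel(self.bridge)
        if self.seed is not None:
            raw["seed"] = self.seed
        with open(path, "wt") as handle:
            yaml.safe_dump(raw, handle, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names stage and sample."""


def _stage(name: str, sample: str = ""):
    def wrap(exc: Exception) -> StageError:
        where = f"stage {name!r}" + (f", sample {sample!r}" if sample else "")
        return StageError(f"{where}: {exc}")

    return wrap


# ---------------------------------------------------------------------------
# stages


def stage_candidates(config: PipelineConfig) -> dict[str, dict[str, cand.CandidateProtein]]:
    """TPM filter + ORF extraction per sample; persists candidate tables."""
    out: dict[str, dict[str, cand.CandidateProtein]] = {}
    cdir = config.outdir / "candidates"
    cdir.mkdir(parents=True, exist_ok=True)
    for sid, entry in config.per_sample.items():
        try:
            expr = io.read_expression_table(entry["expression"], sample_id=sid)
            transcripts = io.read_fasta(entry["transcripts"])
            candidates = cand.candidate_proteins(
                transcripts,
                expr,
                tpm_threshold=config.tpm_threshold,
                min_aa=config.min_aa,
                isoform_sep=config.isoform_sep,
            )
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise _stage("candidates", sid)(exc) from exc
        out[sid] = candidates
        with open(cdir / f"{sid}.tsv", "wt") as handle:
            handle.write("locus\ttranscript\tframe\torf_start\torf_end\tprotein_length\n")
            for locus in sorted(candidates):
                c = candidates[locus]
                handle.write(f"{locus}\t{c.gene_id}\t{c.source_frame}\t{c.orf_start}\t{c.orf_end}\t{len(c.protein)}\n")
        io.write_fasta(
            {locus: candidates[locus].protein for locus in sorted(candidates)},
            cdir / f"{sid}.faa",
        )
        log.info("stage candidates, sample %s: %d candidate proteins", sid, len(candidates))
    return out


def _load_candidate_loci(config: PipelineConfig, sid: str) -> set[str]:
    path = config.outdir / "candidates" / f"{sid}.tsv"
    loci = set()
    with open(path) as handle:
        handle.readline()
        for line in handle:
            if line.strip():
                loci.add(line.split("\t", 1)[0])
    return loci


def _reference_busco_map(config: PipelineConfig) -> dict[str, str]:
    return {
        a.busco_set: a.gene_id
        for a in io.read_busco_table(config.reference_busco)
        if a.category == "C"
    }


def stage_calibrate(config: PipelineConfig) -> cal.CutoffTable:
    """Single-copy ortholog pairing and per-sample cutoff derivation."""
    ref_map = _reference_busco_map(config)
    table = cal.CutoffTable()
    for sid, entry in config.per_sample.items():
        try:
            loci = _load_candidate_loci(config, sid)
            assignments = [
                a
                for a in io.read_busco_table(entry["busco"])
                if a.category != "C" or a.gene_id in loci
            ]
            pairs = cal.busco_gene_pairs(assignments, ref_map, sample_id=sid)
            hits = [h for h in io.read_blast_tabular(entry["blast"]) if h.query_id in loci]
            cutoff, n_used = cal.calibrate_cutoff(pairs, hits, sample_id=sid)
        except Exception as exc:  # noqa: BLE001
            raise _stage("calibrate", sid)(exc) from exc
        table.add(sid, cutoff, n_used, zero_floor=config.zero_floor)
        log.info(
            "stage calibrate, sample %s: cutoff %.3g (-log10 %.1f) from %d pairs",
            sid,
            cutoff,
            table.neg_log10[sid],
            n_used,
        )
    table.write_tsv(config.outdir / "cutoffs.tsv")
    return table


def _load_cutoffs(config: PipelineConfig) -> dict[str, float]:
    cutoffs = {}
    with open(config.outdir / "cutoffs.tsv") as handle:
        handle.readline()
        for line in handle:
            if line.strip():
                sid, ev, _, _ = line.rstrip("\n").split("\t")
                cutoffs[sid] = float(ev)
    return cutoffs


def stage_annotate(config: PipelineConfig) -> dict[str, ann.AnnotationMap]:
    """Cutoff-filtered best-hit annotation; dual-reference concordance."""
    cutoffs = _load_cutoffs(config)
    adir = config.outdir / "annotations"
    adir.mkdir(parents=True, exist_ok=True)
    bridge: dict[str, str] | None = None
    if config.bridge is not None:
        bridge = {}
        with open(config.bridge) as handle:
            handle.readline()
            for line in handle:
                if line.strip():
                    a, b = line.rstrip("\n").split("\t")
                    bridge[a] = b
    maps: dict[str, ann.AnnotationMap] = {}
    concordance_rows = []
    for sid, entry in config.per_sample.items():
        try:
            loci = _load_candidate_loci(config, sid)
            hits = [h for h in io.read_blast_tabular(entry["blast"]) if h.query_id in loci]
            surviving = ann.apply_cutoff(hits, cutoffs[sid])
            amap = ann.assign_annotations(surviving, sample_id=sid)
            maps[sid] = amap
            amap.write_tsv(adir / f"{sid}.tsv")
            log.info(
                "stage annotate, sample %s: %d of %d candidate genes annotated, %d distinct reference genes",
                sid,
                len(amap.assignments),
                len(loci),
                len(amap.matched_reference),
            )
            if bridge is not None and "blast_b" in entry:
                hits_b = [h for h in io.read_blast_tabular(entry["blast_b"]) if h.query_id in loci]
                amap_b = ann.assign_annotations(ann.apply_cutoff(hits_b, cutoffs[sid]), sample_id=sid)
                rate, denom = ann.concordance_rate(amap, amap_b, bridge)
                concordance_rows.append((sid, rate, denom))
        except Exception as exc:  # noqa: BLE001
            raise _stage("annotate", sid)(exc) from exc
    if concordance_rows:
        with open(config.outdir / "concordance.tsv", "wt") as handle:
            handle.write("sample_id\tconcordance\tn_genes_in_both\n")
            for sid, rate, denom in concordance_rows:
                rate_s = "NA" if rate is None else f"{rate:.6g}"
                handle.write(f"{sid}\t{rate_s}\t{denom}\n")
    return maps


def _load_annotations(config: PipelineConfig) -> dict[str, ann.AnnotationMap]:
    maps: dict[str, ann.AnnotationMap] = {}
    for sid in config.per_sample:
        amap = ann.AnnotationMap(sample_id=sid)
        with open(config.outdir / "annotations" / f"{sid}.tsv") as handle:
            handle.readline()
            for line in handle:
                if line.strip():
                    _, gene, ref, _, _ = line.rstrip("\n").split("\t")
                    amap.assignments[gene] = ref
        maps[sid] = amap
    return maps


def stage_groups(config: PipelineConfig) -> dict:
    """Specific sets per grouping, Venn regions and the hit-count matrix."""
    samples = io.read_sample_table(config.sample_table)
    maps = _load_annotations(config)
    matched = {sid: frozenset(m.matched_reference) for sid, m in maps.items()}
    universe = frozenset().union(*matched.values()) if matched else frozenset()
    gdir = config.outdir / "groups"
    gdir.mkdir(parents=True, exist_ok=True)

    by_id = {s.sample_id: s for s in samples if s.sample_id in matched}
    results: dict = {"universe_size": len(universe)}
    for grouping_name, key in (("property", "property"), ("organ", "organ"), ("clade", "clade")):
        grouping = {sid: getattr(by_id[sid], key) for sid in by_id}
        if len(set(grouping.values())) < 2:
            log.info("stage groups: grouping %s has one level, skipped", grouping_name)
            continue
        try:
            spec = gs.GroupSpec(grouping=grouping, universe=universe)
            specific, shared = gs.specific_sets(matched, spec)
        except Exception as exc:  # noqa: BLE001
            raise _stage("groups")(exc) from exc
        with open(gdir / f"specific_{grouping_name}.tsv", "wt") as handle:
            handle.write("group\treference_gene\n")
            for group in sorted(specific):
                for gene in sorted(specific[group]):
                    handle.write(f"{group}\t{gene}\n")
        results[grouping_name] = {"specific": specific, "shared": shared}
        log.info(
            "stage groups (%s): %s specific, %d shared",
            grouping_name,
            {g: len(v) for g, v in sorted(specific.items())},
            len(shared),
        )
        # Venn over per-group union sets (2-4 groups)
        group_union: dict[str, set] = {}
        for sid, genes in matched.items():
            group_union.setdefault(grouping[sid], set()).update(genes)
        if 2 <= len(group_union) <= 4:
            venn = gs.venn_counts(group_union)
            with open(gdir / f"venn_{grouping_name}.tsv", "wt") as handle:
                handle.write("region\tcount\n")
                for region in sorted(venn):
                    handle.write(f"{'&'.join(region)}\t{venn[region]}\n")
            results[grouping_name]["venn"] = venn
        if len(set(grouping.values())) == 2:
            matrix = gs.hit_count_matrix(
                {sid: maps[sid].assignments for sid in maps}, gs.GroupSpec(grouping=grouping, universe=universe)
            )
            with open(gdir / f"hit_matrix_{grouping_name}.tsv", "wt") as handle:
                handle.write("n_group1\tn_group2\tcount\n")
                for (i, j) in sorted(matrix):
                    handle.write(f"{i}\t{j}\t{matrix[(i, j)]}\n")
            results[grouping_name]["hit_matrix"] = matrix
    return results


def _load_specific(config: PipelineConfig, grouping_name: str) -> dict[str, frozenset[str]]:
    path = config.outdir / "groups" / f"specific_{grouping_name}.tsv"
    out: dict[str, set[str]] = {}
    with open(path) as handle:
        handle.readline()
        for line in handle:
            if line.strip():
                group, gene = line.rstrip("\n").split("\t")
                out.setdefault(group, set()).add(gene)
    return {g: frozenset(v) for g, v in out.items()}


def stage_enrich(config: PipelineConfig, grouping_name: str = "property") -> list[enr.EnrichmentRecord]:
    """Enrichment of the group-specific gene lists with clustering/network."""
    terms = io.read_gene_sets(config.term_gmt)
    background = frozenset(io.read_fasta(config.reference_fasta))
    specific = _load_specific(config, grouping_name)
    filters = enr.EnrichmentFilters(
        min_overlap=config.min_overlap, min_factor=config.min_factor, max_p=config.max_p
    )
    edir = config.outdir / "enrichment"
    edir.mkdir(parents=True, exist_ok=True)

    per_group: dict[str, list[enr.EnrichmentRecord]] = {}
    for group in sorted(specific):
        if not specific[group]:
            log.info("stage enrich: group %s has an empty specific set, skipped", group)
            continue
        try:
            records = enr.enrich(specific[group], terms, background, filters)
        except Exception as exc:  # noqa: BLE001
            raise _stage("enrich", group)(exc) from exc
        per_group[group] = records
        enr.write_enrichment_tsv(records, edir / f"{grouping_name}_{group}.tsv")
        n_pass = sum(r.passed_filters for r in records)
        log.info("stage enrich, list %s: %d terms tested, %d pass filters", group, len(records), n_pass)

    # combined clustering over the union of passing terms; a term passing in
    # both lists keeps its better-p record and is sourced "both"
    combined: dict[str, enr.EnrichmentRecord] = {}
    sources: dict[str, str] = {}
    for group, records in per_group.items():
        for r in records:
            if not r.passed_filters:
                continue
            if r.term_id in combined:
                sources[r.term_id] = "both"
                if r.p_value < combined[r.term_id].p_value:
                    combined[r.term_id] = r
            else:
                combined[r.term_id] = r
                sources[r.term_id] = group
    records = sorted(combined.values(), key=lambda r: (r.p_value, r.term_id))
    if records:
        records = enr.cluster_terms(records, terms, background, kappa_threshold=config.kappa_threshold)
        records = enr.select_representatives(records)
        mat = enr.kappa_matrix(records, terms, background)
        nodes, edges = enr.export_network(records, mat, edge_threshold=config.kappa_threshold, sources=sources)
        enr.write_enrichment_tsv(records, edir / f"{grouping_name}_clustered.tsv")
        enr.write_network_tsv(nodes, edges, edir / "network_nodes.tsv", edir / "network_edges.tsv")
        log.info("stage enrich: %d clustered terms, %d network nodes, %d edges", len(records), len(nodes), len(edges))
    return records


def _assembly_metrics(transcripts: Mapping[str, str]) -> dict[str, float]:
    lengths = sorted((len(s) for s in transcripts.values()), reverse=True)
    total = sum(lengths)
    half, acc, n50 = total / 2, 0, 0
    for ln in lengths:
        acc += ln
        if acc >= half:
            n50 = ln
            break
    gc = sum(s.count("G") + s.count("C") for s in transcripts.values())
    return {
        "n_transcripts": float(len(lengths)),
        "mean_length": total / len(lengths) if lengths else 0.0,
        "n50": float(n50),
        "gc_content": gc / total if total else 0.0,
    }


def stage_stats(config: PipelineConfig) -> list[gstat.StatTestResult]:
    """Cold-vs-hot comparison of per-sample assembly/annotation metrics."""
    samples = io.read_sample_table(config.sample_table)
    maps = _load_annotations(config)
    grouping = {s.sample_id: s.property for s in samples if s.sample_id in maps}
    metrics: dict[str, dict[str, float]] = {}
    for sid, entry in config.per_sample.items():
        try:
            tx = io.read_fasta(entry["transcripts"])
            vals = _assembly_metrics(tx)
            vals["n_annotated"] = float(len(maps[sid].assignments))
            vals["n_matched_reference"] = float(len(maps[sid].matched_reference))
        except Exception as exc:  # noqa: BLE001
            raise _stage("stats", sid)(exc) from exc
        for k, v in vals.items():
            metrics.setdefault(k, {})[sid] = v
    spec = gs.GroupSpec(grouping=grouping, universe=frozenset())
    results = gstat.compare_groups(metrics, spec)
    gstat.write_stats_tsv(results, config.outdir / "group_stats.tsv")
    for r in results:
        log.info("stage stats: %s via %s, p=%.4g", r.variable, r.test_used, r.p_value)
    return results


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest."""
    config.validate()
    config.outdir.mkdir(parents=True, exist_ok=True)
    candidates = stage_candidates(config)
    cutoffs = stage_calibrate(config)
    annotations = stage_annotate(config)
    groups = stage_groups(config)
    enr_records = stage_enrich(config)
    stats = stage_stats(config)

    manifest = {
        "version": hmannot.__version__,
        "seed": config.seed,
        "parameters": {
            "tpm_threshold": config.tpm_threshold,
            "min_aa": config.min_aa,
            "kappa_threshold": config.kappa_threshold,
            "min_overlap": config.min_overlap,
            "min_factor": config.min_factor,
            "max_p": config.max_p,
            "fdr_alpha": config.fdr_alpha,
            "zero_floor": config.zero_floor,
        },
        "inputs": {
            "sample_table": str(config.sample_table),
            "reference_fasta": str(config.reference_fasta),
            "term_gmt": str(config.term_gmt),
            "n_samples": len(config.per_sample),
        },
        "counts": {
            "candidates": {sid: len(c) for sid, c in candidates.items()},
            "cutoff_neg_log10": {sid: round(v) for sid, v in cutoffs.neg_log10.items()},
            "annotated": {sid: len(m.assignments) for sid, m in annotations.items()},
            "matched_universe": groups.get("universe_size", 0),
            "enriched_terms_passing": sum(r.passed_filters for r in enr_records),
            "significant_stats": [r.variable for r in stats if r.significant],
        },
        "outputs": sorted(
            str(p.relative_to(config.outdir)) for p in config.outdir.rglob("*.tsv")
        ),
    }
    with open(config.outdir / "manifest.yaml", "wt") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)
    return manifest


def run_synthetic(design: syn.PanelDesign, outdir: str | Path, **config_overrides) -> tuple[dict, dict]:
    """Generate a panel, run the pipeline on it and score recovery.

    Returns ``(manifest, recovery_metrics)``; both are also written under
    ``outdir`` (inputs under ``inputs/``, stage outputs under ``run/``).
    """
    outdir = Path(outdir)
    reference, terms = syn.simulate_reference(design)
    panel = syn.simulate_panel(reference, terms, design)
    indir = outdir / "inputs"
    syn.write_panel(panel, indir)
    config = PipelineConfig(
        sample_table=indir / "samples.tsv",
        reference_fasta=indir / "reference_proteome.faa",
        reference_busco=indir / "reference_busco.tsv",
        term_gmt=indir / "terms.gmt",
        bridge=indir / "bridge.tsv" if design.dual_reference else None,
        per_sample={
            sid: {
                "transcripts": indir / sid / "transcripts.fasta",
                "expression": indir / sid / "expression.tsv",
                "busco": indir / sid / "busco_full_table.tsv",
                "blast": indir / sid / "blast_default.tsv",
                **(
                    {"blast_b": indir / sid / "blast_default_refB.tsv"}
                    if design.dual_reference
                    else {}
                ),
            }
            for sid in design.sample_ids
        },
        outdir=outdir / "run",
        seed=design.seed,
        **config_overrides,
    )
    manifest = run_pipeline(config)

    annotations = _load_annotations(config)
    specific = _load_specific(config, "property")
    clustered = config.outdir / "enrichment"
    significant: list[str] = []
    for group_file in sorted(clustered.glob("property_*.tsv")):
        if group_file.stem.endswith("clustered"):
            continue
        with open(group_file) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            for line in handle:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                if row["passed_filters"] == "1" and float(row["fdr"]) < config.fdr_alpha:
                    significant.append(row["term_id"])
    metrics = syn.truth_report(panel.truth, annotations, specific, significant)
    with open(outdir / "recovery.yaml", "wt") as handle:
        yaml.safe_dump(metrics, handle, sort_keys=True)
    return manifest, metrics
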