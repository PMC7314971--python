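"""Shared plumbing for the numbered analysis drivers.

The study design is fixed here once: a 10 cold + 10 hot panel over 1,000
reference genes with divergence-graded E-values (seed 42). Every driver
re-derives the same design deterministically, so the scripts can be run in
order, each picking up the previous one's outputs under ``results/``.
"""

from pathlib import Path

from hmannot.pipeline import PipelineConfig
from hmannot.synthetic_data import PanelDesign

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
PANEL_DIR = RESULTS / "panel"
RUN_DIR = RESULTS / "run"

SEED = 42


def study_design() -> PanelDesign:
    return PanelDesign(seed=SEED)


def study_config() -> PipelineConfig:
    design = study_design()
    indir = PANEL_DIR
    return PipelineConfig(
        sample_table=indir / "samples.tsv",
        reference_fasta=indir / "reference_proteome.faa",
        reference_busco=indir / "reference_busco.tsv",
        term_gmt=indir / "terms.gmt",
        bridge=indir / "bridge.tsv",
        per_sample={
            sid: {
                "transcripts": indir / sid / "transcripts.fasta",
                "expression": indir / sid / "expression.tsv",
                "busco": indir / sid / "busco_full_table.tsv",
                "blast": indir / sid / "blast_default.tsv",
                "blast_b": indir / sid / "blast_default_refB.tsv",
            }
            for sid in design.sample_ids
        },
        outdir=RUN_DIR,
        seed=SEED,
    )
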