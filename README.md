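# hmannot — cross-species conserved-gene annotation for non-model plant transcriptomes

Comparing gene content across distantly related plants — here, medicinal
plants classified as *cold*- or *hot*-propertied in traditional Chinese
medicine — is hard because most of the species have no annotated genome. A
fixed homology-search E-value cutoff is either too strict for distant
relatives of the reference or too permissive for close ones. `hmannot`
implements an ortholog-calibrated alternative and the comparative analysis
built on top of it:

1. **Candidate genes.** Per sample, keep genes with TPM > 1 and extract the
   longest complete ORF (ATG…stop, six frames) of each locus as its
   candidate protein.
2. **Ortholog gene pairs.** Genes classified *Complete single-copy* (category
   C) in a BUSCO-style assessment share an ortholog set with exactly one
   reference gene; each such (species gene, reference gene) pair is a
   confirmed homolog.
3. **Per-species cutoff.** Collect the default-parameter BLASTP E-values of
   the confirmed pairs; the species' cutoff is their **maximum** —
   the weakest E-value at which a confirmed ortholog was still found, so
   distant species automatically get looser cutoffs.
4. **Annotation and group-specific genes.** Apply the cutoff (inclusive),
   assign each species gene its best hit (minimum E-value, ties by bit
   score), and call a reference gene *group-specific* when only samples of
   one group (cold/hot, one organ, one clade) matched it.
5. **Enrichment modules.** Group-specific sets are tested per term by the
   upper-tail hypergeometric p, P(X ≥ k) for X ~ Hypergeom(N, K, m), with
   enrichment factor (k/m)/(K/N); filters k ≥ 3, factor > 1.5, p < 0.01 and
   BH FDR per ontology category; passing terms are clustered by Cohen's
   kappa over gene memberships (average linkage, tree cut at κ = 0.3) and
   exported as a representative-term network.
6. **Group statistics.** Per-sample metrics are compared cold vs hot through
   a decision tree: Shapiro–Wilk normality, then F-test variance
   homogeneity routing to Student's t or Welch's t; non-normal metrics use
   Mann–Whitney U (two-tailed, α = 0.05).

Real runs consume standard formats (FASTA, 12-column BLAST tabular,
BUSCO-style tables, GMT, TSV). Because the original 20 SRA transcriptomes
are not desk-scale inputs, the package ships a synthetic-data generator
that emulates the study design with known ground truth — planted
group-specific genes, planted enriched terms, and E-values whose magnitude
worsens linearly with divergence — so every stage can be validated by exact
recovery.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
panel (results land under `results/`):

```bash
python analysis/01_simulate_panel.py      # 10 cold + 10 hot species, 1,000 reference genes
python analysis/02_calibrate_cutoffs.py   # candidates + per-species cutoffs
python analysis/03_annotate_genes.py
python analysis/04_group_specific_sets.py
python analysis/05_enrichment_modules.py
python analysis/06_group_statistics.py
python analysis/07_noiseless_recovery.py  # exact-recovery scoring
```

`02_calibrate_cutoffs.py` prints the calibrated cutoff per species next to
its true divergence `d` (excerpt):

```
sample   divergence  -log10(cutoff)  pairs  candidates
cold1          0.06            88.6    233         776
cold5          0.46            55.1    232         772
cold10         0.95             7.1    230         766
hot10          1.00             3.9    226         753

Spearman(divergence, -log10 cutoff) = -0.998 (more divergent species get looser cutoffs)
```

The closest species keeps a stringent cutoff (−log10 E ≈ 89) and the most
distant a loose one (≈ 4); the rank agreement with divergence is near
perfect. `04_group_specific_sets.py` then reports:

```
property-specific genes — cold: 40, hot: 25; shared by 2+ groups: 935
```

exactly the planted 40 cold-specific and 25 hot-specific genes, and
`05_enrichment_modules.py` finds precisely the four planted functional
modules (e.g. `T0000 … k=33/K=41, factor=20.1, p=2.49e-47, FDR=4.24e-46`).
On the noiseless twin (`07_noiseless_recovery.py`) every recovery metric —
annotation accuracy and recall, specific-set precision/recall, enriched-term
recall — equals 1.0 over 19,350 assignments.

The same stages are available as a CLI (`hmannot simulate|calibrate|
annotate|groups|enrich|stats|run`) over a YAML config, and as library
functions (`hmannot.calibrate_cutoff`, `hmannot.enrich`, …) for use on real
data.

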