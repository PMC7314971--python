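"""Functional-module enrichment of the cold/hot-specific gene sets.

Hypergeometric over-representation against the full reference gene
background (filters: overlap >= 3, enrichment factor > 1.5, p < 0.01;
BH FDR per ontology category), kappa-similarity clustering of the passing
terms at threshold 0.3, and export of the representative-term network.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RUN_DIR, study_config

from hmannot.pipeline import stage_enrich


def main() -> None:
    config = study_config()
    records = stage_enrich(config)

    passing = [r for r in records if r.passed_filters]
    reps = [r for r in records if r.is_representative]
    clusters = {r.cluster_id for r in records if r.cluster_id is not None}
    print(f"terms passing all filters: {len(passing)} in {len(clusters)} kappa clusters")
    print(f"representative terms flagged: {len(reps)}")
    print("\ntop terms by p-value:")
    for r in sorted(passing, key=lambda r: r.p_value)[:8]:
        print(
            f"  {r.term_id} [{r.category}] {r.name}: k={r.k}/K={r.K}, "
            f"factor={r.enrichment_factor:.1f}, p={r.p_value:.3g}, FDR={r.fdr:.3g}, "
            f"cluster {r.cluster_id}"
        )
    edges = (RUN_DIR / "enrichment" / "network_edges.tsv").read_text().strip().splitlines()[1:]
    print(f"\nnetwork: {len(reps)} nodes, {len(edges)} kappa > 0.3 edges")


if __name__ == "__main__":
    main()
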