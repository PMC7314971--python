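"""Group-specific reference genes: property, organ and clade groupings.

A reference gene is group-specific when only samples of that group matched
it. Reports the cold/hot-specific counts, the Venn regions of the organ
grouping, and the cold-vs-hot hit-count matrix whose margins tie back to
the specific sets.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import study_config

from hmannot.pipeline import stage_groups


def main() -> None:
    config = study_config()
    results = stage_groups(config)
    print(f"matched reference universe: {results['universe_size']} genes")
    for grouping in ("property", "organ", "clade"):
        if grouping not in results:
            continue
        specific = results[grouping]["specific"]
        shared = results[grouping]["shared"]
        sizes = ", ".join(f"{g}: {len(s)}" for g, s in sorted(specific.items()))
        print(f"\n{grouping}-specific genes — {sizes}; shared by 2+ groups: {len(shared)}")
        if "venn" in results[grouping] and grouping == "organ":
            venn = results[grouping]["venn"]
            full = max(venn, key=len)
            print(f"  genes matched in all four organ groups: {venn[full]}")
    matrix = results["property"].get("hit_matrix", {})
    diag = sum(v for (i, j), v in matrix.items() if i == j)
    print(f"\ncold/hot hit-count matrix: {len(matrix)} occupied cells, "
          f"{diag} reference genes hit equally often by both groups")


if __name__ == "__main__":
    main()
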