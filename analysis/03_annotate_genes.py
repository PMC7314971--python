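"""Stage 4: cutoff-filtered best-hit annotation and dual-reference check.

Applies each species' calibrated cutoff to its homology hits, assigns every
surviving gene the reference gene of its best hit, and validates the
annotation by re-annotating against a second reference and counting
agreements through the between-reference ortholog bridge.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RUN_DIR, study_config

from hmannot.pipeline import stage_annotate


def main() -> None:
    config = study_config()
    maps = stage_annotate(config)

    universe = set()
    for amap in maps.values():
        universe |= amap.matched_reference
    counts = [len(m.matched_reference) for m in maps.values()]
    print(f"distinct reference genes matched per sample: {min(counts)}-{max(counts)}")
    print(f"total matched reference universe: {len(universe)}")

    conc = RUN_DIR / "concordance.tsv"
    if conc.exists():
        rates = []
        for line in conc.read_text().strip().splitlines()[1:]:
            _, rate, _ = line.split("\t")
            if rate != "NA":
                rates.append(float(rate))
        print(
            f"dual-reference annotation concordance: {min(rates):.2%}-{max(rates):.2%} "
            f"(mean {sum(rates) / len(rates):.2%})"
        )


if __name__ == "__main__":
    main()
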