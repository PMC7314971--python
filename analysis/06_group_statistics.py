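"""Cold-vs-hot comparison of per-sample assembly/annotation metrics.

For each metric the test is chosen by the decision tree: Shapiro-Wilk
normality in both groups, then an F-test of variance homogeneity routing to
Student's t or Welch's t; non-normal metrics fall to Mann-Whitney U. All
tests two-tailed at alpha 0.05.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import study_config

from hmannot.pipeline import stage_stats


def main() -> None:
    config = study_config()
    results = stage_stats(config)
    print(f"{'metric':<22}{'test':<16}{'p':>10}  significant")
    for r in results:
        print(f"{r.variable:<22}{r.test_used:<16}{r.p_value:>10.4f}  {'yes' if r.significant else 'no'}")
    n_sig = sum(r.significant for r in results)
    print(f"\n{n_sig} of {len(results)} metrics differ between cold and hot at p < 0.05")


if __name__ == "__main__":
    main()
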