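"""Group-specific gene sets, Venn region counts and hit-count matrices.

A reference gene is specific to a group when at least one sample of that
group matched it and no sample of any other group did; genes matched by two
or more groups are shared. The same exclusivity logic, with a minimum-
sharing threshold, defines group-specific chemical components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

__all__ = [
    "GroupSpec",
    "specific_sets",
    "venn_counts",
    "hit_count_matrix",
    "specific_components",
]


@dataclass
class GroupSpec:
    """Assignment of samples to named groups over a matched-gene universe."""

    grouping: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        labels = set(self.grouping.values())
        if len(labels) < 2:
            raise ValueError("a grouping needs at least two distinct labels")

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.grouping.values()))

    def samples_in(self, label: str) -> list[str]:
        return sorted(s for s, g in self.grouping.items() if g == label)


def specific_sets(
    matched: Mapping[str, frozenset[str] | set[str]],
    spec: GroupSpec,
) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    """Per-group specific gene sets plus the shared remainder.

    ``matched`` maps sample_id -> set of reference genes that sample hit.
    A gene is specific to group g when present in >= 1 sample of g and in 0
    samples of every other group. Returns ``(specific_by_group, shared)``;
    the sets partition the union of all matched genes.
    """
    unknown = set(matched) - set(spec.grouping)
    if unknown:
        raise ValueError(f"samples not in grouping: {sorted(unknown)}")
    for label in spec.labels:
        if not any(s in matched for s in spec.samples_in(label)):
            raise ValueError(f"group {label!r} has no samples in the matched sets")

    group_union: dict[str, set[str]] = {label: set() for label in spec.labels}
    for sample, genes in matched.items():
        group_union[spec.grouping[sample]] |= set(genes)

    universe = frozenset().union(*group_union.values()) if group_union else frozenset()
    specific: dict[str, frozenset[str]] = {}
    for label in spec.labels:
        others = set().union(*(group_union[o] for o in spec.labels if o != label))
        specific[label] = frozenset(group_union[label] - others)
    shared = frozenset(universe - set().union(*specific.values()))
    return specific, shared


def venn_counts(sets: Mapping[str, set[str] | frozenset[str]]) -> dict[tuple[str, ...], int]:
    """Counts of every non-empty Venn region over 2-4 named sets.

    Region keys are sorted tuples of the group names whose sets contain the
    region's elements exclusively; all 2**k - 1 regions are reported, so the
    counts sum to the size of the union.
    """
    names = sorted(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_counts supports 2 to 4 sets")
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            region = set.intersection(*(set(sets[n]) for n in inside))
            for outside in names:
                if outside not in inside:
                    region -= set(sets[outside])
            counts[tuple(inside)] = len(region)
    return counts


def hit_count_matrix(
    assignments: Mapping[str, Mapping[str, str]],
    spec: GroupSpec,
) -> dict[tuple[int, int], int]:
    """Reference-gene counts by (group-1 hits, group-2 hits).

    ``assignments`` maps sample_id -> {species gene -> reference gene}.
    Cell (i, j) counts reference genes hit by exactly i species genes from
    the first group (alphabetically) and j from the second, pooling genes
    across the group's samples. Cells sum to the size of the matched
    universe; the (i>0, j=0) margin totals the group-1-specific set.
    """
    labels = spec.labels
    if len(labels) != 2:
        raise ValueError("hit_count_matrix requires exactly two groups")
    unknown = set(assignments) - set(spec.grouping)
    if unknown:
        raise ValueError(f"samples not in grouping: {sorted(unknown)}")
    per_ref: dict[str, list[int]] = {}
    for sample, amap in assignments.items():
        gidx = labels.index(spec.grouping[sample])
        for ref in amap.values():
            per_ref.setdefault(ref, [0, 0])[gidx] += 1
    matrix: dict[tuple[int, int], int] = {}
    for counts in per_ref.values():
        key = (counts[0], counts[1])
        matrix[key] = matrix.get(key, 0) + 1
    return matrix


def specific_components(
    components: Mapping[str, set[str] | frozenset[str]],
    spec: GroupSpec,
    min_shared: int = 2,
) -> dict[str, frozenset[str]]:
    """Group-specific chemical components.

    A compound is specific to group g when it occurs in at least
    ``min_shared`` samples of g and in no sample of the other group.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    labels = spec.labels
    if len(labels) != 2:
        raise ValueError("specific_components requires exactly two groups")
    unknown = set(components) - set(spec.grouping)
    if unknown:
        raise ValueError(f"samples not in grouping: {sorted(unknown)}")
    counts: dict[str, dict[str, int]] = {label: {} for label in labels}
    for sample, comps in components.items():
        label = spec.grouping[sample]
        for c in comps:
            counts[label][c] = counts[label].get(c, 0) + 1
    out: dict[str, frozenset[str]] = {}
    for label in labels:
        other = labels[1] if label == labels[0] else labels[0]
        out[label] = frozenset(
            c for c, n in counts[label].items() if n >= min_shared and c not in counts[other]
        )
    return out
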