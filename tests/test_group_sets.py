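import pytest

from hmannot.group_sets import (
    GroupSpec,
    hit_count_matrix,
    specific_components,
    specific_sets,
    venn_counts,
)


def two_group_spec(**grouping):
    return GroupSpec(grouping=grouping)


class TestSpecificSets:
    def test_enumerated_example(self):
        matched = {"c1": {"r1", "r2"}, "c2": {"r2", "r3"}, "h1": {"r3", "r4"}}
        spec = two_group_spec(c1="cold", c2="cold", h1="hot")
        specific, shared = specific_sets(matched, spec)
        assert specific == {"cold": frozenset({"r1", "r2"}), "hot": frozenset({"r4"})}
        assert shared == frozenset({"r3"})

    def test_identical_sets_give_empty_specific(self):
        matched = {"a": {"r1"}, "b": {"r1"}}
        specific, shared = specific_sets(matched, two_group_spec(a="cold", b="hot"))
        assert all(not s for s in specific.values())
        assert shared == frozenset({"r1"})

    def test_group_without_samples_is_error(self):
        spec = two_group_spec(a="cold", b="hot")
        with pytest.raises(ValueError, match="hot"):
            specific_sets({"a": {"r1"}}, spec)

    def test_sample_missing_from_grouping_is_error(self):
        with pytest.raises(ValueError, match="mystery"):
            specific_sets({"a": {"r1"}, "mystery": {"r2"}}, two_group_spec(a="cold", b="hot"))

    def test_partition_property_on_random_panels(self, rng):
        """Specific sets and the shared set partition the matched universe."""
        for _ in range(50):
            n_samples = int(rng.integers(2, 8))
            groups = ["g1", "g2", "g3"][: int(rng.integers(2, 4))]
            grouping, matched = {}, {}
            for i in range(n_samples):
                sid = f"s{i}"
                grouping[sid] = groups[i % len(groups)]
                matched[sid] = {f"r{j}" for j in rng.integers(0, 30, size=int(rng.integers(1, 15)))}
            spec = GroupSpec(grouping=grouping)
            specific, shared = specific_sets(matched, spec)
            universe = set().union(*matched.values())
            parts = list(specific.values()) + [shared]
            assert set().union(*parts) == universe
            for i, a in enumerate(parts):
                for b in parts[i + 1 :]:
                    assert not (a & b)
            # brute-force per-gene scan
            for gene in universe:
                present = {grouping[s] for s, genes in matched.items() if gene in genes}
                if len(present) == 1:
                    assert gene in specific[present.pop()]
                else:
                    assert gene in shared


class TestVennCounts:
    def test_two_sets(self):
        counts = venn_counts({"A": {1, 2}, "B": {2, 3}})
        assert counts == {("A",): 1, ("B",): 1, ("A", "B"): 1}

    def test_disjoint_three_sets(self):
        counts = venn_counts({"A": {1}, "B": {2}, "C": {3}})
        assert counts[("A", "B")] == 0
        assert counts[("A", "B", "C")] == 0
        assert sum(counts.values()) == 3

    def test_counts_sum_to_union_on_random_sets(self, rng):
        for _ in range(30):
            sets = {name: set(rng.integers(0, 40, size=int(rng.integers(0, 25)))) for name in "ABCD"}
            counts = venn_counts(sets)
            assert len(counts) == 15
            assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_more_than_four_sets_rejected(self):
        with pytest.raises(ValueError):
            venn_counts({n: {1} for n in "ABCDE"})


class TestHitCountMatrix:
    def test_direct_count(self):
        assignments = {
            "c1": {"x1": "r1", "x2": "r1"},
            "h1": {"y1": "r1"},
        }
        spec = two_group_spec(c1="cold", h1="hot")
        assert hit_count_matrix(assignments, spec) == {(2, 1): 1}

    def test_empty(self):
        spec = two_group_spec(c1="cold", h1="hot")
        assert hit_count_matrix({"c1": {}, "h1": {}}, spec) == {}

    def test_non_binary_grouping_rejected(self):
        spec = GroupSpec(grouping={"a": "x", "b": "y", "c": "z"})
        with pytest.raises(ValueError, match="two groups"):
            hit_count_matrix({}, spec)

    def test_margins_reconcile_with_specific_sets(self, rng):
        """(i>0, 0) margin equals group-1-specific size, on random panels."""
        for _ in range(50):
            grouping, assignments = {}, {}
            for i in range(int(rng.integers(2, 7))):
                sid = f"s{i}"
                grouping[sid] = "cold" if i % 2 == 0 else "hot"
                assignments[sid] = {
                    f"{sid}_g{j}": f"r{rng.integers(0, 25)}" for j in range(int(rng.integers(1, 12)))
                }
            if len(set(grouping.values())) < 2:
                continue
            spec = GroupSpec(grouping=grouping)
            matrix = hit_count_matrix(assignments, spec)
            matched = {sid: frozenset(a.values()) for sid, a in assignments.items()}
            specific, shared = specific_sets(matched, spec)
            universe = set().union(*matched.values())
            assert sum(matrix.values()) == len(universe)
            g1, g2 = spec.labels
            assert sum(v for (i, j), v in matrix.items() if i > 0 and j == 0) == len(specific[g1])
            assert sum(v for (i, j), v in matrix.items() if i == 0 and j > 0) == len(specific[g2])


class TestSpecificComponents:
    SPEC = GroupSpec(grouping={"cold3": "cold", "cold9": "cold", "hot1": "hot", "hot2": "hot"})

    def test_shared_by_two_and_absent_from_other(self):
        components = {
            "cold3": {"chrysoeriol", "x"},
            "cold9": {"chrysoeriol"},
            "hot1": {"y"},
            "hot2": {"y", "z"},
        }
        out = specific_components(components, self.SPEC)
        assert "chrysoeriol" in out["cold"]
        assert out["hot"] == frozenset({"y"})

    def test_single_occurrence_below_threshold(self):
        components = {"cold3": {"c"}, "cold9": set(), "hot1": set(), "hot2": set()}
        assert specific_components(components, self.SPEC)["cold"] == frozenset()

    def test_presence_in_other_group_disqualifies(self):
        components = {"cold3": {"c"}, "cold9": {"c"}, "hot1": {"c"}, "hot2": set()}
        assert specific_components(components, self.SPEC)["cold"] == frozenset()

    def test_min_shared_validation(self):
        with pytest.raises(ValueError):
            specific_components({}, self.SPEC, min_shared=0)
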