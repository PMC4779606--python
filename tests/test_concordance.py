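"""Concordance classification, aggregation and the coalescent transform.

The classifier is checked against a brute-force split-compatibility
oracle over exhaustively enumerated topologies, and the aggregate /
transform layer against the published placental-root count tables.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootquartet.concordance import (
    DEFAULT_HYPOTHESES,
    INDECISIVE,
    REJECTS_ALL,
    Outcome,
    aggregate,
    classify,
    coalescent_length,
    collapse_low_support,
    expected_support,
    passes_group_filter,
    support_fraction,
)
from rootquartet.datasets import load_root_count_tables
from rootquartet.treeio import TaxonGroupMap, parse_newick


class TestCollapse:
    def test_threshold_zero_is_identity(self):
        t = parse_newick("((A,B)40,((C,D)90,E)60);")
        assert dict(collapse_low_support(t, 0).bipartitions()) == dict(t.bipartitions())

    def test_hand_contracted_example(self):
        # only the 40-edge is below 50; (C,D) at 90 and the 60-edge survive
        t = parse_newick("((A,B)40,((C,D)90,E)60);")
        collapsed = collapse_low_support(t, 50)
        leaves = collapsed.leaves
        splits = {
            frozenset({s, leaves - s}) for s, _ in collapsed.bipartitions()
        }
        assert splits == {
            frozenset({frozenset({"C", "D"}), frozenset({"A", "B", "E"})}),
            frozenset({frozenset({"C", "D", "E"}), frozenset({"A", "B"})}),
        }

    def test_at_threshold_retained(self):
        t = parse_newick("((A,B)50,(C,D)50);")
        assert len(collapse_low_support(t, 50).bipartitions()) == 1

    def test_caterpillar_full_support_unchanged(self):
        t = parse_newick("(((((A,B)100,C)100,D)100,E)100,F);")
        assert len(collapse_low_support(t, 75).bipartitions()) == 3

    def test_missing_support_policy(self):
        t = parse_newick("((A,B),(C,D));")
        assert collapse_low_support(t, 50).bipartitions() == []
        kept = collapse_low_support(t, 50, keep_unlabelled=True)
        assert len(kept.bipartitions()) == 1

    @pytest.mark.parametrize("thr", [0, 30, 75, 100])
    def test_idempotent(self, thr):
        t = parse_newick("(((A,B)20,(C,D)80)55,((E,F)95,G)10);")
        once = collapse_low_support(t, thr)
        twice = collapse_low_support(once, thr)
        assert dict(once.bipartitions()) == dict(twice.bipartitions())

    def test_monotone_in_threshold(self):
        t = parse_newick("(((A,B)20,(C,D)80)55,((E,F)95,G)10);")
        prev = None
        for thr in (0, 25, 50, 75, 100):
            splits = {s for s, _ in collapse_low_support(t, thr).bipartitions()}
            if prev is not None:
                assert splits <= prev
            prev = splits


class TestGroupFilter:
    def test_all_groups_present(self, gmap):
        t = parse_newick("((XEN_1,AFR_1),(BOR_1,OUT_1));")
        assert passes_group_filter(t, gmap)

    def test_missing_group(self, gmap):
        t = parse_newick("((AFR_1,BOR_1),(OUT_1,AFR_2));")
        gm = TaxonGroupMap({**gmap.mapping, "AFR_2": "AFR"})
        assert not passes_group_filter(t, gm)

    def test_unmapped_leaf_ignored_by_default(self, gmap):
        t = parse_newick("((XEN_1,AFR_1),(BOR_1,OUT_1),unknown);")
        assert passes_group_filter(t, gmap)
        with pytest.raises(KeyError):
            passes_group_filter(t, gmap, on_unmapped="error")


# ---------------------------------------------------------------------
# classification vs brute-force oracle


def _enumerate_unrooted_binary(leaves):
    """All unrooted binary topologies (as newick) on the given leaves."""

    def rooted(labels):
        if len(labels) == 1:
            yield labels[0]
            return
        for sub in rooted(labels[:-1]):
            for t in _insert_everywhere(sub, labels[-1]):
                yield t

    def _insert_everywhere(tree, leaf):
        # tree is a newick fragment; insert at every edge by string surgery
        # on a parsed nested-tuple form
        def parse(s):
            if not s.startswith("("):
                return s
            depth, parts, cur = 0, [], ""
            for ch in s[1:-1]:
                if ch == "(":
                    depth += 1
                elif ch == ")":
                    depth -= 1
                if ch == "," and depth == 0:
                    parts.append(cur)
                    cur = ""
                else:
                    cur += ch
            parts.append(cur)
            return tuple(parse(p) for p in parts)

        def unparse(t):
            if isinstance(t, str):
                return t
            return "(" + ",".join(unparse(c) for c in t) + ")"

        def insertions(t):
            yield ("(" + unparse(t) + f",{leaf})")
            if isinstance(t, tuple):
                a, b = t
                for ins in insertions(a):
                    yield "(" + ins + "," + unparse(b) + ")"
                for ins in insertions(b):
                    yield "(" + unparse(a) + "," + ins + ")"

        yield from insertions(parse(tree))

    for t in rooted(list(leaves[1:])):
        yield f"({t},{leaves[0]});"


def _oracle_classify(tree, group_map, hypotheses):
    """Compatibility-based oracle: a tree is compatible with a hypothesis's
    constraint tree iff no retained split conflicts with any constraint
    split (each group's coherence plus the root pairing)."""
    universe = tree.leaves
    tree_splits = [s for s, _ in tree.bipartitions()]

    def conflicts(a, b):
        return bool(a & b) and bool(a - b) and bool(b - a) and bool(
            universe - (a | b)
        )

    compatible = []
    for h in hypotheses:
        constraints = []
        for g in group_map.groups:
            members = frozenset(
                l for l in universe if group_map.group_of(l) == g
            )
            if 2 <= len(members) <= len(universe) - 2:
                constraints.append(members)
        side1 = frozenset(
            l for l in universe if group_map.group_of(l) in h.side1
        )
        constraints.append(side1)
        if all(not conflicts(ts, cs) for ts in tree_splits for cs in constraints):
            compatible.append(h.name)
    if not compatible:
        return Outcome(REJECTS_ALL)
    if len(compatible) == len(hypotheses):
        return Outcome(INDECISIVE)
    assert len(compatible) == 1, "compatibility with exactly two hypotheses"
    return Outcome.supports(compatible[0])


class TestClassify:
    def test_displays_atlantogenata(self, gmap):
        t = parse_newick("((XEN_1,AFR_1),(BOR_1,OUT_1));")
        assert classify(t, gmap) == Outcome.supports("Atlantogenata")

    def test_star_indecisive(self, gmap):
        t = parse_newick("(XEN_1,AFR_1,BOR_1,OUT_1);")
        assert classify(t, gmap) == Outcome(INDECISIVE)

    def test_split_group_rejects_all(self, gmap):
        # XEN members split against BOR+OUT: Xenarthra is rejected
        gm = TaxonGroupMap({**gmap.mapping, "XEN_2": "XEN"})
        t = parse_newick("((XEN_1,BOR_1),(XEN_2,OUT_1),AFR_1);")
        assert classify(t, gm) == Outcome(REJECTS_ALL)

    def test_unmapped_taxa_pruned_with_warning(self, gmap):
        t = parse_newick("(((XEN_1,odd_taxon),AFR_1),(BOR_1,OUT_1));")
        with pytest.warns(UserWarning, match="pruning"):
            out = classify(t, gmap)
        assert out == Outcome.supports("Atlantogenata")

    def test_bad_hypothesis_sides_raise(self, gmap):
        from rootquartet.concordance import RootHypothesis

        bad = RootHypothesis("bad", frozenset({"XEN"}), frozenset({"AFR"}))
        t = parse_newick("((XEN_1,AFR_1),(BOR_1,OUT_1));")
        with pytest.raises(ValueError, match="partition"):
            classify(t, gmap, [bad])

    @pytest.mark.parametrize(
        "assignment",
        [
            # 6 leaves: 105 binary topologies
            {"x1": "XEN", "x2": "XEN", "a1": "AFR", "b1": "BOR", "o1": "OUT", "o2": "OUT"},
            # 7 leaves: 945 binary topologies
            {"x1": "XEN", "x2": "XEN", "a1": "AFR", "a2": "AFR", "b1": "BOR",
             "o1": "OUT", "o2": "OUT"},
        ],
        ids=["six-leaf", "seven-leaf"],
    )
    def test_matches_oracle_exhaustively(self, assignment):
        """classify agrees with the split-compatibility oracle on every
        binary topology over the leaf set."""
        gm = TaxonGroupMap(assignment)
        leaves = sorted(assignment)
        seen = set()
        for nwk in _enumerate_unrooted_binary(leaves):
            tree = parse_newick(nwk)
            key = frozenset(s for s, _ in tree.bipartitions())
            if key in seen:
                continue
            seen.add(key)
            assert classify(tree, gm) == _oracle_classify(tree, gm, DEFAULT_HYPOTHESES)
        expected = {6: 105, 7: 945}[len(leaves)]
        assert len(seen) == expected


# ---------------------------------------------------------------------
# aggregation and the coalescent transform


class TestAggregate:
    def test_empty_is_all_zero(self):
        tab = aggregate([])
        assert tab.total == 0

    def test_weighted_total(self):
        tab = aggregate(
            [Outcome.supports("Atlantogenata"), Outcome(INDECISIVE)], weights=[4, 5]
        )
        assert tab.total == 9
        assert tab.counts["Atlantogenata"] == 4

    def test_nonpositive_weight_raises(self):
        with pytest.raises(ValueError):
            aggregate([Outcome(INDECISIVE)], weights=[0.0])

    def test_counts_sum_to_total_weight(self):
        rng = np.random.default_rng(7)
        kinds = [Outcome.supports("Afrotheria"), Outcome(REJECTS_ALL), Outcome(INDECISIVE)]
        outcomes = [kinds[i] for i in rng.integers(0, 3, 200)]
        w = rng.uniform(0.5, 3.0, 200)
        tab = aggregate(outcomes, w)
        assert math.isclose(tab.total, w.sum())
        assert math.isclose(sum(tab.counts.values()), w.sum())


class TestPublishedCounts:
    """The four published analysis variants, rebuilt from integer counts."""

    EXPECTED = {
        "binned_50": (6387, 0.417566933, 0.135075898),
        "unbinned_50": (3495, 0.484406295, 0.256971108),
        "binned_75": (4203, 0.449916726, 0.192220497),
        "unbinned_75": (1327, 0.55990957, 0.415309943),
    }

    @pytest.mark.parametrize("variant", list(EXPECTED))
    def test_fraction_and_length(self, variant):
        tab = load_root_count_tables()[variant]
        total, p, t = self.EXPECTED[variant]
        assert tab.decisive_total == total
        assert tab.support_fraction("Atlantogenata") == pytest.approx(p, abs=5e-10)
        assert tab.coalescent_length("Atlantogenata") == pytest.approx(t, abs=5e-10)

    def test_every_column_totals_11169(self):
        for tab in load_root_count_tables().values():
            assert tab.total == 11169


class TestCoalescentTransform:
    def test_worked_example(self):
        assert round(coalescent_length(1693 / 3495), 3) == 0.257

    def test_one_third_is_zero(self):
        assert coalescent_length(1.0 / 3.0) == pytest.approx(0.0, abs=1e-15)

    def test_below_one_third_warns_negative(self):
        with pytest.warns(UserWarning, match="star"):
            assert coalescent_length(0.2) < 0

    @pytest.mark.parametrize("p", [1.0, -0.1, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            coalescent_length(p)

    def test_expected_support_endpoints(self):
        assert expected_support(0.0) == pytest.approx(1 / 3)
        assert expected_support(50.0) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            expected_support(-0.1)

    @settings(max_examples=60, deadline=None)
    @given(st.floats(0.0, 10.0))
    def test_round_trip_identity(self, t):
        assert coalescent_length(expected_support(t)) == pytest.approx(t, abs=1e-10)

    def test_zero_denominator_raises(self):
        tab = aggregate([Outcome(INDECISIVE)])
        with pytest.raises(ZeroDivisionError):
            support_fraction(tab, "Atlantogenata")
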