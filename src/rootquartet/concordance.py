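"""Gene-tree concordance classification against competing root hypotheses.

Each gene tree, after collapsing weakly supported edges, is compared with
the candidate resolutions of the root quartet.  Five outcomes are
possible: the tree rejects all hypotheses (some declared group, or the
outgroup branch, is contradicted by a retained split), it is indecisive
(compatible with every hypothesis), or it supports exactly one
hypothesis.  The fraction p of decisive trees supporting a hypothesis
converts to an internal branch length in coalescent units through the
multispecies-coalescent quartet law

    t = -ln(3/2 * (1 - p)),      p = 1 - (2/3) e^(-t).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .treeio import GeneTree, TaxonGroupMap

__all__ = [
    "RootHypothesis",
    "Outcome",
    "ConcordanceTable",
    "DEFAULT_HYPOTHESES",
    "collapse_low_support",
    "passes_group_filter",
    "classify",
    "aggregate",
    "support_fraction",
    "coalescent_length",
    "expected_support",
    "classify_trees",
]

REJECTS_ALL = "REJECTS_ALL"
INDECISIVE = "INDECISIVE"


@dataclass(frozen=True)
class RootHypothesis:
    """A pairing of the declared groups into the two sides of a quartet split."""

    name: str
    side1: frozenset
    side2: frozenset

    def __post_init__(self):
        object.__setattr__(self, "side1", frozenset(self.side1))
        object.__setattr__(self, "side2", frozenset(self.side2))
        if not self.side1 or not self.side2 or (self.side1 & self.side2):
            raise ValueError("hypothesis sides must be disjoint and nonempty")

    def validate(self, groups: Iterable[str]) -> None:
        if self.side1 | self.side2 != set(groups):
            raise ValueError(
                f"hypothesis {self.name}: sides {sorted(self.side1)}|"
                f"{sorted(self.side2)} do not partition groups {sorted(groups)}"
            )


#: The three candidate resolutions of the placental root.
DEFAULT_HYPOTHESES = (
    RootHypothesis("Atlantogenata", frozenset({"XEN", "AFR"}), frozenset({"BOR", "OUT"})),
    RootHypothesis("Afrotheria", frozenset({"AFR", "OUT"}), frozenset({"XEN", "BOR"})),
    RootHypothesis("Xenarthra", frozenset({"XEN", "OUT"}), frozenset({"AFR", "BOR"})),
)


@dataclass(frozen=True)
class Outcome:
    """Classification outcome: REJECTS_ALL, INDECISIVE or SUPPORTS(name)."""

    kind: str  # REJECTS_ALL | INDECISIVE | SUPPORTS
    hypothesis: str | None = None

    @classmethod
    def supports(cls, name: str) -> "Outcome":
        return cls("SUPPORTS", name)

    def __str__(self):
        return self.hypothesis if self.kind == "SUPPORTS" else self.kind


def collapse_low_support(
    tree: GeneTree, threshold: float, keep_unlabelled: bool = False
) -> GeneTree:
    """Contract internal edges whose support is below ``threshold``.

    Edges with support >= threshold (and all terminal edges) are kept;
    the comparison is strict, so a support exactly at the threshold
    survives.  Edges with no recorded support carry no evidence and are
    contracted whenever threshold > 0, unless ``keep_unlabelled``.
    """
    if not (0.0 <= threshold <= 100.0):
        raise ValueError("threshold must be in [0, 100]")
    out = tree.copy()
    to_collapse = []
    for edge in out.internal_edges():
        sup = getattr(edge.head_node, "support", None)
        if sup is None:
            if threshold > 0 and not keep_unlabelled:
                to_collapse.append(edge)
        elif sup < threshold:
            to_collapse.append(edge)
    for edge in to_collapse:
        edge.collapse()
    return out


def passes_group_filter(
    tree: GeneTree, group_map: TaxonGroupMap, on_unmapped: str = "ignore"
) -> bool:
    """True iff the tree has at least one leaf from every declared group."""
    present = set()
    for leaf in tree.leaves:
        g = group_map.group_of(leaf)
        if g is None:
            if on_unmapped == "error":
                raise KeyError(f"leaf {leaf!r} absent from group map")
            continue
        present.add(g)
    return present >= set(group_map.groups)


def _splits_conflict(a: frozenset, b: frozenset, universe: frozenset) -> bool:
    """Two bipartitions (given by one side each) conflict iff all four
    side-intersections are nonempty."""
    return bool(a & b) and bool(a - b) and bool(b - a) and bool(universe - (a | b))


def classify(
    tree: GeneTree,
    group_map: TaxonGroupMap,
    hypotheses: Sequence[RootHypothesis] = DEFAULT_HYPOTHESES,
) -> Outcome:
    """Classify one (collapsed) gene tree against the root hypotheses.

    Works on the unrooted bipartitions over the tree's mapped leaves:

    * a group G is rejected when some retained split places members of G
      on both sides together with non-members on both sides; any
      rejected group (including the outgroup) means the tree rejects
      every hypothesis, since group coherence is common to all of them;
    * otherwise the tree supports hypothesis S1|S2 iff some retained
      split places exactly the present leaves of the S1 groups against
      those of the S2 groups; at most one hypothesis can be displayed;
    * displaying none of them leaves the tree indecisive.
    """
    groups = set(group_map.groups)
    for h in hypotheses:
        h.validate(groups)
    mapped = {l for l in tree.leaves if group_map.group_of(l) is not None}
    if mapped != tree.leaves:
        tree = tree.prune_to(mapped)
    universe = frozenset(mapped)
    group_leaves = {
        g: frozenset(l for l in mapped if group_map.group_of(l) == g) for g in groups
    }
    splits = [side for side, _ in tree.bipartitions()]

    for g, members in group_leaves.items():
        for side in splits:
            if _splits_conflict(side, members, universe):
                return Outcome(REJECTS_ALL)

    split_set = set(splits) | {universe - s for s in splits}
    displayed = None
    for h in hypotheses:
        side1 = frozenset().union(*(group_leaves[g] for g in h.side1))
        if side1 in split_set:
            displayed = h
            break
    if displayed is None:
        return Outcome(INDECISIVE)
    return Outcome.supports(displayed.name)


@dataclass
class ConcordanceTable:
    """Weighted counts of the five classification outcomes.

    ``counts`` maps each hypothesis name plus REJECTS_ALL and INDECISIVE
    to a weighted count.  Derived quantities: the per-hypothesis support
    fraction p (share of the decisive total) and the coalescent-unit
    branch length t = -ln(3/2 (1-p)).
    """

    counts: dict[str, float]
    hypothesis_names: tuple[str, ...]
    threshold: float | None = None
    total: float = field(init=False)

    def __post_init__(self):
        for k, v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative count for {k}")
        self.total = float(sum(self.counts.values()))

    @classmethod
    def from_counts(
        cls,
        hypothesis_counts: dict[str, float],
        rejects_all: float = 0.0,
        indecisive: float = 0.0,
        threshold: float | None = None,
    ) -> "ConcordanceTable":
        counts = dict(hypothesis_counts)
        counts[REJECTS_ALL] = rejects_all
        counts[INDECISIVE] = indecisive
        return cls(counts, tuple(hypothesis_counts), threshold=threshold)

    @property
    def decisive_total(self) -> float:
        return sum(self.counts[h] for h in self.hypothesis_names)

    def support_fraction(self, hypothesis: str) -> float:
        return support_fraction(self, hypothesis)

    def coalescent_length(self, hypothesis: str) -> float:
        return coalescent_length(self.support_fraction(hypothesis))

    def to_dict(self) -> dict:
        d = {
            "threshold": self.threshold,
            "total": self.total,
            "counts": dict(self.counts),
            "sum_of_hypotheses": self.decisive_total,
        }
        if self.decisive_total > 0:
            d["support_fraction"] = {
                h: self.support_fraction(h) for h in self.hypothesis_names
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d["coalescent_length"] = {
                    h: self.coalescent_length(h)
                    for h in self.hypothesis_names
                    if self.support_fraction(h) < 1.0
                }
        return d


def aggregate(
    outcomes: Sequence[Outcome],
    weights: Sequence[float] | None = None,
    hypotheses: Sequence[RootHypothesis] = DEFAULT_HYPOTHESES,
    threshold: float | None = None,
) -> ConcordanceTable:
    """Accumulate outcomes into a weighted five-outcome table.

    Weights default to 1 per tree; supergene trees standing for a bin of
    genes are weighted by bin size.
    """
    names = tuple(h.name for h in hypotheses)
    counts = {n: 0.0 for n in names}
    counts[REJECTS_ALL] = 0.0
    counts[INDECISIVE] = 0.0
    if weights is None:
        weights = [1.0] * len(outcomes)
    if len(weights) != len(outcomes):
        raise ValueError("weights must align 1:1 with outcomes")
    for o, w in zip(outcomes, weights):
        if w <= 0:
            raise ValueError(f"nonpositive weight {w}")
        key = o.hypothesis if o.kind == "SUPPORTS" else o.kind
        counts[key] += w
    return ConcordanceTable(counts, names, threshold=threshold)


def support_fraction(table: ConcordanceTable, hypothesis: str) -> float:
    """p = weight supporting ``hypothesis`` / total decisive weight."""
    denom = table.decisive_total
    if denom <= 0:
        raise ZeroDivisionError(
            "no tree supports any hypothesis; support fraction undefined"
        )
    return table.counts[hypothesis] / denom


def coalescent_length(p: float) -> float:
    """Internal branch length in coalescent units from quartet support p.

    t = -ln(3/2 (1-p)).  p = 1/3 gives t = 0 (a star tree); p below 1/3
    gives a negative length, returned with a warning since it means the
    hypothesis is supported less often than under no signal at all.
    """
    if not (0.0 <= p < 1.0):
        if p == 1.0:
            raise ValueError("p = 1 implies an infinite branch length")
        raise ValueError(f"support fraction {p} outside [0, 1)")
    t = -math.log(1.5 * (1.0 - p))
    if t < 0:
        warnings.warn(
            f"support fraction {p:.4f} < 1/3: negative coalescent length "
            "(weaker than a star tree)",
            stacklevel=2,
        )
    return t


def expected_support(t: float) -> float:
    """Inverse transform: p = 1 - (2/3) e^(-t) for t >= 0."""
    if t < 0:
        raise ValueError("coalescent branch length must be nonnegative")
    return 1.0 - (2.0 / 3.0) * math.exp(-t)


def hypothesis_topology(
    taxa: Iterable[str],
    group_map: TaxonGroupMap,
    hypothesis: RootHypothesis,
) -> GeneTree:
    """Build the constraint topology a hypothesis implies for given taxa.

    Groups are monophyletic but internally unresolved; the only resolved
    split is the hypothesis pairing.  Used to fix topologies for
    likelihood comparison.
    """
    from .treeio import parse_newick

    taxa = list(taxa)

    def clade(groups: frozenset) -> str:
        parts = []
        for g in sorted(groups):
            members = sorted(t for t in taxa if group_map.group_of(t) == g)
            if not members:
                continue
            parts.append(members[0] if len(members) == 1 else "(" + ",".join(members) + ")")
        if not parts:
            raise ValueError(f"no taxa present for groups {sorted(groups)}")
        return ",".join(parts)

    nwk = f"(({clade(hypothesis.side1)}),({clade(hypothesis.side2)}));"
    return parse_newick(nwk)


def classify_trees(
    trees: Sequence[GeneTree],
    group_map: TaxonGroupMap,
    threshold: float,
    weights: Sequence[float] | None = None,
    hypotheses: Sequence[RootHypothesis] = DEFAULT_HYPOTHESES,
    keep_unlabelled: bool = False,
) -> ConcordanceTable:
    """Collapse, filter and classify a set of gene trees; aggregate.

    Trees failing the group-presence filter are dropped (the study's
    gene sets were prefiltered the same way), with their weights.
    """
    outcomes, used_w = [], []
    if weights is None:
        weights = [1.0] * len(trees)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tree, w in zip(trees, weights):
            if not passes_group_filter(tree, group_map):
                continue
            collapsed = collapse_low_support(tree, threshold, keep_unlabelled)
            outcomes.append(classify(collapsed, group_map, hypotheses))
            used_w.append(w)
    return aggregate(outcomes, used_w, hypotheses, threshold=threshold)
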