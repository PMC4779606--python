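"""Reading and writing trees, alignments, group maps and weight tables.

Trees are handled in the Newick "support as internal node label" dialect
(the convention of RAxML/PhyML bootstrap output).  Support values are
normalized to a 0-100 percent scale on input; a value absent from an
internal edge is recorded as *missing*, which downstream modules treat
differently from an explicit 0.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "GeneTree",
    "TaxonGroupMap",
    "Alignment",
    "TreeParseError",
    "parse_newick",
    "read_trees",
    "read_group_map",
    "read_weights",
    "read_alignment",
    "write_results",
]

DNA_ALPHABET = ("A", "C", "G", "T")
MISSING_SYMBOLS = frozenset({"-", "?", "N", "n", ".", "X", "x", "O", "o"})


class TreeParseError(ValueError):
    """Raised when a Newick string cannot be interpreted."""


class RaggedAlignmentError(ValueError):
    """Raised when sequences in one alignment differ in length."""


@dataclass
class GeneTree:
    """An unrooted leaf-labelled tree with optional per-edge supports.

    Wraps a :class:`dendropy.Tree`.  Supports live on ``edge.head_node``
    as the attribute ``support`` (float in [0, 100]) or ``None`` when the
    input carried no label for that edge.  Any rooting present in the
    input is ignored for classification purposes: all queries are over
    unrooted bipartitions.
    """

    tree: dendropy.Tree

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, support_scale: str = "auto") -> "GeneTree":
        return parse_newick(text, support_scale=support_scale)

    def copy(self) -> "GeneTree":
        t = self.tree.clone(depth=1)
        return GeneTree(t)

    # -- basic queries -------------------------------------------------

    @property
    def leaves(self) -> frozenset:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def __len__(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def internal_edges(self):
        """Yield internal (non-terminal, non-root-attachment) edges.

        An edge is internal when both sides of its bipartition contain at
        least two leaves; the edge incident to the seed node (a rooting
        artifact on an unrooted tree) is excluded.
        """
        n_leaves = len(self)
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node or node.is_leaf():
                continue
            below = sum(1 for _ in node.leaf_iter())
            if below >= 2 and n_leaves - below >= 2:
                yield node.edge

    def bipartitions(self) -> list[tuple[frozenset, float | None]]:
        """Nontrivial unrooted bipartitions with their supports.

        Returns ``(leafset_below, support)`` pairs; the complement side is
        implicit.  Duplicate splits produced by a rooted input (a root
        with two children induces the same split twice) are merged,
        keeping the maximum support.
        """
        all_leaves = self.leaves
        seen: dict[frozenset, float | None] = {}
        for edge in self.internal_edges():
            below = frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())
            key = min(below, all_leaves - below, key=sorted)
            sup = getattr(edge.head_node, "support", None)
            if key in seen:
                prev = seen[key]
                if prev is None or (sup is not None and sup > prev):
                    seen[key] = sup
            else:
                seen[key] = sup
        return list(seen.items())

    # -- editing -------------------------------------------------------

    def prune_to(self, keep: Iterable[str], warn: bool = True) -> "GeneTree":
        """Return a copy restricted to the given leaf labels."""
        keep = set(keep)
        dropped = self.leaves - keep
        out = self.copy()
        if dropped:
            if warn:
                warnings.warn(
                    f"pruning {len(dropped)} unmapped taxa: {sorted(dropped)[:5]}...",
                    stacklevel=2,
                )
            taxa = [t for t in out.tree.taxon_namespace if t.label in keep]
            out.tree.retain_taxa(taxa)
        return out

    def to_newick(self, with_supports: bool = True, with_lengths: bool = True) -> str:
        t = self.tree.clone(depth=1)
        for node in t.preorder_node_iter():
            if node.is_leaf() or node is t.seed_node:
                continue
            sup = getattr(node, "support", None)
            if with_supports and sup is not None:
                node.label = format(sup, "g")
            else:
                node.label = None
        s = t.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_edge_lengths=not with_lengths,
        )
        return s.strip()


@dataclass
class TaxonGroupMap:
    """Assignment of taxon labels to named groups.

    The default group set mirrors the placental-root problem: XEN
    (Xenarthra), AFR (Afrotheria), BOR (Boreoeutheria) and OUT
    (non-placental outgroups).
    """

    mapping: dict[str, str]
    groups: tuple[str, ...] = ("XEN", "AFR", "BOR", "OUT")

    def __post_init__(self):
        if not self.groups:
            raise ValueError("group set must be nonempty")
        extra = set(self.mapping.values()) - set(self.groups)
        if extra:
            self.groups = tuple(self.groups) + tuple(sorted(extra))

    def group_of(self, taxon: str) -> str | None:
        return self.mapping.get(taxon)

    def members(self, group: str) -> frozenset:
        return frozenset(t for t, g in self.mapping.items() if g == group)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class Alignment:
    """A rectangular character matrix over a finite alphabet.

    ``matrix`` holds integer state codes, with ``-1`` for missing/gap.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray  # (n_taxa, n_sites) int8/int16, -1 = missing
    alphabet: tuple[str, ...] = DNA_ALPHABET

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix shape must be (n_taxa, n_sites)")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def to_fasta(self) -> str:
        out = []
        for i, name in enumerate(self.taxa):
            seq = "".join(
                self.alphabet[c] if c >= 0 else "-" for c in self.matrix[i]
            )
            out.append(f">{name}\n{seq}")
        return "\n".join(out) + "\n"

    @classmethod
    def from_sequences(
        cls, named_seqs: Sequence[tuple[str, str]], alphabet=None
    ) -> "Alignment":
        taxa = tuple(n for n, _ in named_seqs)
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels in alignment")
        lengths = {len(s) for _, s in named_seqs}
        if len(lengths) > 1:
            from collections import Counter

            common = Counter(len(s) for _, s in named_seqs).most_common(1)[0][0]
            bad = next(n for n, s in named_seqs if len(s) != common)
            raise RaggedAlignmentError(
                f"sequences differ in length (offending taxon: {bad})"
            )
        if alphabet is None:
            observed = set()
            for _, s in named_seqs:
                observed.update(s.upper())
            observed -= {m.upper() for m in MISSING_SYMBOLS}
            if observed <= set(DNA_ALPHABET) | {"U"}:
                alphabet = DNA_ALPHABET
            else:
                alphabet = tuple(sorted(observed))
        lookup = {a.upper(): i for i, a in enumerate(alphabet)}
        if alphabet == DNA_ALPHABET:
            lookup["U"] = lookup["T"]
        n_sites = lengths.pop() if lengths else 0
        mat = np.full((len(taxa), n_sites), -1, dtype=np.int16)
        for i, (_, s) in enumerate(named_seqs):
            for j, ch in enumerate(s):
                code = lookup.get(ch.upper())
                if code is None and ch not in MISSING_SYMBOLS and ch.upper() not in {
                    m.upper() for m in MISSING_SYMBOLS
                }:
                    raise ValueError(
                        f"symbol {ch!r} not in alphabet {alphabet} for {taxa[i]}"
                    )
                mat[i, j] = -1 if code is None else code
        return cls(taxa, mat, tuple(alphabet))


# ---------------------------------------------------------------------
# parsing


def _normalize_supports(tree: dendropy.Tree, support_scale: str) -> None:
    vals = []
    nodes = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            node.support = None
            continue
        sup = None
        if node.label is not None:
            try:
                sup = float(node.label)
            except ValueError:
                sup = None
        node.support = sup
        if sup is not None:
            vals.append(sup)
            nodes.append(node)
    if not vals:
        return
    if support_scale == "fraction":
        scale = 100.0
    elif support_scale == "percent":
        scale = 1.0
    elif support_scale == "auto":
        scale = 100.0 if max(vals) <= 1.0 else 1.0
    else:
        raise ValueError(f"unknown support_scale {support_scale!r}")
    for node in nodes:
        node.support *= scale
        if not (0.0 <= node.support <= 100.0):
            raise TreeParseError(
                f"support {node.support} outside [0, 100] after normalization"
            )


def parse_newick(text: str, support_scale: str = "auto") -> GeneTree:
    """Parse one Newick string into a :class:`GeneTree`.

    Numeric internal-node labels are interpreted as edge supports.  With
    ``support_scale='auto'`` a tree whose numeric labels are all <= 1 is
    assumed to carry fractional supports and is rescaled to percent.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeParseError(f"duplicate leaf labels: {sorted(dupes)}")
    _normalize_supports(tree, support_scale)
    return GeneTree(tree)


def read_trees(path, support_scale: str = "auto") -> list[GeneTree]:
    """Read a file of one Newick tree per line (blank lines skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(parse_newick(line, support_scale=support_scale))
    return out


def read_group_map(path, groups: tuple[str, ...] | None = None) -> TaxonGroupMap:
    """Read a two-column taxon<TAB>group table ('#' comments, optional header)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{i + 1}: expected two columns")
            taxon, group = parts[0], parts[1]
            if i == 0 and taxon.lower() in {"taxon", "name", "label"}:
                continue
            if taxon in mapping and mapping[taxon] != group:
                raise ValueError(
                    f"taxon {taxon!r} assigned to both {mapping[taxon]!r} and {group!r}"
                )
            mapping[taxon] = group
    if groups is None:
        default = ("XEN", "AFR", "BOR", "OUT")
        observed = set(mapping.values())
        groups = default if observed <= set(default) else tuple(sorted(observed))
    return TaxonGroupMap(mapping, groups)


def read_weights(path) -> dict[str, float] | list[float]:
    """Read a weight table: either ``id<TAB>weight`` or one weight per line."""
    named: dict[str, float] = {}
    plain: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) >= 2:
                named[parts[0]] = float(parts[1])
            else:
                plain.append(float(parts[0]))
    return named if named else plain


def read_alignment(path, fmt: str = "auto", alphabet=None) -> Alignment:
    """Read a FASTA or relaxed sequential PHYLIP alignment."""
    with open(path) as fh:
        text = fh.read()
    if fmt == "auto":
        fmt = "fasta" if text.lstrip().startswith(">") else "phylip"
    if fmt == "fasta":
        pairs = []
        name, chunks = None, []
        for line in text.splitlines():
            if line.startswith(">"):
                if name is not None:
                    pairs.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line.strip():
                chunks.append(line.strip())
        if name is not None:
            pairs.append((name, "".join(chunks)))
    elif fmt == "phylip":
        lines = [l for l in text.splitlines() if l.strip()]
        header = lines[0].split()
        ntax, nsites = int(header[0]), int(header[1])
        pairs = []
        for line in lines[1 : 1 + ntax]:
            parts = line.split(None, 1)
            pairs.append((parts[0], parts[1].replace(" ", "")))
        for name, seq in pairs:
            if len(seq) != nsites:
                raise RaggedAlignmentError(
                    f"sequence for {name} has {len(seq)} sites, header says {nsites}"
                )
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    return Alignment.from_sequences(pairs, alphabet=alphabet)


def write_results(tables: Mapping[str, object], path, fmt: str = "json") -> None:
    """Write a dict of result objects (anything with ``to_dict``) to TSV/JSON."""

    def _plain(obj):
        if hasattr(obj, "to_dict"):
            return _plain(obj.to_dict())
        if isinstance(obj, Mapping):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    data = _plain(tables)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "tsv":
        buf = io.StringIO()
        for name, table in data.items():
            if isinstance(table, Mapping):
                for k, v in table.items():
                    buf.write(f"{name}\t{k}\t{v}\n")
            else:
                buf.write(f"{name}\t{table}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    else:
        raise ValueError(f"unknown result format {fmt!r}")
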