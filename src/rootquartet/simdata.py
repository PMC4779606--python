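"""Synthetic data under the multispecies coalescent (MSC).

Emulates the statistical structure of a root-quartet study: gene
genealogies drawn in a species tree whose contested internal branch has
length t coalescent units, finite-length sequence evolution on those
genealogies, and gene-tree estimation error with bootstrap supports
(neighbor joining on model-corrected distances, site-resampled
replicates).  Under the MSC with one lineage per group, the probability
that a gene genealogy displays the species quartet is

    p = 1 - (2/3) e^(-t),

the same law the concordance module inverts, so full-pipeline recovery
of t can be checked against closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .concordance import (
    DEFAULT_HYPOTHESES,
    RootHypothesis,
    classify_trees,
    coalescent_length,
)
from .seqlik import SubstitutionModel
from .treeio import Alignment, GeneTree, TaxonGroupMap, parse_newick

__all__ = [
    "MSCParams",
    "default_group_map",
    "sim_gene_trees",
    "sim_alignment",
    "estimate_gene_tree",
    "recovery_experiment",
]

#: Default sequence model for synthetic genes: GTR with transition-biased
#: exchangeabilities, mildly AT-rich frequencies and gamma rate variation.
DEFAULT_MODEL = SubstitutionModel.gtr(
    exchangeabilities=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),
    freqs=(0.3, 0.2, 0.2, 0.3),
    alpha=0.5,
)


@dataclass(frozen=True)
class MSCParams:
    """Simulation conditions for one experiment.

    ``t`` is the length, in coalescent units, of the species-tree branch
    separating the {XEN, AFR} ancestor from the {XEN, AFR, BOR} ancestor
    — the quantity the whole pipeline estimates.  The default species
    tree is ultrametric with one sampled lineage per group and the
    Atlantogenata pairing as truth.  ``mut_scale`` converts coalescent
    units to expected substitutions per site (default 0.01, giving the
    weak per-gene signal regime of short mammalian genes).
    """

    t: float = 0.26
    n_genes: int = 1000
    sites: int = 300
    lineages_per_group: int = 1
    model: SubstitutionModel = DEFAULT_MODEL
    mut_scale: float = 0.01
    stem_depth: float = 1.0  # coalescent time from tips to the first join
    root_branch: float = 1.0  # branch above the {XEN,AFR,BOR} ancestor

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("t must be nonnegative")
        if self.n_genes < 1 or self.sites < 1:
            raise ValueError("n_genes and sites must be >= 1")

    def species_times(self) -> dict[str, float]:
        """Absolute node times (tips at 0) of the default species tree
        (((XEN,AFR),BOR),OUT)."""
        t1 = self.stem_depth
        return {
            "XA": t1,  # XEN+AFR ancestor
            "XAB": t1 + self.t,  # +BOR
            "root": t1 + self.t + self.root_branch,  # +OUT
        }


def default_group_map(lineages_per_group: int = 1) -> TaxonGroupMap:
    """Group map for the simulated taxa ``XEN_1 ... OUT_n``."""
    mapping = {}
    for g in ("XEN", "AFR", "BOR", "OUT"):
        for i in range(1, lineages_per_group + 1):
            mapping[f"{g}_{i}"] = g
    return TaxonGroupMap(mapping)


# ---------------------------------------------------------------------
# genealogy simulation


class _Lineage:
    __slots__ = ("nwk", "height")

    def __init__(self, nwk: str, height: float):
        self.nwk = nwk
        self.height = height


def _coalesce(lineages: list[_Lineage], start: float, duration: float,
              rng: np.random.Generator) -> tuple[list[_Lineage], float]:
    """Coalesce within one species-tree branch for up to ``duration``
    coalescent units; returns surviving lineages and the end time."""
    now = start
    end = start + duration
    while len(lineages) > 1:
        j = len(lineages)
        wait = rng.exponential(1.0 / (j * (j - 1) / 2.0))
        if now + wait > end:
            break
        now += wait
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = lineages[i1], lineages[i2]
        merged = _Lineage(
            f"({a.nwk}:{now - a.height:.10g},{b.nwk}:{now - b.height:.10g})", now
        )
        lineages = [l for m, l in enumerate(lineages) if m not in (i1, i2)]
        lineages.append(merged)
    return lineages, end


def _sim_one_genealogy(params: MSCParams, rng: np.random.Generator) -> str:
    times = params.species_times()
    k = params.lineages_per_group
    pop = {
        g: [_Lineage(f"{g}_{i}", 0.0) for i in range(1, k + 1)]
        for g in ("XEN", "AFR", "BOR", "OUT")
    }
    # within terminal branches (only relevant with >1 lineage per group)
    for g, dur in (("XEN", times["XA"]), ("AFR", times["XA"]),
                   ("BOR", times["XAB"]), ("OUT", times["root"])):
        pop[g], _ = _coalesce(pop[g], 0.0, dur, rng)
    # XEN+AFR ancestral branch of length t
    xa, _ = _coalesce(pop["XEN"] + pop["AFR"], times["XA"], params.t, rng)
    # +BOR branch up to the root
    xab, _ = _coalesce(xa + pop["BOR"], times["XAB"], params.root_branch, rng)
    # root branch: coalesce to completion
    final, _ = _coalesce(xab + pop["OUT"], times["root"], np.inf, rng)
    return final[0].nwk + ";"


def sim_gene_trees(
    params: MSCParams, seed: int | np.random.Generator | None = None
) -> list[GeneTree]:
    """Draw ``n_genes`` true gene genealogies under the MSC.

    Branch lengths are in coalescent units; no support values (these are
    true trees, not estimates).  Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [parse_newick(_sim_one_genealogy(params, rng)) for _ in range(params.n_genes)]


# ---------------------------------------------------------------------
# sequence simulation


def sim_alignment(
    tree: GeneTree,
    model: SubstitutionModel,
    sites: int,
    seed: int | np.random.Generator | None = None,
    length_scale: float = 1.0,
) -> Alignment:
    """Evolve sequences along a tree with branch lengths.

    Root states are drawn from the stationary frequencies; each site gets
    one discrete-gamma rate category; states evolve edge by edge through
    the model's transition matrices.  ``length_scale`` multiplies branch
    lengths (used to convert coalescent units to substitutions).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = model.n_states
    eig = model._eigen()
    n_cat = len(model.category_rates())
    cats = rng.integers(0, n_cat, size=sites)
    freqs = np.asarray(model.freqs)
    states: dict[int, np.ndarray] = {}
    root = tree.tree.seed_node
    states[id(root)] = rng.choice(k, size=sites, p=freqs)
    order = [n for n in tree.tree.preorder_node_iter() if n is not root]
    for node in order:
        t = (node.edge.length or 0.0) * length_scale
        parent = states[id(node.parent_node)]
        child = np.empty(sites, dtype=np.int64)
        P = model.transition_matrices(t, eig=eig)  # (ncat, k, k)
        Pc = np.cumsum(P, axis=2)
        u = rng.random(sites)
        for c in range(n_cat):
            in_c = cats == c
            for s in range(k):
                m = in_c & (parent == s)
                if m.any():
                    child[m] = np.searchsorted(Pc[c, s], u[m], side="right")
        states[id(node)] = np.clip(child, 0, k - 1)
    taxa, rows = [], []
    for leaf in tree.tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        rows.append(states[id(leaf)])
    alphabet = ("A", "C", "G", "T") if k == 4 else tuple(str(i) for i in range(k))
    return Alignment(tuple(taxa), np.stack(rows).astype(np.int16), alphabet)


# ---------------------------------------------------------------------
# gene-tree estimation (NJ + bootstrap)


def _corrected_distances(mism: np.ndarray, valid: np.ndarray, w: np.ndarray,
                         k: int, cap: float = 5.0) -> np.ndarray:
    """Jukes-Cantor-type distance per pair from weighted mismatch counts."""
    num = mism @ w
    den = valid @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(den > 0, num / den, 0.0)
        arg = 1.0 - p * k / (k - 1.0)
        d = np.where(arg > 0, -(k - 1.0) / k * np.log(np.clip(arg, 1e-12, None)), cap)
    return np.minimum(d, cap)


def _nj_splits(dist_condensed: np.ndarray, taxa: list[str]) -> tuple[str, set[frozenset]]:
    n = len(taxa)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = dist_condensed
    m += m.T
    tree = nj(DistanceMatrix(m, taxa))
    all_leaves = frozenset(taxa)
    splits = set()
    for node in tree.non_tips():
        below = frozenset(t.name for t in node.tips())
        if 2 <= len(below) <= n - 2:
            splits.add(min(below, all_leaves - below, key=sorted))
    return str(tree), splits


def estimate_gene_tree(
    aln: Alignment,
    model: SubstitutionModel | None = None,
    bootstrap_reps: int = 100,
    seed: int | np.random.Generator | None = None,
) -> GeneTree:
    """Neighbor joining on corrected distances, with bootstrap supports.

    Distances use the k-state Jukes-Cantor correction (saturated pairs
    capped, with a warning); supports are the percentage of
    site-resampled replicates whose NJ tree contains each internal
    bipartition of the point-estimate tree.  ``bootstrap_reps=0`` yields
    a tree with missing supports.
    """
    if len(aln.taxa) < 4:
        raise ValueError("need at least four taxa to estimate an unrooted tree")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = aln.n_states if model is None else model.n_states
    taxa = list(aln.taxa)
    n = len(taxa)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    mat = aln.matrix
    mism = np.stack([(mat[i] != mat[j]) & (mat[i] >= 0) & (mat[j] >= 0)
                     for i, j in pairs]).astype(float)
    valid = np.stack([(mat[i] >= 0) & (mat[j] >= 0) for i, j in pairs]).astype(float)
    w0 = np.ones(aln.n_sites)
    if not np.all((mism @ w0) / np.clip(valid @ w0, 1, None) < (k - 1.0) / k):
        warnings.warn("saturated pairwise distance capped", stacklevel=2)
    nwk, splits = _nj_splits(_corrected_distances(mism, valid, w0, k), taxa)
    tree = parse_newick(nwk, support_scale="percent")
    # NJ can emit slightly negative branch lengths; clamp for downstream use
    for node in tree.tree.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            node.edge.length = 0.0
        node.support = None
    if bootstrap_reps > 0:
        hits = {s: 0 for s in splits}
        p = np.full(aln.n_sites, 1.0 / aln.n_sites)
        for _ in range(bootstrap_reps):
            w = rng.multinomial(aln.n_sites, p).astype(float)
            _, bs = _nj_splits(_corrected_distances(mism, valid, w, k), taxa)
            for s in splits:
                if s in bs:
                    hits[s] += 1
        all_leaves = frozenset(taxa)
        for edge in tree.internal_edges():
            below = frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())
            key = min(below, all_leaves - below, key=sorted)
            if key in hits:
                edge.head_node.support = 100.0 * hits[key] / bootstrap_reps
    return tree


# ---------------------------------------------------------------------
# end-to-end recovery


def recovery_experiment(
    params: MSCParams,
    threshold: float,
    seed: int | np.random.Generator | None = None,
    estimate_trees: bool = True,
    bootstrap_reps: int = 100,
    hypotheses: Sequence[RootHypothesis] = DEFAULT_HYPOTHESES,
    target: str = "Atlantogenata",
) -> dict:
    """Simulate, (optionally) estimate, classify, and recover t.

    With ``estimate_trees=False`` the true genealogies are classified
    directly (no supports; the threshold must then be 0).  Returns the
    concordance table plus the support fraction and coalescent-unit
    estimate for the target hypothesis, with binomial standard errors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not estimate_trees and threshold > 0:
        raise ValueError("true genealogies carry no supports; use threshold 0")
    gmap = default_group_map(params.lineages_per_group)
    genealogies = sim_gene_trees(params, rng)
    if estimate_trees:
        trees = []
        for g in genealogies:
            aln = sim_alignment(g, params.model, params.sites, rng,
                                length_scale=params.mut_scale)
            trees.append(estimate_gene_tree(aln, params.model, bootstrap_reps, rng))
    else:
        trees = genealogies
    table = classify_trees(trees, gmap, threshold, hypotheses=hypotheses)
    out = {"table": table, "n_genes": params.n_genes, "threshold": threshold}
    if table.decisive_total > 0:
        p_hat = table.support_fraction(target)
        out["p_hat"] = p_hat
        se_p = float(np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / table.decisive_total))
        out["p_se"] = se_p
        if p_hat < 1.0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out["t_hat"] = coalescent_length(p_hat)
            out["t_se"] = se_p / (1.0 - p_hat)  # delta method on -ln(3/2(1-p))
    return out
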