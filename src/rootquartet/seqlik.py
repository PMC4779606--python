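"""Fixed-topology likelihood engine.

Per-site and total log-likelihoods under GTR+Gamma (nucleotides) and the
k-state Mk / Mkv (morphology) models, by Felsenstein's pruning algorithm
with per-node scaling, plus coordinate-wise branch-length and parameter
optimization.  The Mkv variant conditions each site's likelihood on the
character being variable (the ascertainment correction for matrices that
exclude constant characters).

Likelihoods are exact log-likelihoods (underflow is absorbed into log
accumulators, never into rescaled scores), so values are comparable
across topologies — the property the AIC screen and AU test rely on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .treeio import Alignment, GeneTree

__all__ = [
    "SubstitutionModel",
    "SiteLikelihoodTable",
    "site_loglik",
    "total_loglik",
    "fit_branch_lengths",
    "loglik_under_hypotheses",
]

BL_MIN = 1e-8
BL_MAX = 20.0


@dataclass(frozen=True)
class SubstitutionModel:
    """A time-reversible substitution model with discrete-gamma rates.

    ``kind`` is ``"GTR"`` (general time reversible; free exchangeabilities
    and stationary frequencies), ``"Mk"`` (k-state symmetric) or ``"Mkv"``
    (Mk conditioned on variable sites).  The rate matrix is always scaled
    to one expected substitution per unit branch length.  ``alpha`` is the
    gamma shape for among-site rate variation (``None`` = single rate);
    category rates are the means of ``n_cat`` equal-probability quantile
    bands, the usual discrete-gamma convention.
    """

    kind: str = "GTR"
    n_states: int = 4
    exchangeabilities: tuple[float, ...] | None = None
    freqs: tuple[float, ...] | None = None
    alpha: float | None = None
    n_cat: int = 4

    def __post_init__(self):
        if self.kind not in ("GTR", "Mk", "Mkv"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")
        k = self.n_states
        n_ex = k * (k - 1) // 2
        if self.kind in ("Mk", "Mkv"):
            object.__setattr__(self, "exchangeabilities", (1.0,) * n_ex)
            object.__setattr__(self, "freqs", (1.0 / k,) * k)
        else:
            if self.exchangeabilities is None:
                object.__setattr__(self, "exchangeabilities", (1.0,) * n_ex)
            if self.freqs is None:
                object.__setattr__(self, "freqs", (1.0 / k,) * k)
        if len(self.exchangeabilities) != n_ex:
            raise ValueError(f"need {n_ex} exchangeabilities for k={k}")
        if len(self.freqs) != k or abs(sum(self.freqs) - 1.0) > 1e-8:
            raise ValueError("frequencies must be a length-k simplex point")

    # -- constructors --------------------------------------------------

    @classmethod
    def jc(cls, alpha: float | None = None, n_cat: int = 4) -> "SubstitutionModel":
        return cls("GTR", 4, None, None, alpha, n_cat)

    @classmethod
    def gtr(cls, exchangeabilities, freqs, alpha=None, n_cat=4) -> "SubstitutionModel":
        return cls("GTR", len(freqs), tuple(exchangeabilities), tuple(freqs), alpha, n_cat)

    @classmethod
    def mk(cls, k: int, alpha=None, n_cat=4) -> "SubstitutionModel":
        return cls("Mk", k, None, None, alpha, n_cat)

    @classmethod
    def mkv(cls, k: int, alpha=None, n_cat=4) -> "SubstitutionModel":
        return cls("Mkv", k, None, None, alpha, n_cat)

    @property
    def ascertainment(self) -> bool:
        return self.kind == "Mkv"

    # -- matrices ------------------------------------------------------

    def rate_matrix(self) -> np.ndarray:
        """Scaled rate matrix Q with -sum_i pi_i Q_ii = 1."""
        k = self.n_states
        pi = np.asarray(self.freqs)
        Q = np.zeros((k, k))
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                s = self.exchangeabilities[idx]
                Q[i, j] = s * pi[j]
                Q[j, i] = s * pi[i]
                idx += 1
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return Q / mu

    def _eigen(self):
        """Eigendecomposition via the symmetrized matrix (reversibility)."""
        pi = np.asarray(self.freqs)
        sq = np.sqrt(pi)
        B = self.rate_matrix() * sq[:, None] / sq[None, :]
        B = 0.5 * (B + B.T)
        lam, U = np.linalg.eigh(B)
        right = U / sq[:, None]  # rows scaled: V = D^-1/2 U
        left = U.T * sq[None, :]  # V^-1 = U^T D^1/2
        return lam, right, left

    def category_rates(self) -> np.ndarray:
        """Mean rate of each equal-probability gamma quantile band."""
        cached = getattr(self, "_rates_cache", None)
        if cached is not None:
            return cached
        rates = self._category_rates()
        object.__setattr__(self, "_rates_cache", rates)
        return rates

    def _category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.array([1.0])
        a, n = self.alpha, self.n_cat
        edges = gamma_dist.ppf(np.linspace(0, 1, n + 1), a, scale=1.0 / a)
        edges[0], edges[-1] = 0.0, np.inf
        upper = gammainc(a + 1, np.where(np.isinf(edges), np.inf, edges * a))
        rates = n * np.diff(upper)
        return rates / rates.mean() * 1.0

    def transition_matrices(self, t: float, eig=None) -> np.ndarray:
        """P(t * r_c) for every rate category; shape (n_cat, k, k)."""
        lam, right, left = eig if eig is not None else self._eigen()
        rates = self.category_rates()
        expo = np.exp(lam[None, :] * (rates[:, None] * t))  # (ncat, k)
        P = np.einsum("ik,ck,kj->cij", right, expo, left)
        return np.clip(P, 0.0, None)


@dataclass
class SiteLikelihoodTable:
    """Per-site log-likelihoods under each candidate topology for one gene."""

    gene_id: str
    hypotheses: tuple[str, ...]
    sitewise: np.ndarray  # (n_sites, n_hypotheses)
    fitted: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        self.sitewise = np.asarray(self.sitewise, dtype=float)
        if self.sitewise.ndim != 2 or self.sitewise.shape[1] != len(self.hypotheses):
            raise ValueError("sitewise matrix must be (n_sites, n_hypotheses)")

    @property
    def totals(self) -> np.ndarray:
        return self.sitewise.sum(axis=0)

    def best(self) -> tuple[str, ...]:
        """Hypotheses attaining the maximum total lnL (ties possible)."""
        tot = self.totals
        top = tot.max()
        return tuple(h for h, v in zip(self.hypotheses, tot) if v >= top - 1e-9)

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "hypotheses": list(self.hypotheses),
            "total_loglik": self.totals.tolist(),
            "fitted": self.fitted,
        }


# ---------------------------------------------------------------------
# pruning engine


class _Engine:
    """Pruning machinery bound to one (topology, alignment, model) triple.

    The tree is traversed as rooted at the seed node; for reversible
    models the likelihood does not depend on that choice.  Site patterns
    are compressed; per-node scaling keeps partials in range with a log
    accumulator per pattern.
    """

    def __init__(self, tree: GeneTree, aln: Alignment, model: SubstitutionModel):
        self.model = model
        self.k = model.n_states
        leaf_names = tree.leaves
        missing = leaf_names - set(aln.taxa)
        if missing:
            raise ValueError(f"no sequence for leaves: {sorted(missing)}")
        # postorder node list; edges identified by their head node
        self.nodes = list(tree.tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.root = self.index[id(tree.tree.seed_node)]
        self.parent = np.full(len(self.nodes), -1)
        self.children: list[list[int]] = [[] for _ in self.nodes]
        self.lengths = np.zeros(len(self.nodes))
        for i, n in enumerate(self.nodes):
            if n.parent_node is not None:
                p = self.index[id(n.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.lengths[i] = max(n.edge.length or 0.1, BL_MIN)
        # pattern compression over the tree's leaves only
        rows = np.stack([aln.row(n.taxon.label) if n.is_leaf() else
                         np.zeros(aln.n_sites, dtype=np.int16)
                         for n in self.nodes])
        leaf_mask = np.array([n.is_leaf() for n in self.nodes])
        cols = rows[leaf_mask].T
        patterns, self.site_to_pat, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.weights = counts.astype(float)
        self.npat = patterns.shape[0]
        if model.ascertainment:
            # append the k constant patterns used by the Mkv correction
            const = np.tile(np.arange(self.k, dtype=np.int16)[:, None],
                            (1, int(leaf_mask.sum())))
            patterns = np.vstack([patterns, const])
        self.npat_all = patterns.shape[0]
        self.leaf_partial: dict[int, np.ndarray] = {}
        li = 0
        for i, n in enumerate(self.nodes):
            if not leaf_mask[i]:
                continue
            codes = patterns[:, li]
            part = np.ones((self.npat_all, self.k))
            obs = codes >= 0
            part[obs] = 0.0
            part[np.where(obs)[0], codes[obs]] = 1.0
            self.leaf_partial[i] = part
            li += 1
        self.eig = model._eigen()
        self.rates = model.category_rates()
        self.ncat = len(self.rates)
        self.pi = np.asarray(model.freqs)
        self.is_leaf = leaf_mask

    def _pmat(self, t: float) -> np.ndarray:
        return self.model.transition_matrices(t, eig=self.eig)

    def _down_pass(self):
        """Conditional likelihoods of each subtree; returns per-node
        (ncat, npat, k) arrays, per-node up-messages through the parent
        edge, and per-node log scalers (npat,)."""
        down = [None] * len(self.nodes)
        msg = [None] * len(self.nodes)
        scale = [None] * len(self.nodes)
        for i in range(len(self.nodes)):
            if self.is_leaf[i]:
                d = np.broadcast_to(self.leaf_partial[i], (self.ncat, self.npat_all, self.k)).copy()
                s = np.zeros(self.npat_all)
            else:
                d = np.ones((self.ncat, self.npat_all, self.k))
                s = np.zeros(self.npat_all)
                for c in self.children[i]:
                    d = d * msg[c]
                    s = s + scale[c]
                m = d.max(axis=(0, 2))
                bad = m <= 0
                m = np.where(bad, 1.0, m)
                d = d / m[None, :, None]
                s = s + np.where(bad, -np.inf, np.log(m))
            down[i] = d
            scale[i] = s
            if self.parent[i] >= 0:
                P = self._pmat(self.lengths[i])
                msg[i] = np.einsum("cij,cpj->cpi", P, d)
        return down, msg, scale

    def _site_logliks_from_root(self, root_partial, root_scale) -> np.ndarray:
        like = np.einsum("cpi,i->pc", root_partial, self.pi).mean(axis=1)
        with np.errstate(divide="ignore"):
            lnl = np.log(like) + root_scale
        return lnl

    def pattern_logliks(self) -> np.ndarray:
        down, _, scale = self._down_pass()
        return self._site_logliks_from_root(down[self.root], scale[self.root])

    def site_logliks(self) -> np.ndarray:
        lnl = self.pattern_logliks()
        if self.model.ascertainment:
            lnl = self._apply_mkv(lnl)
        return lnl[self.site_to_pat]

    def _apply_mkv(self, pattern_lnl: np.ndarray) -> np.ndarray:
        const = pattern_lnl[self.npat :]
        p_const = np.exp(const).sum()
        if p_const >= 1.0:
            raise FloatingPointError("constant-pattern probability >= 1")
        return pattern_lnl[: self.npat] - math.log1p(-p_const)

    def total_loglik(self) -> float:
        lnl = self.pattern_logliks()
        if self.model.ascertainment:
            return float(self._apply_mkv(lnl) @ self.weights)
        return float(lnl[: self.npat] @ self.weights)

    # -- branch-length optimization -------------------------------------

    def _up_pass(self, down, msg, dscale):
        """Likelihood of the data outside each node's subtree, conditional
        on the state at the node's parent."""
        up = [None] * len(self.nodes)
        uscale = [None] * len(self.nodes)
        order = [i for i in reversed(range(len(self.nodes))) if self.parent[i] >= 0]
        for i in order:
            p = self.parent[i]
            if p == self.root:
                u = np.broadcast_to(self.pi, (self.ncat, self.npat_all, self.k)).copy()
                s = np.zeros(self.npat_all)
            else:
                P = self._pmat(self.lengths[p])
                u = np.einsum("cpi,cij->cpj", up[p], P)
                s = uscale[p].copy()
            for sib in self.children[p]:
                if sib != i:
                    u = u * msg[sib]
                    s = s + dscale[sib]
            m = u.max(axis=(0, 2))
            bad = m <= 0
            m = np.where(bad, 1.0, m)
            up[i] = u / m[None, :, None]
            uscale[i] = s + np.where(bad, -np.inf, np.log(m))
        return up, uscale

    def _edge_objective(self, i, up_i, down_i, sc):
        """Total lnL as a function of edge i's length, everything else fixed."""

        def f(t):
            P = self._pmat(t)
            like = np.einsum("cpi,cij,cpj->pc", up_i, P, down_i).mean(axis=1)
            with np.errstate(divide="ignore"):
                lnl = np.log(np.clip(like, 1e-300, None)) + sc
            if self.model.ascertainment:
                lnl = self._apply_mkv(lnl)
                return float(lnl @ self.weights)
            return float(lnl[: self.npat] @ self.weights)

        return f

    def optimize_branch_lengths(self, tol=1e-6, max_sweeps=20) -> float:
        edges = [i for i in range(len(self.nodes)) if self.parent[i] >= 0]
        best = self.total_loglik()
        for _ in range(max_sweeps):
            start = best
            for i in edges:
                down, msg, dscale = self._down_pass()
                up, uscale = self._up_pass(down, msg, dscale)
                f = self._edge_objective(i, up[i], down[i], dscale[i] + uscale[i])
                res = minimize_scalar(
                    lambda t: -f(t),
                    bounds=(BL_MIN, BL_MAX),
                    method="bounded",
                    options={"xatol": 1e-7},
                )
                if -res.fun > best:
                    self.lengths[i] = float(res.x)
                    best = -res.fun
            if best - start < tol:
                break
        else:
            warnings.warn("branch-length optimization did not converge", stacklevel=2)
        return best

    def write_lengths(self, tree: GeneTree) -> None:
        for i, n in enumerate(self.nodes):
            if self.parent[i] >= 0:
                n.edge.length = float(self.lengths[i])


# ---------------------------------------------------------------------
# public operations


def site_loglik(aln: Alignment, tree: GeneTree, model: SubstitutionModel) -> np.ndarray:
    """Per-site log-likelihoods of the alignment on a tree with branch lengths.

    Missing symbols contribute full-uncertainty partials (an all-missing
    column has log-likelihood 0 under GTR/Mk).  Under Mkv each site's
    log-likelihood is conditioned on variability:
    lnL_site - ln(1 - sum_s L(constant_s)).
    """
    return _Engine(tree, aln, model).site_logliks()


def total_loglik(aln: Alignment, tree: GeneTree, model: SubstitutionModel) -> float:
    return _Engine(tree, aln, model).total_loglik()


def _empirical_freqs(aln: Alignment, k: int) -> tuple[float, ...]:
    counts = np.bincount(aln.matrix[aln.matrix >= 0].ravel(), minlength=k).astype(float)
    counts += 0.5  # avoid zero frequencies on short alignments
    return tuple(counts / counts.sum())


def fit_branch_lengths(
    aln: Alignment,
    topology: GeneTree,
    model: SubstitutionModel,
    optimize_alpha: bool = False,
    optimize_freqs: bool = False,
    optimize_exchangeabilities: bool = False,
    tol: float = 1e-6,
    max_rounds: int = 10,
) -> tuple[GeneTree, SubstitutionModel, float]:
    """Maximize total lnL over branch lengths (and flagged parameters).

    Coordinate-wise: each branch by bounded scalar search on [1e-8, 20],
    sweeping until a full sweep improves lnL by < 1e-6.  Deterministic
    given inputs.  Returns a fitted copy of the topology, the (possibly
    updated) model, and the maximized total log-likelihood.
    """
    fitted = topology.copy()
    if optimize_freqs and model.kind == "GTR":
        model = replace(model, freqs=_empirical_freqs(aln, model.n_states))

    def rebuild():
        return _Engine(fitted, aln, model)

    eng = rebuild()
    best = eng.optimize_branch_lengths(tol=tol)
    eng.write_lengths(fitted)

    for _ in range(max_rounds if (optimize_alpha or optimize_exchangeabilities) else 0):
        prev = best
        if optimize_alpha and model.alpha is not None:

            def neg_alpha(log_a):
                m = replace(model, alpha=float(np.exp(log_a)))
                return -_Engine(fitted, aln, m).total_loglik()

            res = minimize_scalar(neg_alpha, bounds=(np.log(0.02), np.log(100.0)),
                                  method="bounded", options={"xatol": 1e-4})
            model = replace(model, alpha=float(np.exp(res.x)))
        if optimize_exchangeabilities and model.kind == "GTR":
            n_ex = len(model.exchangeabilities)

            def neg_ex(log_s):
                s = np.exp(np.append(log_s, 0.0))  # last exchangeability fixed
                m = replace(model, exchangeabilities=tuple(s))
                return -_Engine(fitted, aln, m).total_loglik()

            x0 = np.log(np.asarray(model.exchangeabilities[:-1])
                        / model.exchangeabilities[-1])
            res = minimize(neg_ex, x0, method="L-BFGS-B")
            s = np.exp(np.append(res.x, 0.0))
            model = replace(model, exchangeabilities=tuple(s / s[-1]))
        eng = rebuild()
        best = eng.optimize_branch_lengths(tol=tol)
        eng.write_lengths(fitted)
        if best - prev < tol:
            break
    return fitted, model, best


def loglik_under_hypotheses(
    aln: Alignment,
    hypotheses: Mapping[str, GeneTree],
    model: SubstitutionModel,
    gene_id: str = "",
    **fit_kwargs,
) -> SiteLikelihoodTable:
    """Fit branch lengths independently under each candidate topology and
    retain the per-site log-likelihood vectors for downstream testing."""
    names = tuple(hypotheses)
    cols, fitted_rec = [], {}
    for name in names:
        tree, m, lnl = fit_branch_lengths(aln, hypotheses[name], model, **fit_kwargs)
        cols.append(site_loglik(aln, tree, m))
        fitted_rec[name] = {
            "total_loglik": lnl,
            "alpha": m.alpha,
            "tree": tree.to_newick(with_supports=False),
        }
    return SiteLikelihoodTable(gene_id, names, np.column_stack(cols), fitted_rec)
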