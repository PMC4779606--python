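"""Per-gene and whole-alignment topology tests.

Three layers, in increasing stringency:

* ``tally_best`` — how many genes have each hypothesis as their maximum
  likelihood topology, ignoring significance;
* ``aic_screen`` — which of those genes support their best topology
  *significantly* better than the best rival (equal parameter counts
  across hypotheses make delta-AIC = 2 * delta-lnL);
* ``au_test`` — the approximately unbiased test: multiscale RELL
  bootstrap of the per-site log-likelihoods, normal-quantile regression
  of bootstrap proportions over scales, p = 1 - Phi(d - c).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .seqlik import SiteLikelihoodTable

__all__ = [
    "TopologyTestResult",
    "tally_best",
    "aic_screen",
    "au_test",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))
TIED = "tied"
INDECISIVE = "indecisive"


@dataclass
class TopologyTestResult:
    """Per-gene test summary: best topology, margins, AU p-values."""

    gene_id: str
    hypotheses: tuple[str, ...]
    best: tuple[str, ...]
    delta_lnl: float
    delta_aic: dict[str, float]
    significant: bool
    au_pvalues: dict[str, float] | None = None
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "best": list(self.best),
            "delta_lnl": self.delta_lnl,
            "delta_aic": self.delta_aic,
            "significant": self.significant,
            "au_pvalues": self.au_pvalues,
            "settings": self.settings,
        }


def tally_best(tables: Sequence[SiteLikelihoodTable]) -> dict[str, int]:
    """Count, per hypothesis, the genes where it is the ML topology.

    Genes whose maximum is attained by more than one hypothesis go into
    an explicit ``"tied"`` bin rather than being split arbitrarily.
    """
    if not tables:
        return {}
    names = tables[0].hypotheses
    if len(names) < 2:
        raise ValueError("need at least two hypotheses to tally")
    counts = {n: 0 for n in names}
    counts[TIED] = 0
    for tab in tables:
        best = tab.best()
        if len(best) == 1:
            counts[best[0]] += 1
        else:
            counts[TIED] += 1
    return counts


def aic_screen(
    tables: Sequence[SiteLikelihoodTable], delta_threshold: float = 2.0
) -> dict[str, float]:
    """Fraction of genes significantly supporting each hypothesis.

    A gene significantly supports its best topology when the AIC margin
    over the best rival reaches ``delta_threshold``; with a shared model
    and equal free-branch counts across hypotheses the margin is
    2 * (lnL_best - lnL_runner_up).  Everything else is indecisive.
    Fractions (including ``"indecisive"``) sum to 1.
    """
    if delta_threshold <= 0:
        raise ValueError("delta_threshold must be positive")
    if not tables:
        return {}
    names = tables[0].hypotheses
    frac = {n: 0.0 for n in names}
    frac[INDECISIVE] = 0.0
    for tab in tables:
        tot = tab.totals
        order = np.argsort(tot)[::-1]
        margin = 2.0 * (tot[order[0]] - tot[order[1]])
        if margin >= delta_threshold:
            frac[names[order[0]]] += 1.0
        else:
            frac[INDECISIVE] += 1.0
    n = len(tables)
    return {k: v / n for k, v in frac.items()}


def _bp_matrix(sitewise: np.ndarray, scales, n_boot: int, rng: np.random.Generator,
               chunk: int = 2000) -> np.ndarray:
    """Bootstrap proportions BP[scale, tree] from RELL resampling.

    For scale r, replicates of round(r * n) sites are drawn with
    replacement (as multinomial site counts); BP is the fraction of
    replicates in which each tree attains the maximum resampled lnL,
    ties split evenly.
    """
    n, k = sitewise.shape
    # sites with identical likelihood rows are exchangeable under RELL:
    # resample over unique rows with multiplicity-weighted probabilities
    rows, counts = np.unique(sitewise, axis=0, return_counts=True)
    sitewise = rows
    bp = np.zeros((len(scales), k))
    p = counts / n
    for si, r in enumerate(scales):
        m = max(int(round(r * n)), 1)
        done = 0
        wins = np.zeros(k)
        while done < n_boot:
            b = min(chunk, n_boot - done)
            counts = rng.multinomial(m, p, size=b)
            tot = counts @ sitewise  # (b, k)
            top = tot.max(axis=1, keepdims=True)
            is_top = tot >= top - 1e-12
            wins += (is_top / is_top.sum(axis=1, keepdims=True)).sum(axis=0)
            done += b
        bp[si] = wins / n_boot
    return bp


def au_test(
    sitewise: np.ndarray | SiteLikelihoodTable,
    scales: Sequence[float] = DEFAULT_SCALES,
    n_boot: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Approximately unbiased p-value for each candidate tree.

    For each scale r, ``n_boot`` RELL replicates of size round(r*n) are
    drawn; the bootstrap proportion BP_r of each tree is mapped through
    the normal quantile, z_r = Phi^-1(1 - BP_r), and fitted by weighted
    least squares to z_r = d*sqrt(r) + c/sqrt(r).  The AU p-value is
    1 - Phi(d - c).  A tree with BP 0 (or 1) at every scale gets p = 0
    (or 1) directly.
    """
    if isinstance(sitewise, SiteLikelihoodTable):
        sitewise = sitewise.sitewise
    sitewise = np.asarray(sitewise, dtype=float)
    n, k = sitewise.shape
    if k < 2:
        raise ValueError("need at least two trees")
    if n < 2:
        raise ValueError("need at least two sites")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if np.allclose(sitewise, sitewise[:, [0]], atol=1e-12):
        import warnings

        warnings.warn("all trees have identical site likelihoods", stacklevel=2)
        return np.ones(k)

    scales = np.asarray(scales, dtype=float)
    bp = _bp_matrix(sitewise, scales, n_boot, rng)
    pvals = np.empty(k)
    sqrt_r = np.sqrt(scales)
    X = np.column_stack([sqrt_r, 1.0 / sqrt_r])
    for j in range(k):
        bpj = bp[:, j]
        if np.all(bpj <= 0):
            pvals[j] = 0.0
            continue
        if np.all(bpj >= 1):
            pvals[j] = 1.0
            continue
        # clip so the quantile transform stays finite at the observed B
        bpc = np.clip(bpj, 0.5 / n_boot, 1 - 0.5 / n_boot)
        z = norm.ppf(1.0 - bpc)
        # binomial delta-method weights: Var(z) = BP(1-BP) / (B phi(z)^2)
        w = n_boot * norm.pdf(z) ** 2 / (bpc * (1 - bpc))
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        d, c = beta
        pvals[j] = float(1.0 - norm.cdf(d - c))
    return pvals
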