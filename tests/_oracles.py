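"""Independent brute-force oracles shared by unit and acceptance tests."""

import itertools

import numpy as np


def brute_force_site_loglik(aln, tree, model):
    """Explicit sum over all internal-node state assignments, averaged
    over gamma categories.  Exponential in tree size; for tiny trees only."""
    k = model.n_states
    nodes = list(tree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    root = tree.tree.seed_node
    rates = model.category_rates()
    pmats = {
        id(n): model.transition_matrices(n.edge.length or 0.0)
        for n in nodes
        if n.parent_node is not None
    }
    freqs = np.asarray(model.freqs)
    out = np.empty(aln.n_sites)
    for site in range(aln.n_sites):
        obs = {t: aln.row(t)[site] for t in aln.taxa}
        site_like = 0.0
        for c in range(len(rates)):
            total = 0.0
            for assign in itertools.product(range(k), repeat=len(internal)):
                states = dict(zip((id(n) for n in internal), assign))
                for n in nodes:
                    if n.is_leaf():
                        states[id(n)] = obs[n.taxon.label]
                prob = freqs[states[id(root)]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    s_par = states[id(n.parent_node)]
                    s_child = states[id(n)]
                    if s_child < 0:  # missing leaf: marginalize below
                        continue
                    prob *= pmats[id(n)][c, s_par, s_child]
                miss = [n for n in nodes if n.is_leaf() and states[id(n)] < 0]
                for n in miss:
                    s_par = states[id(n.parent_node)]
                    prob *= pmats[id(n)][c, s_par, :].sum()
                total += prob
            site_like += total / len(rates)
        out[site] = np.log(site_like)
    return out
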