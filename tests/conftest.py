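import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from rootquartet import (
    DEFAULT_HYPOTHESES,
    MSCParams,
    default_group_map,
    hypothesis_topology,
    sim_alignment,
    sim_gene_trees,
)
from rootquartet.simdata import DEFAULT_MODEL


@pytest.fixture
def gmap():
    return default_group_map()


@pytest.fixture
def quartet_taxa():
    return ("XEN_1", "AFR_1", "BOR_1", "OUT_1")


@pytest.fixture
def hyp_topologies(gmap, quartet_taxa):
    return {
        h.name: hypothesis_topology(quartet_taxa, gmap, h) for h in DEFAULT_HYPOTHESES
    }


@pytest.fixture
def small_gene(gmap):
    """One simulated gene: (genealogy, 300-site alignment) at t = 0.26."""
    params = MSCParams(t=0.26, n_genes=1, sites=300)
    rng = np.random.default_rng(42)
    tree = sim_gene_trees(params, rng)[0]
    aln = sim_alignment(tree, DEFAULT_MODEL, 300, rng, length_scale=params.mut_scale)
    return tree, aln
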