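"""Shared fixtures and the independent brute-force likelihood oracle."""

import itertools

import numpy as np
import pytest

from codonsel import SimulationConfig, SpeciesTree, simulate_alignment
from codonsel.model import encode_alignment


def brute_force_loglik(model, omega_by_class: dict, kappa: float) -> float:
    """Phylogenetic log-likelihood by explicit enumeration of ancestral states.

    Sums the joint probability over every assignment of the 61 codon states
    to every internal node, site by site — no pruning, no factorisation.
    Tips with missing data (state -1) are themselves summed over. Only
    feasible for tiny fixtures; that is the point: it is an independent
    check on the pruning implementation.
    """
    idx = model.index
    Ps = model._edge_Ps(omega_by_class, kappa)
    pi = model.pi
    taxa_order = [idx.leaf_taxon[i] for i in sorted(idx.leaf_taxon)]
    mat = encode_alignment(model.alignment, taxa_order)
    leafrow = {i: r for r, i in enumerate(sorted(idx.leaf_taxon))}
    internal = [n for n in idx.postorder if idx.children[n]]
    parent_of = {}
    for n in idx.postorder:
        for ch in idx.children[n]:
            parent_of[ch] = n
    lnL = 0.0
    for site in range(model.alignment.n_codons):
        free_nodes = list(internal)
        fixed = {}
        for n in idx.postorder:
            if not idx.children[n]:
                s = int(mat[leafrow[n], site])
                if s >= 0:
                    fixed[n] = s
                else:
                    free_nodes.append(n)  # missing tip: marginalise
        total = 0.0
        for assign in itertools.product(range(61), repeat=len(free_nodes)):
            states = dict(zip(free_nodes, assign))
            states.update(fixed)
            p = pi[states[idx.root]]
            for n in idx.postorder:
                if n == idx.root:
                    continue
                p *= Ps[n][states[parent_of[n]], states[n]]
            total += p
        lnL += np.log(total)
    return float(lnL)


@pytest.fixture(scope="session")
def brute_force():
    return brute_force_loglik


QUARTET_NEWICK = "((a:0.2,b:0.15):0.1,(c:0.3,d:0.05):0.07):0.0;"
EIGHT_TAXON_NEWICK = (
    "((((A:0.08,B:0.08):0.04,(C:0.10,D:0.10):0.02):0.04,"
    "(E:0.12,F:0.12):0.06):0.06,(G:0.15,H:0.15):0.09):0.0;"
)


@pytest.fixture()
def quartet_tree():
    return SpeciesTree.from_newick(QUARTET_NEWICK, foreground_taxa=["a", "b"])


@pytest.fixture()
def eight_taxon_tree():
    return SpeciesTree.from_newick(
        EIGHT_TAXON_NEWICK, foreground_taxa=["A", "B", "C"]
    )


@pytest.fixture()
def small_alignment(quartet_tree):
    cfg = SimulationConfig(tree=quartet_tree, n_codons=60, seed=11)
    return simulate_alignment(cfg)
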