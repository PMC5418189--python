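"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from psgscan.codon_model import (
    BACKGROUND_OMEGA,
    FOREGROUND_OMEGA,
    N_CLASSES,
    branch_site_class_mixture,
    build_codon_rate_matrix,
    stationary_rate,
)
from psgscan.genetics import standard_codon_space
from psgscan.phylo import Tree
from psgscan.simulate import SimulationConfig, simulate_codon_alignment, study_tree


@pytest.fixture(scope="session")
def space():
    return standard_codon_space()


@pytest.fixture()
def tree8():
    return study_tree()


@pytest.fixture(scope="session")
def small_selected_data():
    """6-taxon alignment with strong foreground selection (shared, read-only)."""
    tree = Tree.parse(
        "(((A:0.1,B:0.1):0.05,(C:0.1,D:0.1) #1:0.3):0.05,(E:0.1,F:0.1):0.05);"
    )
    cfg = SimulationConfig(
        tree.copy(), n_sites=200, kappa=2.0, omega0=0.2, omega2=8.0,
        p0=0.4, p1=0.4, seed=11,
    )
    alignment, truth = simulate_codon_alignment(cfg)
    return tree, alignment, truth


def brute_force_loglik(alignment, tree, params):
    """Exhaustive-enumeration branch-site log-likelihood.

    Sums the joint probability over all internal-node state assignments
    explicitly (no pruning, no rescaling); practical for trees with at
    most three internal nodes. Serves as the independent oracle for the
    pruning implementation.
    """
    space = alignment.space
    n = space.n_states
    pi = params.pi
    weights = branch_site_class_mixture(params.p0, params.p1)
    omegas = (params.omega0, 1.0, params.omega2)
    Qs = [build_codon_rate_matrix(params.kappa, om, pi, space, normalize=False)
          for om in omegas]
    rates = [stationary_rate(Q, pi) for Q in Qs]
    rho = sum(weights[k] * rates[BACKGROUND_OMEGA[k]] for k in range(N_CLASSES))

    from scipy.linalg import expm

    nodes = tree.nodes()  # postorder; root last
    internal = [nd for nd in nodes if not nd.is_leaf]
    root = nodes[-1]
    row = {t: i for i, t in enumerate(alignment.taxa)}

    def edge_P(node, klass):
        slot = FOREGROUND_OMEGA[klass] if node.foreground else BACKGROUND_OMEGA[klass]
        return expm(Qs[slot] * (node.length / rho))

    total = 0.0
    for site in range(alignment.n_sites):
        site_lik = 0.0
        for k in range(N_CLASSES):
            P = {id(nd): edge_P(nd, k) for nd in nodes if nd.parent is not None}
            lik = 0.0
            for assignment in itertools.product(range(n), repeat=len(internal)):
                state = {id(nd): s for nd, s in zip(internal, assignment)}
                p = pi[state[id(root)]]
                for nd in nodes:
                    if nd.parent is None:
                        continue
                    parent_state = state[id(nd.parent)]
                    if nd.is_leaf:
                        code = alignment.codes[row[nd.name], site]
                        p *= 1.0 if code < 0 else P[id(nd)][parent_state, code]
                    else:
                        p *= P[id(nd)][parent_state, state[id(nd)]]
                lik += p
            site_lik += weights[k] * lik
        total += np.log(site_lik)
    return total
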