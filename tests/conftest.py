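import numpy as np
import pytest

from axialtrends import Phylogeny
from axialtrends.simulate import SimulationConfig, simulate_trait, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_tip_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def caterpillar_tree():
    return Phylogeny.from_newick("(((A:1,B:1):1,C:2):1,D:3);")


def random_tree_and_trait(seed, n_tips, **cfg_kwargs):
    """Small random ultrametric tree plus a BM trait keyed by tip label."""
    cfg = SimulationConfig(n_tips=n_tips, seed=seed, **cfg_kwargs)
    tree = simulate_tree(cfg)
    node_values, tip_values = simulate_trait(tree, cfg)
    return tree, node_values, tip_values


def dense_gls_ancestral(tree, tip_values):
    """Brute-force GLS ancestral states from the explicit BM covariance.

    Independent oracle for the message-passing estimator: builds the
    full tip covariance C (shared root-to-MRCA path lengths), estimates
    the root by GLS, and predicts each internal node as the Gaussian
    conditional expectation given the tips.
    """
    depth = tree.node_depths()
    tips = list(tree.tip_indices)

    def ancestors(node):
        out, u = set(), int(node)
        while u != -1:
            out.add(u)
            u = int(tree.parent[u])
        return out

    anc = [ancestors(t) for t in tips]
    m = len(tips)
    cov = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            cov[a, b] = max(depth[u] for u in anc[a] & anc[b])
    x = np.array([tip_values[tree.node_id[t]] for t in tips])
    cov_inv = np.linalg.inv(cov)
    one = np.ones(m)
    mu = one @ cov_inv @ x / (one @ cov_inv @ one)
    estimates = {}
    for u in tree.internal_indices:
        if u == 0:
            estimates[tree.node_id[u]] = float(mu)
            continue
        anc_u = ancestors(u)
        c_u = np.array([max(depth[w] for w in anc_u & anc[a]) for a in range(m)])
        estimates[tree.node_id[u]] = float(mu + c_u @ cov_inv @ (x - mu * one))
    return estimates
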