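"""Maximum-likelihood ancestral states for a continuous trait under
Brownian motion (BM).

Under BM with rate sigma^2, trait values at the tips are jointly
Gaussian with covariance sigma^2 * (shared path length).  The ML
estimate of the state at an internal node equals the generalized
least squares (GLS) prediction given the tips, and is computed here by
Gaussian message passing on the tree (an upward "peeling" pass followed
by a downward pass), which is linear in the number of nodes and agrees
with the explicit dense GLS solve to numerical precision.  Estimates
are convex combinations of the tip values, hence always lie inside the
observed tip range, and do not depend on sigma^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError
from .trees import Phylogeny

__all__ = ["AncestralEstimateSet", "ml_ancestral_states", "branch_pairs"]


@dataclass
class AncestralEstimateSet:
    """ML ancestral states plus node ages and the BM rate estimate."""

    node_values: dict[str, float]  # internal node id -> trait estimate
    node_ages: dict[str, float]  # all node ids -> Myr before present
    sigma2_hat: float  # BM rate, trait^2 / Myr (ML, denominator n)
    tip_values: dict[str, float] = field(default_factory=dict)

    def value_of(self, node_id: str) -> float:
        if node_id in self.node_values:
            return self.node_values[node_id]
        return self.tip_values[node_id]


def _collapse_zero_internal_edges(tree: Phylogeny) -> Phylogeny:
    """Collapse zero-length internal edges (child merged into parent)."""
    zero_internal = [
        i
        for i in range(1, tree.n_nodes)
        if not tree.is_tip[i] and tree.lengths[i] == 0.0
    ]
    if not zero_internal:
        return tree
    warnings.warn(
        f"collapsed {len(zero_internal)} zero-length internal branch(es); "
        "ancestor and descendant share one estimate",
        stacklevel=3,
    )
    # rebuild: re-parent children of collapsed nodes onto the survivor
    survivor = list(range(tree.n_nodes))
    for i in zero_internal:
        survivor[i] = survivor[tree.parent[i]]
    keep = [i for i in range(tree.n_nodes) if survivor[i] == i]
    new_index = {old: new for new, old in enumerate(keep)}
    parent, lengths, labels = [], [], []
    for old in keep:
        if old == 0:
            parent.append(-1)
        else:
            parent.append(new_index[survivor[tree.parent[old]]])
        lengths.append(float(tree.lengths[old]))
        labels.append(tree.node_id[old] if tree.is_tip[old] else None)
    return Phylogeny(parent, lengths, labels)


def ml_ancestral_states(
    tree: Phylogeny, tip_values: Mapping[str, float]
) -> AncestralEstimateSet:
    """Estimate trait values at every internal node under BM by ML.

    Each node exchanges Gaussian (mean, variance) messages with its
    neighbours; the estimate at a node is the precision-weighted
    combination of the messages arriving from all incident subtrees.
    The root estimate from the upward pass alone is the classic pruning
    estimate; the downward pass extends it to all internal nodes,
    equivalently re-rooting at each node in turn.

    Zero-length internal branches are collapsed first (shared
    estimate); a zero-length terminal branch is an error because it
    forces the estimate onto the tip value and signals a malformed
    time tree.
    """
    if tree.n_tips < 2:
        raise DomainError("ancestral estimation needs at least 2 tips")
    missing = [t for t in tree.tip_labels if t not in tip_values]
    if missing:
        raise DomainError(f"missing tip values for {missing[:5]}")
    for t in tree.tip_labels:
        if not np.isfinite(tip_values[t]):
            raise DomainError(f"non-finite tip value for {t!r}")
    work = _collapse_zero_internal_edges(tree)
    if np.any(work.lengths[1:] <= 0):
        bad = int(np.flatnonzero(work.lengths[1:] <= 0)[0]) + 1
        raise DomainError(
            f"non-positive branch length at node {work.node_id[bad]!r} "
            "after collapsing zero internal edges"
        )

    n = work.n_nodes
    # upward pass: message from each node toward its parent, as the
    # conditional (mean, variance) of the node state given its subtree
    up_mean = np.zeros(n)
    up_var = np.zeros(n)
    contrast_sum = 0.0  # accumulates squared standardized contrasts for sigma2
    n_contrasts = 0
    for i in work.postorder():
        if work.is_tip[i]:
            up_mean[i] = tip_values[work.node_id[i]]
            up_var[i] = 0.0
        else:
            kids = work.children[i]
            ms = np.array([up_mean[c] for c in kids])
            vs = np.array([up_var[c] + work.lengths[c] for c in kids])
            prec = 1.0 / vs
            total = prec.sum()
            up_mean[i] = (ms * prec).sum() / total
            up_var[i] = 1.0 / total
            # REML-style contrasts for the rate (sequential peeling)
            m, v = ms[0], vs[0]
            for j in range(1, len(kids)):
                contrast_sum += (ms[j] - m) ** 2 / (vs[j] + v)
                n_contrasts += 1
                w1, w2 = 1.0 / v, 1.0 / vs[j]
                m = (m * w1 + ms[j] * w2) / (w1 + w2)
                v = 1.0 / (w1 + w2)

    # downward pass: message from the parent side of each edge
    down_mean = np.zeros(n)
    down_var = np.full(n, np.inf)  # root has no parent-side message
    for i in work.preorder():
        if work.is_tip[i]:
            continue
        for c in work.children[i]:
            # combine parent-side message of i with up-messages of siblings
            means, variances = [], []
            if np.isfinite(down_var[i]):
                means.append(down_mean[i])
                variances.append(down_var[i])
            for s in work.children[i]:
                if s != c:
                    means.append(up_mean[s])
                    variances.append(up_var[s] + work.lengths[s])
            prec = np.array([1.0 / v for v in variances])
            total = prec.sum()
            down_mean[c] = float(np.dot(means, prec) / total)
            down_var[c] = 1.0 / total + work.lengths[c]

    node_values: dict[str, float] = {}
    for i in work.internal_indices:
        means = [up_mean[c] for c in work.children[i]]
        variances = [up_var[c] + work.lengths[c] for c in work.children[i]]
        if np.isfinite(down_var[i]):
            means.append(down_mean[i])
            variances.append(down_var[i])
        prec = np.array([1.0 / v for v in variances])
        node_values[work.node_id[i]] = float(np.dot(means, prec) / prec.sum())

    sigma2_hat = contrast_sum / work.n_tips  # ML (not REML) denominator
    ages = work.node_ages()
    return AncestralEstimateSet(
        node_values=node_values,
        node_ages=ages,
        sigma2_hat=float(sigma2_hat),
        tip_values={t: float(tip_values[t]) for t in work.tip_labels},
    )


def branch_pairs(
    tree: Phylogeny,
    estimates: AncestralEstimateSet,
    include_tips: bool = False,
) -> pd.DataFrame:
    """One (ancestor value, descendant value) record per qualifying branch.

    By default only internal→internal branches qualify, so both members
    of every pair are ML node estimates; ``include_tips`` adds the
    terminal branches with the observed tip values as descendants.
    Columns: ancestor_id, descendant_id, ancestor_value,
    descendant_value, descendant_age, descendant_is_tip.
    """
    rows = []
    for i in range(1, tree.n_nodes):
        is_tip = bool(tree.is_tip[i])
        if is_tip and not include_tips:
            continue
        anc_id = tree.node_id[tree.parent[i]]
        dec_id = tree.node_id[i]
        if anc_id not in estimates.node_values:
            continue  # ancestor collapsed away or absent
        dec_value = (
            estimates.tip_values[dec_id] if is_tip else estimates.node_values.get(dec_id)
        )
        if dec_value is None:
            continue
        rows.append(
            {
                "ancestor_id": anc_id,
                "descendant_id": dec_id,
                "ancestor_value": estimates.node_values[anc_id],
                "descendant_value": dec_value,
                "descendant_age": estimates.node_ages.get(dec_id, np.nan),
                "descendant_is_tip": is_tip,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ancestor_id",
            "descendant_id",
            "ancestor_value",
            "descendant_value",
            "descendant_age",
            "descendant_is_tip",
        ],
    )
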