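"""Tree I/O, branch score distance, centroid selection, pruning, ages."""

import numpy as np
import pytest

from axialtrends import (
    Phylogeny,
    bsd_distance,
    bsd_matrix,
    centroid_tree,
    read_trees,
)
from axialtrends.errors import DomainError, FormatError
from axialtrends.simulate import SimulationConfig, simulate_tree


def test_read_multiple_newick_trees(tmp_path):
    path = tmp_path / "trees.nwk"
    path.write_text(
        "(A:1,(B:1,C:1):1);\n(A:2,(B:1,C:1):1);\n((A:1,B:1):1,C:2);\n"
    )
    trees = read_trees(path)
    assert len(trees) == 3
    assert trees[0].n_tips == 3
    # one internal non-root edge
    assert len(trees[0].internal_indices) == 2  # root + one internal


def test_nexus_translate_table_round_trip(tmp_path):
    newick = "((A:1,B:1):1,C:2);"
    nexus = (
        "#NEXUS\nBEGIN TAXA;\nDIMENSIONS NTAX=3;\nTAXLABELS A B C;\nEND;\n"
        "BEGIN TREES;\nTRANSLATE\n 1 A,\n 2 B,\n 3 C;\n"
        "TREE t1 = ((1:1,2:1):1,3:2);\nEND;\n"
    )
    path = tmp_path / "t.nex"
    path.write_text(nexus)
    (tree,) = read_trees(path)
    direct = Phylogeny.from_newick(newick)
    assert sorted(tree.tip_labels) == sorted(direct.tip_labels)
    labels, d1 = tree.tip_distance_matrix()
    labels2, d2 = direct.tip_distance_matrix()
    order = [labels.index(l) for l in labels2]
    assert np.allclose(d1[np.ix_(order, order)], d2)


def test_missing_branch_length_is_format_error(tmp_path):
    path = tmp_path / "bad.nwk"
    path.write_text("((A:1,B),C:2);\n")
    with pytest.raises(FormatError, match="length"):
        read_trees(path)


def test_explicitly_unrooted_tree_rejected(tmp_path):
    path = tmp_path / "unrooted.nwk"
    path.write_text("[&U] (A:1,B:1,C:1);\n")
    with pytest.raises(FormatError, match="unrooted"):
        read_trees(path)


# ----------------------------------------------------------------------
# branch score distance
# ----------------------------------------------------------------------
def test_bsd_zero_on_identical_trees():
    t = Phylogeny.from_newick("((A:1,B:2):1,C:2);")
    assert bsd_distance(t, t) == 0.0


def test_bsd_single_differing_branch():
    t1 = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    t2 = Phylogeny.from_newick("((A:1,B:1.75):1,C:2);")
    assert bsd_distance(t1, t2) == pytest.approx(0.75, abs=1e-12)


def test_bsd_unmatched_internal_bipartitions():
    # both topologies on 4 tips, all branch lengths 1: each tree has one
    # internal split (the bifurcating root's two edges merge, length 2),
    # unmatched across trees, so BSD = sqrt(2^2 + 2^2); pendant edges
    # all match.  Value cross-checked against phangorn's KF.dist.
    t1 = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = Phylogeny.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
    assert bsd_distance(t1, t2) == pytest.approx(np.sqrt(8.0), abs=1e-12)


def test_bsd_requires_same_tip_set():
    t1 = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    t2 = Phylogeny.from_newick("((A:1,B:1):1,D:2);")
    with pytest.raises(DomainError):
        bsd_distance(t1, t2)


def test_bsd_root_edge_convention():
    # the two edges of a bifurcating root form one split: only the sum
    # of their lengths matters under the default convention
    t1 = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):3);")
    t2 = Phylogeny.from_newick("((A:1,B:1):3,(C:1,D:1):1);")
    assert bsd_distance(t1, t2) == pytest.approx(0.0, abs=1e-12)
    assert bsd_distance(t1, t2, merge_root_edges=False) > 0


def test_bsd_pseudometric_on_random_trees():
    trees = [simulate_tree(SimulationConfig(n_tips=8, seed=s)) for s in range(6)]
    mat = bsd_matrix(trees)
    assert np.allclose(mat, mat.T)
    assert np.all(mat >= 0)
    n = len(trees)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert mat[i, j] <= mat[i, k] + mat[k, j] + 1e-12


# ----------------------------------------------------------------------
# centroid selection
# ----------------------------------------------------------------------
def test_centroid_of_identical_trees():
    t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    idx, mat = centroid_tree([t, t, t])
    assert idx == 0
    assert np.all(mat == 0)


def test_centroid_prefers_duplicated_tree():
    t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    far = Phylogeny.from_newick("((A:4,B:4):4,C:5);")
    d = bsd_distance(t, far)
    idx, mat = centroid_tree([t, t, far])
    assert idx == 0  # tie between the duplicates broken by lowest index
    assert mat.sum(axis=0)[0] == pytest.approx(d)
    assert mat.sum(axis=0)[2] == pytest.approx(2 * d)


def test_centroid_of_collinear_trees_is_middle():
    # interpolate branch lengths between two endpoint trees
    def scaled(w):
        return Phylogeny.from_newick(
            f"((A:{1 + 3 * w},B:1):1,C:{2 + 2 * w});"
        )

    trees = [scaled(0.0), scaled(0.5), scaled(1.0)]
    idx, _ = centroid_tree(trees)
    assert idx == 1


def test_centroid_matches_brute_force_on_random_sample():
    trees = [simulate_tree(SimulationConfig(n_tips=10, seed=s)) for s in range(12)]
    idx, mat = centroid_tree(trees)
    brute = min(
        range(len(trees)),
        key=lambda i: sum(bsd_distance(trees[i], t) for t in trees),
    )
    assert idx == brute
    assert np.argmin(mat.sum(axis=0)) == brute


# ----------------------------------------------------------------------
# node ages and pruning
# ----------------------------------------------------------------------
def test_node_ages_simple_trees():
    t = Phylogeny.from_newick("(A:2,B:2);")
    ages = t.node_ages()
    assert ages["N1"] == 2.0 and ages["A"] == 0.0 and ages["B"] == 0.0
    t2 = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    ages = t2.node_ages()
    assert ages["N1"] == 2.0 and ages["N2"] == 1.0
    assert all(ages[tip] == 0.0 for tip in "ABC")


def test_node_ages_match_path_length_oracle():
    tree = simulate_tree(SimulationConfig(n_tips=20, seed=7))
    ages = tree.node_ages()
    labels, dmat = tree.tip_distance_matrix()
    depth = tree.node_depths()
    height = max(depth[i] for i in tree.tip_indices)
    # every tip's age via an independent path-length computation
    for i, lab in enumerate(labels):
        tip_index = list(tree.tip_indices)[list(tree.tip_labels).index(lab)]
        assert ages[lab] == pytest.approx(height - depth[tip_index], abs=1e-10)
    # ultrametric: all tips at the present
    assert max(abs(ages[l]) for l in labels) < 1e-9


def test_non_ultrametric_tree_warns():
    t = Phylogeny.from_newick("((A:1,B:2):1,C:2);")
    with pytest.warns(UserWarning, match="ultrametric"):
        ages = t.node_ages()
    assert ages["A"] == pytest.approx(1.0)


def test_prune_keep_all_preserves_everything():
    tree = simulate_tree(SimulationConfig(n_tips=12, seed=3))
    pruned = tree.prune_to(tree.tip_labels)
    l1, d1 = tree.tip_distance_matrix()
    l2, d2 = pruned.tip_distance_matrix()
    order = [l2.index(l) for l in l1]
    assert np.allclose(d1, d2[np.ix_(order, order)], atol=1e-12)


def test_prune_preserves_pairwise_distances(caterpillar_tree):
    pruned = caterpillar_tree.prune_to(["A", "C", "D"])
    labels, dist = pruned.tip_distance_matrix()
    full_labels, full = caterpillar_tree.tip_distance_matrix()
    for a in ["A", "C", "D"]:
        for b in ["A", "C", "D"]:
            got = dist[labels.index(a), labels.index(b)]
            want = full[full_labels.index(a), full_labels.index(b)]
            assert got == pytest.approx(want, abs=1e-12)


def test_prune_random_trees_distance_oracle():
    rng = np.random.default_rng(5)
    for seed in range(4):
        tree = simulate_tree(SimulationConfig(n_tips=15, seed=seed))
        keep = list(rng.choice(tree.tip_labels, size=7, replace=False))
        pruned = tree.prune_to(keep)
        assert sorted(pruned.tip_labels) == sorted(keep)
        l1, d1 = tree.tip_distance_matrix()
        l2, d2 = pruned.tip_distance_matrix()
        for a in keep:
            for b in keep:
                assert d2[l2.index(a), l2.index(b)] == pytest.approx(
                    d1[l1.index(a), l1.index(b)], abs=1e-10
                )


def test_prune_errors():
    t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    with pytest.raises(DomainError):
        t.prune_to(["A"])
    with pytest.raises(DomainError):
        t.prune_to(["A", "nope"])
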