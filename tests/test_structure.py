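"""K2P/NJ/bootstrap, PCA + Tracy-Widom, and median-joining networks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import declinescan as ds
from conftest import build_gm


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------

def test_k2p_identical_sequences():
    assert ds.k2p_distance("ACGTACGT", "ACGTACGT") == 0.0


def test_k2p_one_transition_closed_form():
    d = ds.k2p_distance("AAAAAAAAAA", "GAAAAAAAAA")
    assert d == pytest.approx(-0.5 * math.log(0.8), rel=1e-12)


def test_k2p_pure_transversion_closed_form():
    # P=0, Q=0.1 over 10 sites: d = -1/2 ln(0.8 * sqrt(0.8))
    d = ds.k2p_distance("AAAAAAAAAA", "CAAAAAAAAA")
    assert d == pytest.approx(-0.5 * math.log(0.9 * math.sqrt(0.8)), rel=1e-12)


def test_k2p_drops_n_columns_pairwise():
    assert ds.k2p_distance("ANGT", "AAGT") == 0.0


def test_k2p_saturation_raises_with_counts():
    with pytest.raises(ds.SaturationError, match="P="):
        ds.k2p_distance("ACACACAC", "CACACACA")


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

def _path_lengths(tree):
    """Tip-to-tip path lengths from a skbio TreeNode."""
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for a, b in itertools.combinations(tips, 2):
        out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


def test_nj_recovers_four_taxon_additive_tree():
    """Distances from ((A:1,B:2):1,(C:3,D:4)) are inverted exactly."""
    want = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
    labels = ["A", "B", "C", "D"]
    m = np.zeros((4, 4))
    for (a, b), v in want.items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = v
    tree = ds.nj_tree(pd.DataFrame(m, index=labels, columns=labels))
    got = _path_lengths(tree)
    for k, v in want.items():
        assert got[k] == pytest.approx(v, abs=1e-9)


def test_nj_three_taxa_closed_form():
    m = pd.DataFrame([[0, 5, 9], [5, 0, 10], [9, 10, 0]],
                     index=list("ABC"), columns=list("ABC"))
    tree = ds.nj_tree(m)
    got = _path_lengths(tree)
    assert got[("A", "B")] == pytest.approx(5)
    assert got[("A", "C")] == pytest.approx(9)
    assert got[("B", "C")] == pytest.approx(10)


@pytest.mark.parametrize("seed", range(10))
def test_nj_exact_on_random_additive_matrices(seed):
    """Oracle: distances generated from a random tree are recovered exactly."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    labels = [f"t{i}" for i in range(n)]
    # random additive metric: random binary tree with positive branch lengths
    import skbio
    nodes = [skbio.TreeNode(name=l, length=float(rng.uniform(0.5, 3)))
             for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))[::-1]
        parent = skbio.TreeNode(length=float(rng.uniform(0.5, 3)))
        parent.extend([nodes.pop(int(i)), nodes.pop(int(j))])
        nodes.append(parent)
    root = skbio.TreeNode()
    root.extend(nodes)
    m = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        d = root.find(labels[a]).distance(root.find(labels[b]))
        m[a, b] = m[b, a] = d
    dm = pd.DataFrame(m, index=labels, columns=labels)
    tree = ds.nj_tree(dm)
    got = _path_lengths(tree)
    for a, b in itertools.combinations(sorted(labels), 2):
        assert got[(a, b)] == pytest.approx(m[labels.index(a), labels.index(b)],
                                            abs=1e-8)


def test_nj_agrees_with_skbio_on_additive_input():
    """Independent implementation cross-check on an additive matrix."""
    import skbio
    want = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
    labels = ["A", "B", "C", "D"]
    m = np.zeros((4, 4))
    for (a, b), v in want.items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = v
    theirs = skbio.tree.nj(skbio.DistanceMatrix(m, labels))
    mine = ds.nj_tree(pd.DataFrame(m, index=labels, columns=labels))
    d_theirs = {k: theirs.find(k[0]).distance(theirs.find(k[1]))
                for k in want}
    d_mine = _path_lengths(mine)
    for k in want:
        assert d_mine[k] == pytest.approx(d_theirs[k], abs=1e-9)


def test_nj_invariant_to_row_permutation():
    rng = np.random.default_rng(3)
    labels = list("ABCDEF")
    m = rng.uniform(1, 10, (6, 6))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    dm = pd.DataFrame(m, index=labels, columns=labels)
    perm = list(rng.permutation(labels))
    dm2 = dm.loc[perm, perm]
    t1 = _path_lengths(ds.nj_tree(dm))
    t2 = _path_lengths(ds.nj_tree(dm2))
    for k in t1:
        assert t1[k] == pytest.approx(t2[k], abs=1e-9)


def test_nj_duplicate_labels_rejected():
    m = pd.DataFrame(np.zeros((3, 3)), index=["A", "A", "B"],
                     columns=["A", "A", "B"])
    with pytest.raises(ValueError, match="duplicate"):
        ds.nj_tree(m)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _two_cluster_seqs(n_fixed=20, n_var=100, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), n_fixed + n_var)
    seqs = {}
    for grp, flip in (("x", False), ("y", True)):
        for k in range(3):
            s = base.copy()
            if flip:
                # >=20 fixed differences separate the clusters
                s[:n_fixed] = np.where(s[:n_fixed] == "A", "G", "A")
            # one private mutation per sequence
            s[n_fixed + k] = "T" if s[n_fixed + k] != "T" else "C"
            seqs[f"{grp}{k}"] = "".join(s)
    return seqs


def test_bootstrap_separated_clusters_full_support():
    seqs = _two_cluster_seqs()
    _tree, support = ds.bootstrap_support(seqs, n_reps=100, seed=1)
    split = frozenset(["x0", "x1", "x2"])
    assert support[split] == pytest.approx(1.0)


def test_bootstrap_deterministic_and_bounded():
    seqs = _two_cluster_seqs(seed=2)
    _t1, s1 = ds.bootstrap_support(seqs, n_reps=30, seed=9)
    _t2, s2 = ds.bootstrap_support(seqs, n_reps=30, seed=9)
    assert s1 == s2
    assert all(0.0 <= v <= 1.0 for v in s1.values())


def test_bootstrap_single_replicate_support_binary():
    seqs = _two_cluster_seqs(seed=3)
    _t, s = ds.bootstrap_support(seqs, n_reps=1, seed=4)
    assert set(s.values()) <= {0.0, 1.0}


def test_bootstrap_requires_columns():
    seqs = {"a": "ACGTA", "b": "ACGTT", "c": "ACGAA"}
    with pytest.raises(ValueError, match="10 columns"):
        ds.bootstrap_support(seqs, n_reps=5, seed=0)


# ---------------------------------------------------------------------------
# PCA + Tracy-Widom
# ---------------------------------------------------------------------------

def _two_pop_gm(seed=0, n_per=10, n_sites=300):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.8, n_sites)
    q = np.clip(p + rng.choice([-0.4, 0.4], n_sites), 0.02, 0.98)
    gt = np.vstack([rng.binomial(2, p, (n_per, n_sites)),
                    rng.binomial(2, q, (n_per, n_sites))]).T.astype(np.int8)
    return build_gm(gt, positions=np.arange(1, n_sites + 1))


def test_pca_planted_structure_separates_and_significant():
    gm = _two_pop_gm()
    res = ds.pca_genotypes(gm, n_axes=2)
    pc1 = res.coordinates["PC1"].to_numpy()
    assert (np.sign(pc1[:10]) != np.sign(pc1[10:])).all() or \
        (abs(pc1[:10].mean() - pc1[10:].mean())
         > 3 * (pc1[:10].std() + pc1[10:].std()))
    assert res.tw_pvalues[0] < 1e-6


def test_pca_null_tw_pvalues_calibrated():
    """Single panmictic population: leading TW p approximately uniform."""
    rng = np.random.default_rng(12)
    ps = []
    for _ in range(200):
        p = rng.uniform(0.1, 0.9, 300)
        gt = rng.binomial(2, p, (25, 300)).T.astype(np.int8)
        gm = build_gm(gt, positions=np.arange(1, 301))
        ps.append(ds.pca_genotypes(gm, n_axes=1).tw_pvalues[0])
    ps = np.array(ps)
    assert 0.3 < ps.mean() < 0.7
    assert (ps < 0.05).mean() < 0.12


def test_pca_duplicate_individuals_coincide():
    rng = np.random.default_rng(13)
    gt = rng.choice([0, 1, 2], size=(200, 8)).astype(np.int8)
    gt[:, 7] = gt[:, 6]
    gm = build_gm(gt, positions=np.arange(1, 201))
    res = ds.pca_genotypes(gm, n_axes=2)
    assert np.allclose(res.coordinates.iloc[6], res.coordinates.iloc[7],
                       atol=1e-8)


def test_pca_sample_reordering_invariance_up_to_sign():
    gm = _two_pop_gm(seed=5)
    res1 = ds.pca_genotypes(gm, n_axes=2)
    perm = list(np.random.default_rng(1).permutation(gm.samples))
    res2 = ds.pca_genotypes(gm.subset_samples(perm), n_axes=2)
    back = res2.coordinates.loc[gm.samples]
    for ax in ("PC1", "PC2"):
        a, b = res1.coordinates[ax], back[ax]
        assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


def test_pca_truncates_excess_axes_with_warning():
    gm = _two_pop_gm(seed=6, n_per=3, n_sites=100)
    with pytest.warns(UserWarning, match="rank"):
        res = ds.pca_genotypes(gm, n_axes=50)
    assert res.coordinates.shape[1] < 50


def test_pca_eigenvalues_descending():
    res = ds.pca_genotypes(_two_pop_gm(seed=7), n_axes=3)
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)


# ---------------------------------------------------------------------------
# median-joining
# ---------------------------------------------------------------------------

def test_mj_two_haplotypes_single_edge():
    g = ds.median_joining_network({"a": "AAAA", "b": "AAAT"})
    assert g.number_of_edges() == 1
    assert ds.network_total_length(g) == 1


def test_mj_triangle_adds_single_median():
    """{000, 110, 101} -> one Steiner vector 100; total length 3 (< any
    spanning tree's 4), matching the brute-force Steiner optimum."""
    g = ds.median_joining_network({"a": "AAA", "b": "TTA", "c": "TAT"})
    medians = [n for n, d in g.nodes(data=True) if d["median"]]
    assert medians == ["TAA"]
    assert ds.network_total_length(g) == 3
    best, added = ds.minimal_steiner_length(["AAA", "TTA", "TAT"])
    assert best == 3 and added == ["TAA"]


def test_mj_sampled_star_center_no_medians():
    center = "AAAAA"
    haps = {"c": center}
    for i in range(4):
        s = list(center)
        s[i] = "T"
        haps[f"h{i}"] = "".join(s)
    g = ds.median_joining_network(haps)
    assert not any(d["median"] for _, d in g.nodes(data=True))
    assert g.degree[center] == 4
    assert ds.network_total_length(g) == 4


def test_mj_unequal_lengths_rejected():
    with pytest.raises(ValueError, match="equal length"):
        ds.median_joining_network({"a": "AAA", "b": "AAAA"})


@pytest.mark.parametrize("seed", range(12))
def test_mj_matches_bruteforce_steiner_on_small_instances(seed):
    """On <=5 haplotypes x <=6 segregating sites the network's node set
    supports a spanning structure no longer than the brute-force Steiner
    optimum."""
    import networkx as nx
    rng = np.random.default_rng(seed)
    n_hap = int(rng.integers(3, 6))
    n_sites = int(rng.integers(3, 7))
    haps = {}
    while len(set(haps.values())) < n_hap:
        haps = {f"h{i}": "".join(rng.choice(["A", "T"], n_sites))
                for i in range(n_hap)}
    g = ds.median_joining_network(haps)
    best, _ = ds.minimal_steiner_length(list(haps.values()))
    # MST over the MJ node set
    nodes = list(g.nodes)
    k = nx.Graph()
    k.add_nodes_from(range(len(nodes)))
    for i, j in itertools.combinations(range(len(nodes)), 2):
        w = sum(x != y for x, y in zip(nodes[i], nodes[j]))
        k.add_edge(i, j, weight=w)
    mst = nx.minimum_spanning_tree(k)
    mj_len = sum(d["weight"] for _, _, d in mst.edges(data=True))
    assert mj_len == best


def test_mj_total_length_not_above_observed_mst():
    import networkx as nx
    rng = np.random.default_rng(99)
    haps = {f"h{i}": "".join(rng.choice(list("ACGT"), 8)) for i in range(6)}
    g = ds.median_joining_network(haps)
    obs = list(set(haps.values()))
    k = nx.Graph()
    for i, j in itertools.combinations(range(len(obs)), 2):
        k.add_edge(i, j, weight=sum(x != y for x, y in zip(obs[i], obs[j])))
    mst_obs = sum(d["weight"] for _, _, d
                  in nx.minimum_spanning_tree(k).edges(data=True))
    nodes = list(g.nodes)
    k2 = nx.Graph()
    k2.add_nodes_from(range(len(nodes)))
    for i, j in itertools.combinations(range(len(nodes)), 2):
        k2.add_edge(i, j, weight=sum(x != y for x, y in zip(nodes[i], nodes[j])))
    mj_mst = sum(d["weight"] for _, _, d
                 in nx.minimum_spanning_tree(k2).edges(data=True))
    assert mj_mst <= mst_obs


def test_mj_connected_and_medians_degree_three():
    import networkx as nx
    rng = np.random.default_rng(5)
    haps = {f"h{i}": "".join(rng.choice(["A", "G"], 7)) for i in range(5)}
    g = ds.median_joining_network(haps)
    assert nx.is_connected(g)
    for node, d in g.nodes(data=True):
        if d["median"]:
            assert g.degree[node] >= 3
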