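"""Phylogenies, PCA with Tracy-Widom significance, and haplotype networks.

* Kimura two-parameter distances with pairwise deletion of N-containing
  columns; neighbor-joining (Saitou-Nei, standard Q-criterion) with
  deterministic tie-breaking and non-negative branch lengths; bipartition
  bootstrap support by column resampling.
* Genotype PCA normalized per site by sqrt(p(1-p)) with per-axis
  Tracy-Widom statistics via Patterson-style moment matching.
* Bandelt median-joining networks: iterated minimum-spanning-network
  construction with consensus (Steiner) median vectors of connected
  triplets, pruning medians left with degree < 3.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """K2P distance undefined: too many differences for the correction."""


# ===========================================================================
# Kimura two-parameter distance
# ===========================================================================

def k2p_distance(seq_a: str, seq_b: str) -> float:
    """K2P distance d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)].

    P and Q are the transition and transversion proportions over columns
    where both sequences carry an unambiguous base (N columns dropped
    pairwise).  Raises :class:`SaturationError` when the log argument is
    non-positive.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    n = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P saturated: P={P:.3f}, Q={Q:.3f} over {n} sites"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance_matrix(seqs: Mapping[str, str]) -> pd.DataFrame:
    labels = list(seqs)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    m = np.zeros((len(labels), len(labels)))
    for i, j in itertools.combinations(range(len(labels)), 2):
        d = k2p_distance(seqs[labels[i]], seqs[labels[j]])
        m[i, j] = m[j, i] = d
    return pd.DataFrame(m, index=labels, columns=labels)


# ===========================================================================
# Neighbor-joining
# ===========================================================================

def nj_tree(dm: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor-joining on a labelled distance matrix.

    Additive matrices are recovered exactly.  Q-criterion ties are broken
    by the lexicographically lowest label pair, so output is deterministic.
    Negative branch lengths are clamped to 0 with the difference moved to
    the sister branch.  Returns an unrooted (trifurcating-root) tree.
    """
    labels = list(dm.index)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    D: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            D[(a, b)] = float(dm.iloc[i, j])
    nodes: dict[str, TreeNode] = {l: TreeNode(name=l) for l in labels}
    active = list(labels)
    counter = itertools.count()
    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (r - 2) * D[(a, b)] - row_sum[a] - row_sum[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        d_ab = D[(a, b)]
        la = 0.5 * d_ab + (row_sum[a] - row_sum[b]) / (2 * (r - 2))
        lb = d_ab - la
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        new = f"_nj{next(counter)}"
        parent = TreeNode(name=None)
        ca, cb = nodes.pop(a), nodes.pop(b)
        ca.length, cb.length = la, lb
        parent.extend([ca, cb])
        nodes[new] = parent
        for c in active:
            if c in (a, b):
                continue
            D[(new, c)] = D[(c, new)] = 0.5 * (D[(a, c)] + D[(b, c)] - d_ab)
        active = [c for c in active if c not in (a, b)] + [new]
    a, b, c = active
    la = 0.5 * (D[(a, b)] + D[(a, c)] - D[(b, c)])
    lb = 0.5 * (D[(a, b)] + D[(b, c)] - D[(a, c)])
    lc = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
    root = TreeNode(name=None)
    lengths = {a: la, b: lb, c: lc}
    for lbl in (a, b, c):
        child = nodes.pop(lbl)
        child.length = max(lengths[lbl], 0.0)
        root.append(child)
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions (as the smaller-side tip set per split)."""
    tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            other = tips - side
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def bootstrap_support(alignment: Mapping[str, str] | pd.DataFrame,
                      n_reps: int = 1000, seed: int = 0,
                      ) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Column-resampling bootstrap support for NJ tree bipartitions.

    ``alignment`` is either label->sequence (K2P distances) or a DataFrame
    of allele dosages (rows = sites, columns = samples; distances are mean
    absolute dosage differences / 2).  Returns the full-data tree and the
    support fraction for each of its non-trivial bipartitions.
    """
    rng = np.random.default_rng(seed)
    if isinstance(alignment, pd.DataFrame):
        mat = alignment.to_numpy(float)
        labels = list(alignment.columns)
        n_cols = mat.shape[0]

        def build(col_idx: np.ndarray) -> TreeNode:
            sub = mat[col_idx]
            diffs = np.zeros((len(labels), len(labels)))
            for i, j in itertools.combinations(range(len(labels)), 2):
                ok = ~np.isnan(sub[:, i]) & ~np.isnan(sub[:, j])
                d = np.abs(sub[ok, i] - sub[ok, j]).mean() / 2 if ok.any() else 0.0
                diffs[i, j] = diffs[j, i] = d
            return nj_tree(pd.DataFrame(diffs, index=labels, columns=labels))
    else:
        labels = list(alignment)
        arr = np.array([list(alignment[l]) for l in labels])
        n_cols = arr.shape[1]

        def build(col_idx: np.ndarray) -> TreeNode:
            seqs = {l: "".join(arr[i, col_idx]) for i, l in enumerate(labels)}
            return nj_tree(k2p_distance_matrix(seqs))

    if n_cols < 10:
        raise ValueError("need at least 10 columns to bootstrap")
    ref_tree = build(np.arange(n_cols))
    ref_splits = tree_bipartitions(ref_tree)
    counts = {s: 0 for s in ref_splits}
    n_ok = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        try:
            rep_splits = tree_bipartitions(build(idx))
        except (SaturationError, ValueError):
            continue  # e.g. a resample saturating the distance correction
        n_ok += 1
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    support = {s: c / max(n_ok, 1) for s, c in counts.items()}
    return ref_tree, support


# ===========================================================================
# PCA with Tracy-Widom significance
# ===========================================================================

# Chiani (2014): TW(beta=1) is closely approximated by a shifted gamma law.
_TW1_K = 46.44604884387787
_TW1_THETA = 0.18605402228279955
_TW1_SHIFT = 9.848007781128567


def tracy_widom_sf(x: float) -> float:
    """Upper-tail probability of the Tracy-Widom (beta=1) distribution."""
    return float(stats.gamma.sf(x + _TW1_SHIFT, a=_TW1_K, scale=_TW1_THETA))


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending
    coordinates: pd.DataFrame        # samples x PCs
    tw_stats: np.ndarray             # per returned axis
    tw_pvalues: np.ndarray


def pca_genotypes(gm, n_axes: int = 10,
                  n_eff_mode: str = "markers") -> PCAResult:
    """Genotype PCA with per-axis Tracy-Widom tests.

    Sites are centered by mean dosage and scaled by sqrt(p(1-p)) with p the
    sample allele frequency; monomorphic sites are dropped and missing
    genotypes contribute 0 after centering.  For axis k the eigenvalue is
    normalized against the residual spectrum (top k-1 axes removed) and
    standardized with
    ``mu = (sqrt(n'-1) + sqrt(m))^2 / n'`` and
    ``sigma = (sqrt(n'-1) + sqrt(m)) / n' * (1/sqrt(n'-1) + 1/sqrt(m))^(1/3)``
    where m is the residual eigenvalue count and n' the effective marker
    count.  With ``n_eff_mode='markers'`` (default, intended for LD-thinned
    input) n' is the number of polymorphic markers used — this is well
    calibrated for independent sites; ``'moments'`` estimates n' from the
    first two spectral moments instead, which additionally discounts
    residual LD but is noisier.
    """
    import warnings
    dos = gm.dosage()                       # sites x samples
    p = np.nanmean(dos, axis=1) / 2.0
    keep = (p > 0) & (p < 1)
    dos = dos[keep]
    p = p[keep]
    X = (dos - 2 * p[:, None]) / np.sqrt(p * (1 - p))[:, None]
    X = np.nan_to_num(X, nan=0.0)
    n = X.shape[1]
    C = X.T @ X / X.shape[0]
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int((evals > 1e-10).sum())
    if n_axes > rank:
        warnings.warn(f"requested {n_axes} axes but rank is {rank}; truncating",
                      stacklevel=2)
        n_axes = rank
    coords = evecs[:, :n_axes] * np.sqrt(np.maximum(evals[:n_axes], 0.0))
    cols = [f"PC{i + 1}" for i in range(n_axes)]
    coordinates = pd.DataFrame(coords, index=list(gm.samples), columns=cols)
    tw_stats, tw_p = [], []
    spectrum = evals[:rank]
    for k in range(n_axes):
        tail = spectrum[k:]
        m = len(tail)
        if m < 3:
            tw_stats.append(np.nan)
            tw_p.append(np.nan)
            continue
        s1 = tail.sum()
        if n_eff_mode == "markers":
            n_eff = float(X.shape[0])
        else:
            s2 = (tail ** 2).sum()
            denom = (m - 1) * s2 - s1 * s1
            if denom <= 0:
                tw_stats.append(np.nan)
                tw_p.append(np.nan)
                continue
            n_eff = (m + 1) * s1 * s1 / denom
        if n_eff <= 1:
            tw_stats.append(np.nan)
            tw_p.append(np.nan)
            continue
        ell = m * tail[0] / s1
        sq_n = math.sqrt(n_eff - 1)
        sq_m = math.sqrt(m)
        mu = (sq_n + sq_m) ** 2 / n_eff
        sigma = (sq_n + sq_m) / n_eff * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
        x = (ell - mu) / sigma
        tw_stats.append(x)
        tw_p.append(tracy_widom_sf(x))
    return PCAResult(evals[:rank], coordinates, np.array(tw_stats), np.array(tw_p))


# ===========================================================================
# Median-joining haplotype network
# ===========================================================================

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(nodes: list[str], epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Minimum-spanning-network edges (Kruskal keeping within-weight ties,
    plus edges within ``epsilon`` of the connecting weight class)."""
    n = len(nodes)
    edges = sorted(
        (_hamming(nodes[i], nodes[j]), i, j)
        for i, j in itertools.combinations(range(n), 2)
    )
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    kept = []
    k = 0
    while k < len(edges):
        w = edges[k][0]
        # evaluate the whole weight class against the current components
        group = []
        while k < len(edges) and edges[k][0] <= w + epsilon:
            group.append(edges[k])
            k += 1
        useful = [(wt, i, j) for wt, i, j in group if find(i) != find(j)]
        if not useful:
            continue
        for wt, i, j in useful:
            kept.append((wt, i, j))
        for wt, i, j in useful:
            pi, pj = find(i), find(j)
            if pi != pj:
                parent[pi] = pj
        if all(find(i) == find(0) for i in range(n)):
            break
    return kept


def _consensus_median(u: str, v: str, w: str) -> str:
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(a)  # three-way tie: keep the first sequence's state
    return "".join(out)


def median_joining_network(haplotypes: Mapping[str, str], epsilon: int = 0,
                           max_iter: int = 50) -> nx.Graph:
    """Bandelt median-joining network over aligned haplotypes.

    Nodes are haplotype strings; node attributes carry ``samples`` (labels
    of observed haplotypes; empty for inferred median vectors) and
    ``median`` (bool).  Edges carry integer ``weight`` mutation counts.
    Median (Steiner) vectors are consensus sequences of MSN-connected
    triplets; after convergence, medians with degree < 3 are pruned.
    """
    seqs = list(haplotypes.values())
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("haplotypes must be aligned to equal length")
    by_seq: dict[str, list[str]] = {}
    for label, s in haplotypes.items():
        by_seq.setdefault(s.upper(), []).append(label)
    observed = set(by_seq)
    nodes = sorted(observed)
    for _ in range(max_iter):
        if len(nodes) == 1:
            break
        edges = _msn_edges(nodes, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for _, i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        candidates: dict[str, int] = {}
        node_set = set(nodes)
        for u in adj:
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                med = _consensus_median(nodes[u], nodes[v], nodes[w])
                if med in node_set or med in candidates:
                    continue
                cost = (_hamming(med, nodes[u]) + _hamming(med, nodes[v])
                        + _hamming(med, nodes[w]))
                candidates[med] = cost
        if not candidates:
            break
        best_cost = min(candidates.values())
        new = sorted(m for m, c in candidates.items() if c <= best_cost + epsilon)
        nodes = sorted(set(nodes) | set(new))
    # prune obsolete median vectors: a median is kept only while it strictly
    # shortens the minimum spanning structure over the node set (this also
    # removes any median left with degree < 3)
    def _mst_length(node_list: list[str]) -> int:
        t = nx.Graph()
        t.add_nodes_from(range(len(node_list)))
        for i, j in itertools.combinations(range(len(node_list)), 2):
            t.add_edge(i, j, weight=_hamming(node_list[i], node_list[j]))
        return sum(d["weight"] for _, _, d
                   in nx.minimum_spanning_tree(t).edges(data=True))

    changed = True
    while changed:
        changed = False
        current = _mst_length(nodes)
        for med in [s for s in nodes if s not in observed]:
            without = [s for s in nodes if s != med]
            if _mst_length(without) <= current:
                nodes = without
                changed = True
                break
    g = nx.Graph()
    for s in nodes:
        g.add_node(s, samples=tuple(by_seq.get(s, ())), median=s not in observed,
                   multiplicity=len(by_seq.get(s, ())))
    if len(nodes) > 1:
        for wt, i, j in _msn_edges(nodes, epsilon):
            g.add_edge(nodes[i], nodes[j], weight=int(wt))
    return g


def network_total_length(g: nx.Graph) -> int:
    return int(sum(d["weight"] for _, _, d in g.edges(data=True)))


def minimal_steiner_length(haplotypes: Sequence[str]) -> tuple[int, list[str]]:
    """Brute-force minimal Steiner network (test-oracle scale only).

    Enumerates candidate intermediate vectors over the alleles observed per
    column, adds subsets of growing size, and returns the smallest achievable
    minimum-spanning-tree total length together with one optimal added set.
    """
    obs = sorted(set(haplotypes))
    columns = list(zip(*obs))
    alphabet = [sorted(set(col)) for col in columns]
    n_cand = int(np.prod([len(a) for a in alphabet]))
    if n_cand > 4096:
        raise ValueError("instance too large for brute force")
    candidates = ["".join(c) for c in itertools.product(*alphabet)]
    extras = [c for c in candidates if c not in obs]

    def mst_length(vs: Sequence[str]) -> int:
        g = nx.Graph()
        g.add_nodes_from(range(len(vs)))
        for i, j in itertools.combinations(range(len(vs)), 2):
            g.add_edge(i, j, weight=_hamming(vs[i], vs[j]))
        t = nx.minimum_spanning_tree(g)
        return int(sum(d["weight"] for _, _, d in t.edges(data=True)))

    best = mst_length(obs)
    best_set: list[str] = []
    for k in (1, 2, 3):
        improved = False
        for combo in itertools.combinations(extras, k):
            L = mst_length(obs + list(combo))
            if L < best:
                best, best_set = L, list(combo)
                improved = True
        if not improved and k >= 2:
            break
    return best, best_set
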