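"""Species-tree estimation by fragment consensus, and per-gene re-testing.

The species tree for the scan is built the robust way: the concatenated
coding alignment is cut into fixed-size fragments (15 knt by default), a
tree is estimated for every fragment, and the final topology is the
majority-rule consensus of the fragment trees. Per-fragment estimation is
neighbor joining from TN93 maximum-likelihood distances followed by
nearest-neighbor-interchange hill climbing under an HKY likelihood with
ML branch lengths — deterministic given the input.

Positively selected genes found with the global species tree are
re-tested with a tree estimated from that gene's alignment alone, which
guards against incomplete-lineage-sorting-style discordance producing
spurious foreground signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .alignment import CodonAlignment
from .codon_model import _prob_from_eigen, _reversible_eigen
from .fit import branch_site_lrt
from .phylo import Node, Tree

__all__ = [
    "FragmentSet",
    "fragment_alignment",
    "estimate_tree",
    "majority_consensus",
    "ConsensusTree",
    "per_gene_retest",
    "RetestResult",
]

NUC_INDEX = {"T": 0, "C": 1, "A": 2, "G": 3}


# --------------------------------------------------------------------------
# fragments
# --------------------------------------------------------------------------
@dataclass
class FragmentSet:
    """Contiguous tiling of a concatenated alignment (nucleotide coords)."""

    intervals: list  # (start, stop) 0-based half-open
    size: int

    def __len__(self):
        return len(self.intervals)


def fragment_alignment(total_length: int, size: int = 15_000, min_tail: int = 1_000) -> FragmentSet:
    """Tile ``total_length`` nucleotides into fragments of ``size``.

    A trailing remainder shorter than ``min_tail`` is merged into the
    previous fragment; otherwise it stays as a final short fragment.
    """
    if size < 1:
        raise ValueError("fragment size must be >= 1")
    if total_length < 1:
        raise ValueError("empty alignment")
    starts = list(range(0, total_length, size))
    intervals = [(s, min(s + size, total_length)) for s in starts]
    if len(intervals) > 1 and intervals[-1][1] - intervals[-1][0] < min_tail:
        last = intervals.pop()
        prev = intervals.pop()
        intervals.append((prev[0], last[1]))
    return FragmentSet(intervals, size)


# --------------------------------------------------------------------------
# distances and neighbor joining
# --------------------------------------------------------------------------
def _site_matrix(sequences: dict) -> tuple:
    names = list(sequences)
    length = {len(s) for s in sequences.values()}
    if len(length) != 1:
        raise ValueError("sequences must be aligned (equal lengths)")
    mat = np.full((len(names), length.pop()), -1, dtype=np.int8)
    for i, name in enumerate(names):
        for j, ch in enumerate(sequences[name].upper().replace("U", "T")):
            mat[i, j] = NUC_INDEX.get(ch, -1)
    return names, mat


def tn93_distance(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """TN93 ML distance between two encoded nucleotide rows (gaps skipped)."""
    ok = (row_a >= 0) & (row_b >= 0)
    a, b = row_a[ok], row_b[ok]
    n = len(a)
    if n == 0:
        return 0.0
    freqs = np.bincount(np.concatenate([a, b]), minlength=4) / (2 * n)
    gT, gC, gA, gG = freqs
    gR, gY = gA + gG, gT + gC
    diff = a != b
    p1 = np.mean(diff & (np.isin(a, (2, 3)) & np.isin(b, (2, 3))))  # A<->G
    p2 = np.mean(diff & (np.isin(a, (0, 1)) & np.isin(b, (0, 1))))  # C<->T
    q = np.mean(diff) - p1 - p2  # transversions
    with np.errstate(divide="ignore", invalid="ignore"):
        k1 = 2 * gA * gG / gR if gR > 0 else 0.0
        k2 = 2 * gT * gC / gY if gY > 0 else 0.0
        k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY) if gR > 0 < gY else 0.0
        w1 = 1 - p1 / k1 - q / (2 * gR) if k1 > 0 else 1.0
        w2 = 1 - p2 / k2 - q / (2 * gY) if k2 > 0 else 1.0
        w3 = 1 - q / (2 * gR * gY)
    if min(w1, w2, w3) <= 0:
        return 5.0  # saturated; cap
    d = -k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3)
    return float(max(d, 0.0))


def neighbor_joining(names: list, D: np.ndarray) -> Tree:
    """Classic NJ; deterministic tie-breaking by index order.

    Returns a tree rooted at the final three-way join (the conventional
    unrooted representation).
    """
    n = len(names)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes = [Node(name) for name in names]
    D = D.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                qv = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or qv < best[0] - 1e-12:
                    best = (qv, i, j)
        _, i, j = best
        vi = max(0.0, 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2)))
        vj = max(0.0, D[i, j] - vi)
        parent = Node()
        nodes[i].length, nodes[j].length = vi, vj
        parent.add(nodes[i])
        parent.add(nodes[j])
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        for x in active:
            if x in (i, j):
                continue
            D[k, x] = D[x, k] = max(0.0, 0.5 * (D[i, x] + D[j, x] - D[i, j]))
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]
    root = Node()
    if len(active) == 3:
        i, j, k = active
        di = max(0.0, 0.5 * (D[i, j] + D[i, k] - D[j, k]))
        dj = max(0.0, 0.5 * (D[i, j] + D[j, k] - D[i, k]))
        dk = max(0.0, 0.5 * (D[i, k] + D[j, k] - D[i, j]))
        for x, dx in zip((i, j, k), (di, dj, dk)):
            nodes[x].length = dx
            root.add(nodes[x])
    else:  # two taxa
        i, j = active
        nodes[i].length = D[i, j] / 2
        nodes[j].length = D[i, j] / 2
        root.add(nodes[i])
        root.add(nodes[j])
    return Tree(root)


# --------------------------------------------------------------------------
# HKY likelihood on a fixed topology
# --------------------------------------------------------------------------
class _HKYEngine:
    """Pruning likelihood for nucleotide data under HKY85."""

    def __init__(self, names: list, mat: np.ndarray):
        patterns, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True
        )
        self.names = names
        self.patterns = patterns
        self.weights = counts.astype(float)
        counts4 = np.bincount(mat[mat >= 0].ravel(), minlength=4).astype(float)
        counts4 += 1.0  # avoid zero frequencies on tiny fragments
        self.freqs = counts4 / counts4.sum()

    def _eigen(self, kappa: float):
        pi = self.freqs
        Q = np.tile(pi, (4, 1)).astype(float)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                if (i, j) in ((0, 1), (1, 0), (2, 3), (3, 2)):  # transitions
                    Q[i, j] *= kappa
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.dot(pi, np.diag(Q))
        Q /= rate
        return _reversible_eigen(Q, pi)

    def loglik(self, tree: Tree, kappa: float) -> float:
        lam, B, C = self._eigen(kappa)
        npat = self.patterns.shape[1]
        row = {name: i for i, name in enumerate(self.names)}
        ones = np.ones((4, 1))
        logscale = np.zeros(npat)
        partial = {}
        for node in tree.postorder():
            if node.is_leaf:
                continue
            M = None
            for child in node.children:
                P = np.hstack([_prob_from_eigen(lam, B, C, max(child.length, 0.0)), ones])
                if child.is_leaf:
                    codes = self.patterns[row[child.name]].astype(int).copy()
                    codes[codes < 0] = 4
                    contrib = P[:, codes]
                else:
                    contrib = P[:, :-1] @ partial[id(child)]
                M = contrib if M is None else M * contrib
            mx = M.max(axis=0)
            mx[mx <= 0] = 1.0
            M = M / mx
            logscale += np.log(mx)
            partial[id(node)] = M
        site = self.freqs @ partial[id(tree.root)]
        return float(np.dot(self.weights, np.log(np.maximum(site, 1e-300)) + logscale))

    def optimize(self, tree: Tree, kappa: float = 2.0, maxiter: int = 60):
        """ML branch lengths and kappa on a fixed topology (in place)."""
        edges = tree.edges()
        x0 = np.concatenate([[np.log(kappa)], np.log(np.maximum([e.length for e in edges], 1e-6))])
        bounds = [(np.log(0.05), np.log(50.0))] + [(np.log(1e-8), np.log(10.0))] * len(edges)

        def neg(x):
            for e, lx in zip(edges, x[1:]):
                e.length = float(np.exp(lx))
            return -self.loglik(tree, float(np.exp(x[0])))

        res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-10})
        for e, lx in zip(edges, res.x[1:]):
            e.length = float(np.exp(lx))
        return float(np.exp(res.x[0])), -res.fun


# ----------------------------------------------------------- unrooted NNI
def _to_adjacency(tree: Tree):
    """Unrooted adjacency map {node_id: [(other_id, length)]} plus labels."""
    nodes = tree.nodes()
    adj = {id(n): [] for n in nodes}
    label = {id(n): n.name for n in nodes}
    for n in nodes:
        if n.parent is not None:
            adj[id(n)].append([id(n.parent), n.length])
            adj[id(n.parent)].append([id(n), n.length])
    return adj, label


def _adjacency_to_tree(adj: dict, label: dict) -> Tree:
    # root at an internal node (highest degree) for a clean trifurcation
    root_id = max(adj, key=lambda k: (len(adj[k]), -list(adj).index(k)))
    built = {}

    def build(nid, parent_id, length):
        node = Node(label.get(nid, ""), length)
        for other, ln in adj[nid]:
            if other != parent_id:
                node.add(build(other, nid, ln))
        return node

    root = build(root_id, None, 0.0)
    return Tree(root)


def _nni_neighbors(tree: Tree):
    """All NNI rearrangements of an unrooted tree, as new Tree objects."""
    adj, label = _to_adjacency(tree)
    internal = [k for k in adj if len(adj[k]) >= 3]
    seen_edges = set()
    out = []
    for u in internal:
        for v, _ in adj[u]:
            if len(adj[v]) < 3 or (v, u) in seen_edges:
                continue
            seen_edges.add((u, v))
            u_sub = [x for x, _ in adj[u] if x != v][:2]
            v_sub = [x for x, _ in adj[v] if x != u][:2]
            for bswap in v_sub:
                a = u_sub[1]  # swap one fixed u-side subtree with each v-side
                new_adj = {k: [list(p) for p in ps] for k, ps in adj.items()}

                def relink(node_id, old, new):
                    for p in new_adj[node_id]:
                        if p[0] == old:
                            p[0] = new

                # a moves to v; bswap moves to u
                new_adj[u] = [[x, ln] if x != a else [bswap, ln] for x, ln in new_adj[u]]
                new_adj[v] = [[x, ln] if x != bswap else [a, ln] for x, ln in new_adj[v]]
                relink(a, u, v)
                relink(bswap, v, u)
                out.append(_adjacency_to_tree(new_adj, label))
    return out


def estimate_tree(sequences, kappa: float = 2.0, nni: bool = True, max_rounds: int = 8) -> Tree:
    """Estimate an unrooted ML-ish tree for aligned nucleotide sequences.

    ``sequences`` is either ``{name: aligned nucleotide string}`` or a
    :class:`CodonAlignment`. Pipeline: TN93 distances -> neighbor joining
    -> ML branch lengths and kappa under HKY -> NNI hill climbing until no
    rearrangement improves the likelihood. Deterministic given the input.
    """
    if isinstance(sequences, CodonAlignment):
        sequences = {t: sequences.sequence(t) for t in sequences.taxa}
    if len(sequences) < 3:
        raise ValueError("need at least 3 taxa to estimate a tree")
    names, mat = _site_matrix(sequences)
    order = sorted(range(len(names)), key=lambda i: names[i])
    names = [names[i] for i in order]
    mat = mat[order]

    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tn93_distance(mat[i], mat[j])
    tree = neighbor_joining(names, D)
    if np.all(D == 0):
        warnings.warn("all sequences identical: returning star-like tree with zero lengths")
        for e in tree.edges():
            e.length = 0.0
        return tree

    engine = _HKYEngine(names, mat)
    kappa, best = engine.optimize(tree, kappa)
    if not nni:
        return tree
    for _ in range(max_rounds):
        improved = False
        for cand in _nni_neighbors(tree):
            k2, lnl = engine.optimize(cand, kappa, maxiter=30)
            if lnl > best + 1e-6:
                tree, best, kappa = cand, lnl, k2
                improved = True
                break
        if not improved:
            break
    return tree


# --------------------------------------------------------------------------
# consensus
# --------------------------------------------------------------------------
@dataclass
class ConsensusTree:
    """Majority-rule consensus with bipartition supports."""

    tree: Tree
    supports: dict  # frozenset (non-anchor side) -> fraction of input trees
    rule: str = "majority"
    n_trees: int = 0


def majority_consensus(trees: list) -> ConsensusTree:
    """Strict-majority (> 50%) consensus of trees on one leaf set.

    Consensus branch lengths are the mean length of the bipartition over
    the trees that contain it (leaf edges average over all trees). Ties
    at exactly 50% are dropped.
    """
    if not trees:
        raise ValueError("no trees given")
    leafset = frozenset(trees[0].leaf_names())
    for idx, t in enumerate(trees):
        if frozenset(t.leaf_names()) != leafset:
            raise ValueError(f"tree {idx} has a different leaf set")
    n = len(trees)
    counts: dict = {}
    lengths: dict = {}
    leaf_lengths: dict = {name: [] for name in leafset}
    for t in trees:
        for split, ln in t.bipartitions().items():
            counts[split] = counts.get(split, 0) + 1
            lengths.setdefault(split, []).append(ln)
        for leaf in t.leaves():
            leaf_lengths[leaf.name].append(leaf.length)

    majority = {s: c / n for s, c in counts.items() if c / n > 0.5}
    anchor = min(leafset)

    # laminar family (all splits exclude the anchor) -> nested construction
    clusters = sorted(majority, key=lambda s: (-len(s), sorted(s)))
    root = Node()
    leaf_nodes = {}
    for name in sorted(leafset):
        leaf_nodes[name] = Node(name, float(np.mean(leaf_lengths[name])))

    containers: list = []  # (cluster, node), from largest to smallest

    def attach(parent_node, child_node):
        parent_node.add(child_node)

    cluster_nodes = []
    for cl in clusters:
        node = Node("", float(np.mean(lengths[cl])))
        parent = root
        for other_cl, other_node in cluster_nodes:
            if cl < other_cl:
                parent = other_node  # smallest strict superset wins (sorted order)
        cluster_nodes.append((cl, node))
        attach(parent, node)
    # place leaves in the smallest containing cluster
    for name, lf in leaf_nodes.items():
        parent = root
        best_size = None
        if name != anchor:
            for cl, node in cluster_nodes:
                if name in cl and (best_size is None or len(cl) < best_size):
                    parent, best_size = node, len(cl)
        attach(parent, lf)
    return ConsensusTree(Tree(root), majority, "majority", n)


# --------------------------------------------------------------------------
# per-gene re-test
# --------------------------------------------------------------------------
@dataclass
class RetestResult:
    gene: str
    pvalue_global: float
    pvalue_gene_tree: float | None
    confirmed: bool
    reason: str = ""
    gene_tree: Tree | None = field(default=None, repr=False)


def per_gene_retest(
    gene: str,
    alignment: CodonAlignment,
    pvalue_global: float,
    foreground_taxa,
    alpha: float = 0.05,
    **fit_kwargs,
) -> RetestResult:
    """Re-test a candidate with a tree estimated from its own alignment.

    The gene tree is estimated from the gene's nucleotide alignment; the
    foreground is re-anchored as the edge above the MRCA of the foreground
    taxa present; the branch-site LRT is re-run. Confirmed means the
    gene-tree P-value also reaches ``alpha``.
    """
    try:
        gene_tree = estimate_tree(alignment)
    except Exception as exc:  # noqa: BLE001 - failure is a reportable outcome
        return RetestResult(gene, pvalue_global, None, False, f"tree estimation failed: {exc}")
    fg = [t for t in foreground_taxa if t in alignment.taxa]
    if not fg:
        return RetestResult(gene, pvalue_global, None, False, "no foreground taxa in alignment")
    try:
        gene_tree.set_foreground(fg)
    except ValueError as exc:
        return RetestResult(gene, pvalue_global, None, False, str(exc))
    lrt = branch_site_lrt(alignment, gene_tree, **fit_kwargs)
    return RetestResult(
        gene,
        pvalue_global,
        lrt.pvalue,
        confirmed=lrt.pvalue <= alpha,
        gene_tree=gene_tree,
    )
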