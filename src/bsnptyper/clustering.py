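"""Grouping SNP haplotypes into lettered families.

The pipeline treats haplotypes as taxa: pairwise uncorrected fractional
dissimilarity over the core SNPs (pairwise deletion of missing calls,
dual-allele BOTH as its own state), a neighbor-joining topology, branch
support from a majority-rule consensus of bootstrap replicates obtained
by resampling SNP columns, and cluster definition by median pairwise
patristic distance (MPPD): a candidate clade is a family when the median
path-length distance among all of its nodes (internal and terminal) falls
below a percentile — by default the 10th — of the patristic distances of
the whole topology.  A complementary constraint flags families whose
subtending branch has bootstrap reliability below 70%.  Families are
lettered A, B, C, ... in tree-traversal order; haplotypes falling in no
multi-member family become singleton families with letters of their own.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .panel import Allele, Haplotype

__all__ = [
    "DistanceMatrix",
    "ClusterAssignment",
    "fractional_dissimilarity",
    "distance_matrix",
    "neighbor_joining",
    "bipartitions",
    "bootstrap_support",
    "majority_rule_consensus",
    "patristic_matrix",
    "mppd_clusters",
    "jackknife_stability",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")


@dataclass
class ClusterAssignment:
    """haplotype label -> family letter, with per-family diagnostics."""

    assignment: dict[str, str]
    members: dict[str, list[str]] = field(default_factory=dict)
    mppd: dict[str, float] = field(default_factory=dict)
    support: dict[str, float] = field(default_factory=dict)
    meets_mppd: dict[str, bool] = field(default_factory=dict)
    meets_bootstrap: dict[str, bool] = field(default_factory=dict)
    threshold: float = float("nan")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _hap_array(haps: list[Haplotype]) -> np.ndarray:
    return np.array([[int(a) for a in h.alleles] for h in haps], dtype=np.int8)


def _pairwise_counts(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n_equal, n_comparable) per haplotype pair, missing-aware."""
    present = (X != int(Allele.MISSING)).astype(np.float64)
    comparable = present @ present.T
    equal = np.zeros_like(comparable)
    for state in (Allele.X, Allele.Y, Allele.BOTH):
        ind = (X == int(state)).astype(np.float64)
        equal += ind @ ind.T
    return equal, comparable


def fractional_dissimilarity(a: Haplotype, b: Haplotype) -> float:
    """Proportion of mutually non-missing core SNPs at which two
    haplotypes differ (uncorrected p-distance with pairwise deletion)."""
    if len(a) != len(b):
        raise ValueError(f"haplotype lengths differ: {len(a)} vs {len(b)}")
    comparable = diff = 0
    for x, y in zip(a.alleles, b.alleles):
        if x == Allele.MISSING or y == Allele.MISSING:
            continue
        comparable += 1
        if x != y:
            diff += 1
    if comparable == 0:
        raise ValueError("no comparable (mutually non-missing) positions")
    return diff / comparable


def distance_matrix(
    haps: list[Haplotype],
    labels: list[str] | None = None,
    min_comparable_frac: float = 0.5,
) -> DistanceMatrix:
    """All-pairs fractional dissimilarity.

    Pairs sharing fewer than ``min_comparable_frac`` of the core SNPs are
    refused rather than silently distanced on a sliver of data.
    """
    if labels is None:
        labels = [f"H{i + 1}" for i in range(len(haps))]
    X = _hap_array(haps)
    equal, comparable = _pairwise_counts(X)
    n, m = X.shape
    too_sparse = comparable < max(1.0, min_comparable_frac * m)
    np.fill_diagonal(too_sparse, False)
    if too_sparse.any():
        i, j = np.argwhere(too_sparse)[0]
        raise ValueError(
            f"haplotypes {labels[i]!r} and {labels[j]!r} share fewer than "
            f"{min_comparable_frac:.0%} comparable SNPs"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(comparable > 0, 1.0 - equal / comparable, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=tuple(labels), d=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou–Nei agglomeration with a deterministic tie-break.

    When several pairs minimize the Q-criterion (within 1e-12), the pair
    whose subtrees contain the lexicographically smallest label pair is
    joined.  Negative branch lengths are clamped to zero.  Returns an
    unrooted topology as a trifurcating-rooted scikit-bio tree (a single
    edge for two taxa).
    """
    n = len(D.labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 labels")
    nodes = [TreeNode(name=lbl) for lbl in D.labels]
    reps = [lbl for lbl in D.labels]  # smallest leaf label per subtree
    d = D.d.astype(float).copy()
    active = list(range(n))

    if n == 2:
        half = d[0, 1] / 2.0
        root = TreeNode()
        for i in (0, 1):
            nodes[i].length = half
            root.append(nodes[i])
        return root

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        rsum = sub.sum(axis=1)
        q = (k - 2) * sub - rsum[:, None] - rsum[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best, best_key = None, None
        for ai, aj in np.argwhere(q <= qmin + 1e-12):
            if ai >= aj:
                continue
            key = tuple(sorted((reps[active[ai]], reps[active[aj]])))
            if best_key is None or key < best_key:
                best, best_key = (int(ai), int(aj)), key
        ai, aj = best
        i, j = active[ai], active[aj]
        li = d[i, j] / 2.0 + (rsum[ai] - rsum[aj]) / (2.0 * (k - 2))
        lj = d[i, j] - li
        li, lj = max(0.0, li), max(0.0, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.append(nodes[i])
        parent.append(nodes[j])
        # new row for the joined node
        new = len(nodes)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for a in active:
            if a in (i, j):
                continue
            d[new, a] = d[a, new] = 0.5 * (d[a, i] + d[a, j] - d[i, j])
        active = [a for a in active if a not in (i, j)] + [new]

    # final three-point resolution
    i, j, k = active
    root = TreeNode()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(0.0, ln)
        root.append(nodes[idx])
    return root


def bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Non-trivial splits of an unrooted tree, keyed by the smaller tip
    set (ties by sorted names), mapped to the subtending child node."""
    tips = frozenset(t.name for t in tree.tips())
    out: dict[frozenset, TreeNode] = {}
    for node in tree.preorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out[key] = node
    return out


def _resample_distance(
    X: np.ndarray, labels: tuple[str, ...], cols: np.ndarray
) -> DistanceMatrix:
    Xb = X[:, cols]
    equal, comparable = _pairwise_counts(Xb)
    with np.errstate(invalid="ignore"):
        d = np.where(comparable > 0, 1.0 - equal / comparable, 0.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(labels=labels, d=d)


def bootstrap_support(
    haps: list[Haplotype],
    labels: list[str] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, TreeNode]:
    """NJ tree with bootstrap supports, plus the majority-rule consensus.

    Core-SNP columns are resampled with replacement ``n_reps`` times;
    distances and the NJ topology are recomputed per replicate, and each
    original-tree bipartition's support is the percentage of replicates
    containing it.  Supports are attached to internal nodes (``support``
    attribute and node name).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if labels is None:
        labels = [f"H{i + 1}" for i in range(len(haps))]
    D = distance_matrix(haps, labels)
    tree = neighbor_joining(D)
    orig = bipartitions(tree)
    X = _hap_array(haps)
    m = X.shape[1]
    rng = np.random.default_rng(seed)
    hits = {key: 0 for key in orig}
    split_counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, m, size=m)
        rep_tree = neighbor_joining(_resample_distance(X, D.labels, cols))
        rep_splits = bipartitions(rep_tree)
        for key in rep_splits:
            split_counts[key] = split_counts.get(key, 0) + 1
            if key in hits:
                hits[key] += 1
    for key, node in orig.items():
        support = 100.0 * hits[key] / n_reps
        node.support = support
        node.name = f"{support:.0f}"
    consensus = majority_rule_consensus(
        split_counts, [t.name for t in tree.tips()], n_reps
    )
    return tree, consensus


def majority_rule_consensus(
    split_counts: dict[frozenset, int],
    tip_names: list[str],
    n_reps: int,
) -> TreeNode:
    """Build the strict-majority (>50%) consensus tree from bootstrap
    split counts; majority splits are mutually compatible by pigeonhole."""
    majority = sorted(
        (
            (count, key)
            for key, count in split_counts.items()
            if count * 2 > n_reps
        ),
        key=lambda t: (-t[0], len(t[1]), tuple(sorted(t[1]))),
    )
    all_tips = frozenset(tip_names)
    root = TreeNode()
    clade_of: dict[frozenset, TreeNode] = {all_tips: root}
    leaves = {name: TreeNode(name=name) for name in sorted(tip_names)}
    clusters: list[frozenset] = [all_tips]
    for count, key in majority:
        cluster = key if len(key) * 2 <= len(all_tips) else all_tips - key
        if cluster in clade_of:
            continue
        node = TreeNode(name=f"{100.0 * count / n_reps:.0f}")
        node.support = 100.0 * count / n_reps
        clade_of[cluster] = node
        clusters.append(cluster)
    # attach each cluster/leaf to its smallest proper superset
    def parent_of(s: frozenset) -> TreeNode:
        best = all_tips
        for c in clusters:
            if s < c and len(c) < len(best):
                best = c
        return clade_of[best]

    for cluster in sorted(clusters, key=len):
        if cluster != all_tips:
            parent_of(cluster).append(clade_of[cluster])
    for name, leaf in leaves.items():
        parent_of(frozenset([name])).append(leaf)
    return root


# ---------------------------------------------------------------------------
# patristic distances & MPPD clustering
# ---------------------------------------------------------------------------

def _node_ids(tree: TreeNode) -> list[TreeNode]:
    return list(tree.postorder(include_self=True))


def patristic_matrix(tree: TreeNode) -> tuple[list[TreeNode], np.ndarray]:
    """Path-length distance between every pair of nodes, internal and
    terminal.  Returns (nodes, matrix) in postorder."""
    nodes = _node_ids(tree)
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    depth = np.zeros(n)
    order: list[TreeNode] = list(tree.preorder(include_self=True))
    for node in order:
        if node.parent is not None:
            if node.length is None:
                raise ValueError("tree has missing branch lengths")
            depth[index[id(node)]] = depth[index[id(node.parent)]] + node.length
    # ancestor chains for LCA
    anc: dict[int, list[int]] = {}
    for node in order:
        i = index[id(node)]
        if node.parent is None:
            anc[i] = [i]
        else:
            anc[i] = anc[index[id(node.parent)]] + [i]
    dist = np.zeros((n, n))
    for i in range(n):
        ai = anc[i]
        si = set(ai)
        for j in range(i + 1, n):
            lca = next(a for a in reversed(anc[j]) if a in si)
            dij = depth[i] + depth[j] - 2 * depth[lca]
            dist[i, j] = dist[j, i] = dij
    return nodes, dist


def _clade_mppd(
    node: TreeNode, index: dict[int, int], dist: np.ndarray
) -> float:
    ids = [index[id(x)] for x in node.postorder(include_self=True)]
    if len(ids) < 2:
        return 0.0
    sub = dist[np.ix_(ids, ids)]
    iu = np.triu_indices(len(ids), k=1)
    return float(np.median(sub[iu]))


def mppd_clusters(
    tree: TreeNode,
    percentile: float = 10.0,
    bootstrap_min: float = 70.0,
) -> ClusterAssignment:
    """Family assignment by median pairwise patristic distance.

    The tree is midpoint-rooted for clade enumeration.  The similarity
    threshold is the given percentile of the patristic distances among
    ALL node pairs of the topology; candidate families are maximal clades
    whose within-clade MPPD is at or below the threshold, found by
    preorder descent (a qualifying clade is not subdivided).  Leaves in
    no qualifying clade become singleton families.  Bootstrap reliability
    of the clade's subtending branch is recorded as a flag
    (``meets_bootstrap``); it does not alter membership.
    """
    if not (0.0 < percentile <= 100.0):
        raise ValueError("percentile must be in (0, 100]")
    rooted = tree.copy()
    if len(rooted.children) > 2 and rooted.count(tips=True) > 2:
        rooted = rooted.root_at_midpoint()
    nodes, dist = patristic_matrix(rooted)
    index = {id(n): i for i, n in enumerate(nodes)}
    iu = np.triu_indices(len(nodes), k=1)
    threshold = float(np.percentile(dist[iu], percentile))

    if bootstrap_min > 0 and not any(
        getattr(n, "support", None) is not None for n in rooted.non_tips()
    ) and rooted.count(tips=True) > 2:
        raise ValueError(
            "tree carries no bootstrap supports; run bootstrap_support "
            "first or set bootstrap_min=0"
        )

    out = ClusterAssignment(assignment={}, threshold=threshold)
    letter_i = 0

    def next_letter() -> str:
        nonlocal letter_i
        q, r = divmod(letter_i, 26)
        letter_i += 1
        return chr(ord("A") + r) * (q + 1)

    def emit(node: TreeNode, is_clade: bool) -> None:
        letter = next_letter()
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        for t in tips:
            out.assignment[t] = letter
        out.members[letter] = tips
        out.mppd[letter] = _clade_mppd(node, index, dist) if is_clade else 0.0
        sup = getattr(node, "support", None)
        out.support[letter] = float(sup) if sup is not None else 100.0
        out.meets_mppd[letter] = True
        out.meets_bootstrap[letter] = out.support[letter] >= bootstrap_min

    def descend(node: TreeNode) -> None:
        if node.is_tip():
            emit(node, is_clade=False)
            return
        if _clade_mppd(node, index, dist) <= threshold:
            emit(node, is_clade=True)
            return
        for child in node.children:
            descend(child)

    descend(rooted)
    return out


def jackknife_stability(
    haps: list[Haplotype],
    labels: list[str] | None = None,
    drop_fraction: float = 0.2,
    n_reps: int = 100,
    seed: int = 0,
    percentile: float = 10.0,
) -> dict[str, float]:
    """Per-family persistence under leaf jackknifing.

    Clustering is repeated on random leaf subsets (each replicate drops
    ``drop_fraction`` of the haplotypes); for every original multi-member
    family the returned value is the fraction of evaluable replicates
    (>= 2 members retained) in which its retained members still share one
    family."""
    if not (0.0 < drop_fraction < 1.0):
        raise ValueError("drop_fraction must be in (0, 1)")
    if labels is None:
        labels = [f"H{i + 1}" for i in range(len(haps))]
    base = mppd_clusters(
        neighbor_joining(distance_matrix(haps, labels)),
        percentile=percentile, bootstrap_min=0.0,
    )
    multi = {k: v for k, v in base.members.items() if len(v) >= 2}
    rng = np.random.default_rng(seed)
    n = len(haps)
    n_drop = max(1, int(round(drop_fraction * n)))
    persisted = {k: 0 for k in multi}
    evaluable = {k: 0 for k in multi}
    for _ in range(n_reps):
        keep = sorted(rng.choice(n, size=n - n_drop, replace=False))
        if len(keep) < 3:
            continue
        sub_labels = [labels[i] for i in keep]
        rep = mppd_clusters(
            neighbor_joining(
                distance_matrix([haps[i] for i in keep], sub_labels)
            ),
            percentile=percentile, bootstrap_min=0.0,
        )
        for fam, members in multi.items():
            retained = [x for x in members if x in rep.assignment]
            if len(retained) < 2:
                continue
            evaluable[fam] += 1
            if len({rep.assignment[x] for x in retained}) == 1:
                persisted[fam] += 1
    return {
        fam: (persisted[fam] / evaluable[fam]) if evaluable[fam] else float("nan")
        for fam in multi
    }


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
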