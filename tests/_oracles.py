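"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: phasing by
exhaustive enumeration of consistent pair assignments, tree distances by
construction, topology comparison by bipartition sets.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from bsnptyper.panel import (
    GenotypeCall,
    GenotypeMatrix,
    SNPDef,
    SNPPanel,
)


def make_panel(n_snps: int, spacing: int = 1000, start: int = 1000) -> SNPPanel:
    snps = tuple(
        SNPDef(name=f"S{i:02d}", position_bp=start + spacing * i,
               allele_x="A", allele_y="G")
        for i in range(n_snps)
    )
    return SNPPanel(snps=snps, reference_length=start + spacing * (n_snps + 1))


def gvec_to_calls(g: str) -> list[GenotypeCall]:
    return [
        {"0": GenotypeCall.XX, "1": GenotypeCall.YY, "H": GenotypeCall.XY}[x]
        for x in g
    ]


def line_matrix(gvecs: list[str]) -> GenotypeMatrix:
    n_snps = len(gvecs[0])
    panel = make_panel(n_snps)
    calls = np.empty((len(gvecs), n_snps), dtype=object)
    for i, g in enumerate(gvecs):
        calls[i, :] = gvec_to_calls(g)
    return GenotypeMatrix(
        panel=panel,
        bird_ids=[f"B{i}" for i in range(len(gvecs))],
        line_ids=["L"] * len(gvecs),
        calls=calls,
    )


# ---------------------------------------------------------------------------
# phasing oracle
# ---------------------------------------------------------------------------

def consistent_pairs(gvec: str) -> list[tuple[tuple, tuple]]:
    """All unordered haplotype pairs consistent with one genotype vector
    ('0'/'1' homozygous, 'H' heterozygous)."""
    het = [i for i, g in enumerate(gvec) if g == "H"]
    base = [None if g == "H" else int(g) for g in gvec]
    if not het:
        v = tuple(base)
        return [(v, v)]
    pairs = []
    for bits in product((0, 1), repeat=len(het) - 1):
        bits = (0,) + bits  # fix the first het site to break pair symmetry
        a, b = list(base), list(base)
        for i, pos in enumerate(het):
            a[pos] = bits[i]
            b[pos] = 1 - bits[i]
        pairs.append((tuple(a), tuple(b)))
    return pairs


def parsimony_resolved(gvecs: list[str]) -> set[tuple]:
    """Haplotypes present in EVERY minimum-cardinality consistent phasing
    of a line (exhaustive search with iterative deepening on the number
    of distinct haplotypes)."""
    per_bird = [consistent_pairs(g) for g in gvecs]
    lower = max(1 if "H" not in g else 2 for g in gvecs)
    for bound in range(lower, 2 * len(gvecs) + 2):
        states: set[frozenset] = {frozenset()}
        for pairs in per_bird:
            new: set[frozenset] = set()
            for st in states:
                for a, b in pairs:
                    u = st | {a, b}
                    if len(u) <= bound:
                        new.add(u)
            states = new
            if not states:
                break
        if states:
            finals = [s for s in states if len(s) == bound] or list(states)
            inter = set(finals[0])
            for s in finals[1:]:
                inter &= s
            return inter
    return set()


def _founder_compatible(founder: tuple, gvec: str) -> bool:
    return all(g == "H" or str(f) == g for f, g in zip(founder, gvec))


def random_identifiable_line(rng: np.random.Generator) -> list[str]:
    """A random tiny segregating line of the kind the subtraction
    procedure is designed for: every founder haplotype is anchored by a
    homozygous bird, except at most one that is reachable by unique
    subtraction (a heterozygote in which exactly one anchored founder
    fits the genotype)."""
    n_snps = int(rng.integers(3, 9))
    n_founders = int(rng.integers(2, 5))
    founders: set[tuple] = set()
    while len(founders) < n_founders:
        founders.add(tuple(int(x) for x in rng.integers(0, 2, n_snps)))
    flist = sorted(founders)
    unobserved = int(rng.integers(0, n_founders)) if rng.random() < 0.6 else -1
    gvecs: list[str] = []
    if unobserved >= 0:
        u = flist[unobserved]
        observed = [f for i, f in enumerate(flist) if i != unobserved]
        anchor = None
        for ki in rng.permutation(len(observed)):
            k = observed[int(ki)]
            g = "".join(
                "H" if a != b else str(a) for a, b in zip(k, u)
            )
            if sum(_founder_compatible(f, g) for f in observed) == 1:
                anchor = g
                break
        if anchor is None:
            unobserved = -1
        else:
            gvecs.append(anchor)
    for i, f in enumerate(flist):
        if i != unobserved:
            gvecs.append("".join(map(str, f)))
    for _ in range(int(rng.integers(0, 3))):
        i, j = rng.integers(0, n_founders, 2)
        gvecs.append(
            "".join(
                "H" if a != b else str(a)
                for a, b in zip(flist[int(i)], flist[int(j)])
            )
        )
    return gvecs


# ---------------------------------------------------------------------------
# tree oracles
# ---------------------------------------------------------------------------

def random_additive_tree(
    rng: np.random.Generator, n_taxa: int
) -> tuple[list[str], np.ndarray, set[frozenset]]:
    """A random unrooted binary tree with positive branch lengths; returns
    (labels, additive distance matrix, non-trivial bipartitions), all
    computed by direct construction (no NJ involved)."""
    labels = [f"T{i:02d}" for i in range(n_taxa)]
    # start from a 3-star; attach remaining taxa to random edges
    # nodes: 0..n_taxa-1 leaves; internal nodes numbered from n_taxa
    edges: dict[tuple[int, int], float] = {}
    nxt = n_taxa

    def add_edge(a, b, w):
        edges[(min(a, b), max(a, b))] = w

    def del_edge(a, b):
        return edges.pop((min(a, b), max(a, b)))

    def rand_len() -> float:
        return float(rng.uniform(0.05, 1.0))

    if n_taxa == 2:
        add_edge(0, 1, rand_len())
    else:
        center = nxt
        nxt += 1
        for leaf in range(3):
            add_edge(leaf, center, rand_len())
        for leaf in range(3, n_taxa):
            a, b = list(edges)[int(rng.integers(0, len(edges)))]
            w = del_edge(a, b)
            mid = nxt
            nxt += 1
            split = float(rng.uniform(0.25, 0.75))
            add_edge(a, mid, w * split)
            add_edge(mid, b, w * (1 - split))
            add_edge(leaf, mid, rand_len())

    adj: dict[int, list[tuple[int, float]]] = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    def leaves_beyond(start: int, avoid: int) -> set[int]:
        out, stack, seen = set(), [start], {avoid, start}
        while stack:
            node = stack.pop()
            if node < n_taxa:
                out.add(node)
            for nb, _ in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return out

    # distances by BFS accumulation from each leaf
    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    stack.append(nb)
        for dst in range(n_taxa):
            D[src, dst] = dist[dst]

    splits: set[frozenset] = set()
    allset = frozenset(labels)
    for (a, b) in edges:
        side = frozenset(labels[x] for x in leaves_beyond(a, b))
        if 2 <= len(side) <= n_taxa - 2:
            key = min(
                side, allset - side,
                key=lambda s: (len(s), tuple(sorted(s))),
            )
            splits.add(key)
    return labels, D, splits


def tree_splits(tree) -> set[frozenset]:
    """Non-trivial bipartitions of a scikit-bio tree, canonical side."""
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.preorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out
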