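"""Independent brute-force implementations used as test oracles.

These deliberately avoid the package's vectorized code paths: windowed
diversity statistics are computed by enumerating every haplotype pair at
every site, monophyly by enumerating tree edges on an independently parsed
Newick string, and additive distance matrices are built from random trees
by summing path lengths.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# windowed pi / Tajima's D by pair enumeration
# ---------------------------------------------------------------------------

def expand_haplotypes(genotypes: np.ndarray) -> np.ndarray:
    """Diploid alt-allele counts (N x P) -> haplotype alleles (2N x P).

    Hets expand to (0, 1); the split is irrelevant for site-count statistics.
    """
    n, p = genotypes.shape
    haps = np.zeros((2 * n, p), dtype=np.int64)
    haps[0::2] = (genotypes >= 1).astype(np.int64)
    haps[1::2] = (genotypes == 2).astype(np.int64)
    return haps


def brute_window_stats(positions, genotypes, segment_length, window_bp, step_bp):
    """Per-window (start, end, S, k_hat, pi, D) with every pair enumerated."""
    genotypes = np.asarray(genotypes)
    keep = [j for j in range(genotypes.shape[1])
            if not np.any(genotypes[:, j] < 0)]
    positions = np.asarray(positions)[keep]
    haps = expand_haplotypes(genotypes[:, keep])
    n = haps.shape[0]

    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)

    out = []
    start = 1
    while start <= segment_length:
        end = min(start + window_bp - 1, segment_length)
        span = end - start + 1
        in_win = [j for j, p in enumerate(positions) if start <= p <= end]
        total_diff = 0
        S = 0
        for j in in_win:
            col = haps[:, j]
            if 0 < col.sum() < n:
                S += 1
            for a in range(n):
                for b in range(a + 1, n):
                    total_diff += int(col[a] != col[b])
        n_pairs = n * (n - 1) // 2
        k_hat = total_diff / n_pairs
        if S == 0:
            d = None
        else:
            var = e1 * S + e2 * S * (S - 1)
            d = None if var <= 0 else (k_hat - S / a1) / math.sqrt(var)
        out.append((start, end, S, k_hat, k_hat / span, d))
        start += step_bp
    return out


def brute_site_diversity(j: int, n: int) -> float:
    """Mean pairwise difference at one site by explicit pair enumeration."""
    alleles = [1] * j + [0] * (n - j)
    diffs = sum(
        int(alleles[a] != alleles[b])
        for a in range(n) for b in range(a + 1, n)
    )
    return diffs / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# monophyly by edge enumeration on an independently parsed tree
# ---------------------------------------------------------------------------

def brute_is_monophyletic(newick: str, leafset) -> bool:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    leafset = frozenset(leafset)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        below = frozenset(
            l.taxon.label for l in edge.head_node.leaf_iter()
        )
        if below == leafset or (all_leaves - below) == leafset:
            return True
    return len(leafset) == 1


# ---------------------------------------------------------------------------
# random additive matrices from random trees
# ---------------------------------------------------------------------------

def random_additive_matrix(rng: np.random.Generator, n_leaves: int):
    """(labels, matrix, truth_tree) for a random binary tree with positive
    branch lengths; the matrix holds leaf-to-leaf path lengths."""
    from chimpop.tree import TreeNode

    nodes = [TreeNode(name=f"t{i:02d}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode()
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        parent.add_child(a)
        parent.add_child(b)
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for child in nodes:
        child.length = float(rng.uniform(0.1, 1.0))
        root.add_child(child)

    labels = sorted(root.leaf_names())
    paths = root.path_lengths()
    k = len(labels)
    d = np.zeros((k, k))
    for x in range(k):
        for y in range(x + 1, k):
            d[x, y] = d[y, x] = paths[(labels[x], labels[y])]
    return labels, d, root
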