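"""Distance-based gene-tree construction and origin analyses.

Tree inference here is a deterministic desk-scale surrogate: p-distances
with pairwise deletion, Saitou-Nei neighbor joining with lexicographic tie
breaking and negative branch lengths clamped to zero, a bipartition-based
monophyly test, and a column-bootstrap of the monophyly statistic.  The
rate-feasibility calculation converts an observed pairwise divergence and a
time window into the fold increase over a baseline divergence rate
(interpreted as pairwise divergence accumulated per million years).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .errors import NoInformationError, ParameterError
from .io_formats import AlleleSequence
from .tree import GeneTree, TreeNode

logger = logging.getLogger(__name__)

_UNAMBIG = frozenset(b"ACGT")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.labels)
        if self.d.shape != (k, k):
            raise ParameterError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ParameterError("distance matrix has non-finite entries")
        if np.any(self.d < 0) or np.any(np.diag(self.d) != 0):
            raise ParameterError("distances must be nonnegative with zero diagonal")
        if not np.allclose(self.d, self.d.T):
            raise ParameterError("distance matrix must be symmetric")


@dataclass
class RateFeasibilityResult:
    d_obs: float
    T_years: float
    baseline_lo_pct_per_myr: float
    baseline_hi_pct_per_myr: float
    required_rate: float  # substitutions/site/year
    fold_lo: float  # vs the high baseline (smaller fold)
    fold_hi: float  # vs the low baseline (larger fold)


@dataclass
class BootstrapResult:
    support: float
    n_retained: int
    n_discarded: int


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def p_distance(
    sequences: Sequence[Union[AlleleSequence, tuple[str, str]]],
) -> DistanceMatrix:
    """Pairwise proportion of differing unambiguous columns (pairwise deletion).

    Columns where either sequence is gapped or ambiguous are excluded per
    pair; a pair with no comparable columns is an error.
    """
    labels, mats = [], []
    for s in sequences:
        if isinstance(s, AlleleSequence):
            labels.append(s.id)
            seq = s.sequence
        else:
            labels.append(s[0])
            seq = s[1]
        mats.append(np.frombuffer(seq.encode("ascii"), dtype=np.uint8))
    if len(labels) < 2:
        raise ParameterError("p_distance needs at least two sequences")
    lengths = {m.size for m in mats}
    if len(lengths) != 1:
        raise ParameterError("sequences must be aligned to equal length")
    arr = np.stack(mats)
    ok = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    k = len(labels)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = ok[i] & ok[j]
            denom = int(both.sum())
            if denom == 0:
                raise NoInformationError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            diff = int(np.sum((arr[i] != arr[j]) & both))
            d[i, j] = d[j, i] = diff / denom
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> GeneTree:
    """Saitou-Nei neighbor joining.

    Q-criterion ties are broken by the lexicographically smallest pair of
    cluster labels (a cluster's label is the smallest leaf label it
    contains), and negative branch lengths are clamped to zero, so the
    output is deterministic.  Returns a tree rooted at a trifurcating
    internal node (unrooted semantics).
    """
    k = len(dm.labels)
    if k < 3:
        raise ParameterError("nj_tree requires at least 3 taxa")
    if len(set(dm.labels)) != k:
        raise ParameterError("leaf labels must be unique")

    nodes: dict[int, TreeNode] = {i: TreeNode(name=lab) for i, lab in enumerate(dm.labels)}
    tags: dict[int, str] = {i: lab for i, lab in enumerate(dm.labels)}  # tie-break keys
    d: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            d[(i, j)] = dm.d[i, j]

    def dist(a: int, b: int) -> float:
        return d[(a, b) if a < b else (b, a)]

    active = list(range(k))
    next_id = k
    while len(active) > 2:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = tuple(sorted((tags[a], tags[b])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, a, b)
        _, _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = TreeNode()
        child_a, child_b = nodes[a], nodes[b]
        child_a.length, child_b.length = la, lb
        parent.add_child(child_a)
        parent.add_child(child_b)
        u = next_id
        next_id += 1
        nodes[u] = parent
        tags[u] = min(tags[a], tags[b])
        for c in active:
            if c in (a, b):
                continue
            d[(min(c, u), max(c, u))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [u]

    a, b = active
    # attach the leftover node under the internal one (unrooted join)
    if nodes[a].is_leaf and not nodes[b].is_leaf:
        a, b = b, a
    root, other = nodes[a], nodes[b]
    other.length = max(dist(a, b), 0.0)
    root.add_child(other)
    return root


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------

def is_monophyletic(tree: GeneTree, leafset: Union[set, frozenset]) -> bool:
    """True iff removing one edge splits the leaves into (leafset, rest).

    The tree is unrooted: a clade may appear as a rooted subtree's leaf set
    or as its complement.  Singleton leafsets are trivially monophyletic.
    """
    leafset = frozenset(leafset)
    all_leaves = tree.leaf_name_set()
    if not leafset:
        raise ParameterError("leafset must be nonempty")
    if not leafset < all_leaves:
        raise ParameterError("leafset must be a proper subset of the tree's leaves")
    if len(leafset) == 1:
        return True
    complement = all_leaves - leafset

    found = False

    def walk(node: TreeNode) -> frozenset:
        nonlocal found
        if node.is_leaf:
            below = frozenset((node.name,))
        else:
            below = frozenset().union(*(walk(c) for c in node.children))
        if below == leafset or below == complement:
            found = True
        return below

    walk(tree)
    return found


def monophyly_bootstrap(
    alignment: Sequence[AlleleSequence],
    leafset: Union[set, frozenset],
    replicates: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Column bootstrap of the monophyly statistic.

    Each replicate resamples alignment columns with replacement (one index
    draw shared by all sequences), recomputes p-distance and the NJ tree,
    and tests monophyly of ``leafset``; support is the fraction of retained
    replicates that are monophyletic.  Replicates where some pair has no
    comparable columns are discarded and logged.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    labels = [s.id for s in alignment]
    seqs = [s.sequence for s in alignment]
    n_cols = len(seqs[0])
    if any(len(s) != n_cols for s in seqs):
        raise ParameterError("alignment sequences must share a length")
    arr = np.array([list(s) for s in seqs])
    rng = np.random.default_rng(seed)
    hits = retained = discarded = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        boot = ["".join(row) for row in arr[:, cols]]
        try:
            dm = p_distance(list(zip(labels, boot)))
        except NoInformationError:
            discarded += 1
            continue
        retained += 1
        if is_monophyletic(nj_tree(dm), leafset):
            hits += 1
    if retained == 0:
        raise NoInformationError("all bootstrap replicates were discarded")
    if discarded:
        logger.info("monophyly_bootstrap: discarded %d of %d replicates",
                    discarded, replicates)
    return BootstrapResult(
        support=hits / retained, n_retained=retained, n_discarded=discarded
    )


# ---------------------------------------------------------------------------
# divergence-rate feasibility
# ---------------------------------------------------------------------------

def rate_feasibility(
    d_obs: float,
    T_years: float,
    baseline_lo_pct_per_myr: float = 1.5,
    baseline_hi_pct_per_myr: Optional[float] = 2.5,
) -> RateFeasibilityResult:
    """Fold increase over a baseline divergence rate needed to accumulate
    ``d_obs`` substitutions/site within ``T_years``.

    The baseline (percent divergence per million years) is treated as a
    pairwise-divergence accumulation rate and converted to
    substitutions/site/year.  With a single baseline (``hi=None`` or equal
    bounds) both folds coincide.
    """
    if d_obs < 0:
        raise ParameterError("d_obs must be >= 0")
    if T_years <= 0:
        raise ParameterError("T_years must be > 0")
    lo = baseline_lo_pct_per_myr
    hi = baseline_hi_pct_per_myr if baseline_hi_pct_per_myr is not None else lo
    if lo <= 0 or hi < lo:
        raise ParameterError("baselines must satisfy 0 < lo <= hi")
    required = d_obs / T_years
    # fold = (d_obs/T) / (pct/100/1e6), evaluated in one expression to keep
    # the closed-form cases exact in floating point
    return RateFeasibilityResult(
        d_obs=d_obs,
        T_years=T_years,
        baseline_lo_pct_per_myr=lo,
        baseline_hi_pct_per_myr=hi,
        required_rate=required,
        fold_lo=d_obs * 1e8 / (T_years * hi),
        fold_hi=d_obs * 1e8 / (T_years * lo),
    )
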