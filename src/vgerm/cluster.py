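"""Cluster discovery: percent-difference windows, UPGMA linkage, consensus.

Two complementary routes propose candidate germline sequences among the reads
assigned to one database allele:

* **Windowed clustering** bins reads by their percent difference to the
  assigned allele in half-open 2% windows ``[0,2), [2,4), ...`` and builds one
  consensus per populated window.  A novel allele expressed alongside the
  database allele shows up as a second mode in the histogram and hence as its
  own window.
* **Linkage cluster analysis** takes a random subsample (default 1,000
  sequences), computes all pairwise Levenshtein distances, clusters them with
  UPGMA (average linkage) and reports subtrees that are internally tight but
  well separated from their sibling — resolving novel alleles whose
  percent-difference modes overlap.

Consensus calling emits the base reaching a 60% majority per column of a
multiple alignment of the cluster members (votes weighted by duplicate
counts), N otherwise; gap-majority columns are deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
from scipy.cluster import hierarchy

from .assign import VJAssignment


@dataclass
class WindowCluster:
    """Reads of one allele falling in one percent-difference window."""

    source_allele: str
    interval: tuple[float, float]
    members: list[str]
    counts: list[int]

    @property
    def n_unique(self) -> int:
        return len(self.members)


def windowed_clusters(
    assignments_for_allele: Sequence[VJAssignment],
    width_percent: float = 2.0,
    min_members: int = 5,
) -> list[WindowCluster]:
    """Bin assignments into half-open percent-difference windows.

    Bins are ``[0, w), [w, 2w), ...``; only bins with at least
    ``min_members`` distinct V-region sequences are reported.  All
    assignments must share the same ``v_name``.
    """
    if not assignments_for_allele:
        return []
    names = {a.v_name for a in assignments_for_allele}
    if len(names) != 1:
        raise ValueError("assignments must all share the same v_name")
    source = names.pop()
    bins: dict[int, dict[str, int]] = {}
    for a in assignments_for_allele:
        k = int(a.v_percent_difference // width_percent)
        bins.setdefault(k, {})
        bins[k][a.v_sequence] = bins[k].get(a.v_sequence, 0) + a.count
    out = []
    for k in sorted(bins):
        uniq = bins[k]
        if len(uniq) < min_members:
            continue
        members = list(uniq)
        out.append(WindowCluster(
            source_allele=source,
            interval=(k * width_percent, (k + 1) * width_percent),
            members=members,
            counts=[uniq[m] for m in members],
        ))
    return out


def percent_difference_histogram(
    assignments, width_percent: float = 2.0
):
    """Binned percent-difference counts per assigned allele.

    Returns a DataFrame with columns ``v_name, bin_lo, bin_hi, reads`` — the
    data behind the windowed-clustering histograms.
    """
    import pandas as pd

    counts: dict[tuple[str, int], int] = {}
    for a in assignments:
        if a.v_name is None:
            continue
        k = int(a.v_percent_difference // width_percent)
        counts[(a.v_name, k)] = counts.get((a.v_name, k), 0) + a.count
    rows = [
        {"v_name": name, "bin_lo": k * width_percent,
         "bin_hi": (k + 1) * width_percent, "reads": c}
        for (name, k), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["v_name", "bin_lo", "bin_hi", "reads"])


def subsample(
    assignments: Sequence[VJAssignment], n: int = 1000, seed: int = 0
) -> list[VJAssignment]:
    """Uniform random subset without replacement of size ``min(n, len(input))``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(assignments) <= n:
        return list(assignments)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(assignments), size=n, replace=False)
    idx.sort()
    return [assignments[i] for i in idx]


def levenshtein(a: str, b: str) -> int:
    """Edit distance (substitutions, insertions and deletions each count 1)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def distance_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Symmetric Levenshtein distance matrix."""
    n = len(sequences)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = levenshtein(sequences[i], sequences[j])
    return d


@dataclass
class DendrogramNode:
    """Binary UPGMA tree node; leaves carry an index, inner nodes a height."""

    id: int
    height: float = 0.0
    left: Optional["DendrogramNode"] = None
    right: Optional["DendrogramNode"] = None
    leaves: list[int] = field(default_factory=list)
    # smallest / largest merge height among the node's internal merges;
    # a leaf has no internal merge and contributes 0 for both
    min_internal: float = 0.0
    max_internal: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def size(self) -> int:
        return len(self.leaves)


def upgma(distances: np.ndarray) -> DendrogramNode:
    """Average-linkage (UPGMA) hierarchical clustering of a distance matrix.

    Merge heights equal the arithmetic mean of all inter-cluster pairwise
    distances and are non-decreasing from leaves to root.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n == 1:
        return DendrogramNode(id=0, leaves=[0])
    iu = np.triu_indices(n, k=1)
    condensed = d[iu]
    Z = hierarchy.linkage(condensed, method="average")
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(id=i, leaves=[i]) for i in range(n)
    }
    for k, (ia, ib, h, _) in enumerate(Z):
        a, b = nodes[int(ia)], nodes[int(ib)]
        mins = [float(h)] + [c.min_internal for c in (a, b) if not c.is_leaf]
        nodes[n + k] = DendrogramNode(
            id=n + k, height=float(h), left=a, right=b,
            leaves=a.leaves + b.leaves,
            min_internal=min(mins),
            max_internal=float(h),
        )
    return nodes[n + len(Z) - 1]


@dataclass
class LinkageCluster:
    """A detected subcluster of the UPGMA tree."""

    source_allele: str
    member_indices: list[int]
    merge_height: float


def detect_subclusters(
    tree: DendrogramNode,
    min_size: int = 5,
    ratio_threshold: float = 0.8,
    source_allele: str = "",
) -> list[LinkageCluster]:
    """Find tight, well-separated subtrees of a UPGMA dendrogram.

    For every inner node whose two child subtrees both have at least
    ``min_size`` leaves, child A qualifies as a subcluster when the ratio of
    A's smallest internal merge height to B's largest internal merge height
    is below ``ratio_threshold`` (and symmetrically for B) — A is then
    internally tighter than its neighbourhood.  Leaves contribute height 0.
    All inner nodes are scanned; of nested qualifying subtrees only the
    innermost is reported, which keeps the reported clusters pure (one tight
    bundle rather than a union of bundles) and their leaf sets disjoint.
    """

    def ratio(a: DendrogramNode, b: DendrogramNode) -> float:
        if b.max_internal == 0.0:
            return 0.0 if a.min_internal == 0.0 else float("inf")
        return a.min_internal / b.max_internal

    qualifying: list[DendrogramNode] = []

    def scan(node: DendrogramNode) -> None:
        if node.is_leaf:
            return
        a, b = node.left, node.right
        if a.size >= min_size and b.size >= min_size:
            if ratio(a, b) < ratio_threshold:
                qualifying.append(a)
            if ratio(b, a) < ratio_threshold:
                qualifying.append(b)
        scan(a)
        scan(b)

    scan(tree)
    # keep only minimal (innermost) qualifying subtrees
    leaf_sets = [frozenset(q.leaves) for q in qualifying]
    out: list[LinkageCluster] = []
    for q, ls in zip(qualifying, leaf_sets):
        if any(other < ls for other in leaf_sets):
            continue
        out.append(LinkageCluster(
            source_allele=source_allele,
            member_indices=sorted(q.leaves),
            merge_height=q.height,
        ))
    return out


def _parse_cigar(cigar: str):
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + int(ch)
        else:
            yield num, ch
            num = 0


MAX_CONSENSUS_MEMBERS = 400


def consensus(
    members: Sequence[str],
    counts: Optional[Sequence[int]] = None,
    majority: float = 0.6,
) -> str:
    """Majority-vote consensus of near-identical sequences.

    Members are multiple-aligned by a star alignment around the
    highest-count member; per column, a base is emitted when it reaches at
    least ``majority`` of the non-gap weighted votes (threshold inclusive),
    columns where gaps hold the overall majority are deleted, and N is
    emitted otherwise.  Duplicate counts weight the votes.  For efficiency
    only the ``MAX_CONSENSUS_MEMBERS`` highest-count members vote.
    """
    if not members:
        raise ValueError("need at least one member")
    if counts is None:
        counts = [1] * len(members)
    pairs = sorted(zip(members, counts), key=lambda mc: (-mc[1], -len(mc[0]), mc[0]))
    pairs = pairs[:MAX_CONSENSUS_MEMBERS]
    center = pairs[0][0]
    L = len(center)
    # columns: (pos, 0) = center position; (pos, k>0) = k-th insertion after it
    votes: dict[tuple[int, int], dict[str, float]] = {}

    def vote(col: tuple[int, int], base: str, w: float) -> None:
        votes.setdefault(col, {})
        votes[col][base] = votes[col].get(base, 0.0) + w

    total = 0.0
    for seq, w in pairs:
        total += w
        if seq == center:
            for p in range(L):
                vote((p, 0), seq[p], w)
            continue
        res = edlib.align(seq, center, mode="NW", task="path")
        qi = ci = 0
        covered = [False] * L
        for ln, op in _parse_cigar(res["cigar"]):
            if op in ("=", "X"):
                for _ in range(ln):
                    vote((ci, 0), seq[qi], w)
                    covered[ci] = True
                    qi += 1
                    ci += 1
            elif op == "I":  # insertion relative to the center
                for k in range(ln):
                    vote((ci - 1, k + 1) if ci > 0 else (-1, k + 1), seq[qi], w)
                    qi += 1
            elif op == "D":  # gap in this member
                for _ in range(ln):
                    covered[ci] = True
                    vote((ci, 0), "-", w)
                    ci += 1
    cols = sorted(votes)
    out = []
    for col in cols:
        v = dict(votes[col])
        gap_w = v.pop("-", 0.0) + (total - sum(votes[col].values()))
        # members that do not touch an insertion column implicitly vote gap
        if gap_w > total / 2:
            continue
        nongap = sum(v.values())
        if nongap <= 0:
            continue
        base, w = max(v.items(), key=lambda kv: (kv[1], kv[0]))
        out.append(base if w >= majority * nongap else "N")
    return "".join(out)


__all__ = [
    "WindowCluster", "LinkageCluster", "DendrogramNode",
    "windowed_clusters", "subsample", "levenshtein", "distance_matrix",
    "upgma", "detect_subclusters", "consensus",
]
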