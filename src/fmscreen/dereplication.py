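"""Group active clones into effector regions by pairwise insert overlap.

Two cosmid inserts drawn from the same genomic locus share a long stretch
of identical sequence. The overlap length between a pair is estimated by
chaining shared unique 31-mers: k-mers occurring exactly once in each
insert are matched (in both orientations of the second insert), the longest
chain of matches that is strictly colinear — increasing in both sequences —
is found, and the overlap is the insert span of that chain plus k-1. For
error-free sequence this equals the exact shared-substring length. The
uniqueness filter keeps repeats within an insert from seeding spurious
chains.

Clones whose pairwise overlap exceeds a threshold (strictly more than
5 kbp by default) are joined by an edge; effector regions are the connected
components of that graph, so chains of pairwise overlaps merge even when
the end clones do not directly overlap. Isolated clones become singleton
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .seqs import canonical_kmer_set, revcomp, unique_kmer_positions
from .synthetic import CloneInsert

DEFAULT_K = 31
MIN_OVERLAP_BP = 5_000


@dataclass
class OverlapEdge:
    clone_a: str
    clone_b: str
    overlap_bp: int
    strand: str  # "same" | "opposite"


@dataclass
class EffectorRegion:
    region_id: str
    members: frozenset[str]

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def _longest_colinear_span(pa: np.ndarray, pb: np.ndarray, k: int) -> int:
    """Span (in sequence a) of the longest chain of (pa, pb) matches that is
    strictly increasing in both coordinates, plus k-1; 0 when no matches.

    Patience-style longest-increasing-subsequence on pb after sorting by pa;
    unique-k-mer matches make coordinate pairs distinct, so ties cannot
    occur within a diagonal.
    """
    if pa.size == 0:
        return 0
    order = np.argsort(pa, kind="stable")
    pa, pb = pa[order], pb[order]
    # tails[i] = smallest pb ending an increasing chain of length i+1
    tails: list[int] = []
    tail_idx: list[int] = []  # index into pa/pb of that chain end
    parent = np.full(pa.size, -1)
    for i in range(pa.size):
        lo, hi = 0, len(tails)
        while lo < hi:
            mid = (lo + hi) // 2
            if tails[mid] < pb[i]:
                lo = mid + 1
            else:
                hi = mid
        if lo > 0:
            parent[i] = tail_idx[lo - 1]
        if lo == len(tails):
            tails.append(int(pb[i]))
            tail_idx.append(i)
        elif pb[i] < tails[lo]:
            tails[lo] = int(pb[i])
            tail_idx[lo] = i
    end = tail_idx[-1]
    start = end
    while parent[start] != -1:
        start = parent[start]
    return int(pa[end] - pa[start]) + k


def estimate_overlap(a: CloneInsert, b: CloneInsert, k: int = DEFAULT_K) -> OverlapEdge:
    """Estimate the shared-sequence length between two inserts.

    Both orientations of ``b`` are tried; the orientation with the larger
    chained span wins and sets the edge strand. Returns overlap 0 when the
    inserts share no unique k-mers, or (with a warning) when either insert
    is shorter than k.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("insert sequences must be non-empty")
    if k > min(len(a.sequence), len(b.sequence)):
        warnings.warn(
            f"k={k} exceeds an insert length for pair "
            f"({a.clone_id}, {b.clone_id}); reporting overlap 0", stacklevel=2)
        return OverlapEdge(a.clone_id, b.clone_id, 0, "same")
    pos_a = unique_kmer_positions(a.sequence, k)
    best_span, best_strand = 0, "same"
    for strand, seq_b in (("same", b.sequence), ("opposite", revcomp(b.sequence))):
        pos_b = unique_kmer_positions(seq_b, k)
        shared = pos_a.keys() & pos_b.keys()
        if not shared:
            continue
        pa = np.fromiter((pos_a[s] for s in shared), dtype=np.int64, count=len(shared))
        pb = np.fromiter((pos_b[s] for s in shared), dtype=np.int64, count=len(shared))
        span = _longest_colinear_span(pa, pb, k)
        if span > best_span:
            best_span, best_strand = span, strand
    return OverlapEdge(a.clone_id, b.clone_id, best_span, best_strand)


def build_overlap_graph(
    library: list[CloneInsert],
    min_overlap: int = MIN_OVERLAP_BP,
    k: int = DEFAULT_K,
) -> list[OverlapEdge]:
    """Edges between all insert pairs whose overlap is strictly above
    ``min_overlap`` bp.

    All unordered pairs are considered; pairs sharing no canonical k-mer at
    all are skipped by a sorted-array intersection prefilter before the
    chaining estimator runs.
    """
    sets = [canonical_kmer_set(c.sequence, k) if len(c.sequence) >= k
            else np.empty(0, dtype=np.uint64) for c in library]
    edges = []
    for i in range(len(library)):
        for j in range(i + 1, len(library)):
            if sets[i].size and sets[j].size:
                if np.intersect1d(sets[i], sets[j], assume_unique=False).size == 0:
                    continue
            edge = estimate_overlap(library[i], library[j], k=k)
            if edge.overlap_bp > min_overlap:
                edges.append(edge)
    return edges


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def group_effector_regions(edges: list[OverlapEdge],
                           clones: list[str]) -> list[EffectorRegion]:
    """Connected components of the overlap graph as effector regions.

    Isolated clones become singleton regions. Regions are numbered in order
    of their lexicographically smallest member, so output is deterministic.
    """
    uf = _UnionFind(clones)
    for e in edges:
        uf.union(e.clone_a, e.clone_b)
    comps: dict[str, set[str]] = {}
    for c in clones:
        comps.setdefault(uf.find(c), set()).add(c)
    ordered = sorted(comps.values(), key=min)
    return [EffectorRegion(f"ER{i + 1:03d}", frozenset(m))
            for i, m in enumerate(ordered)]


def summarize_regions(regions: list[EffectorRegion]) -> dict[str, int]:
    """Clone/region tallies: total clones, clones in multi-clone groups,
    number of groups, singletons, and total regions."""
    n_singletons = sum(1 for r in regions if r.is_singleton)
    n_groups = len(regions) - n_singletons
    n_clones = sum(len(r.members) for r in regions)
    return {
        "n_clones": n_clones,
        "n_overlapping_clones": n_clones - n_singletons,
        "n_groups": n_groups,
        "n_singletons": n_singletons,
        "n_regions": len(regions),
    }
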