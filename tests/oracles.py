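"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths they check: overlap length by
dynamic-programming longest common substring, protein alignment by an
explicit Gotoh recursion, ORFs by regex-free six-frame codon scanning, and
image maxima by an exhaustive neighborhood scan.
"""

from __future__ import annotations

import numpy as np

from fmscreen.seqs import revcomp

STOPS = {"TAA", "TAG", "TGA"}


def longest_common_substring(a: str, b: str) -> int:
    """Exact LCS length via row-vectorized dynamic programming."""
    if not a or not b:
        return 0
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(b), dtype=np.int32)
    best = 0
    for ch in a.encode():
        eq = bb == ch
        cur = np.zeros_like(prev)
        cur[0] = eq[0]
        cur[1:] = np.where(eq[1:], prev[:-1] + 1, 0)
        m = cur.max()
        if m > best:
            best = int(m)
        prev = cur
    return best


def overlap_by_lcs(seq_a: str, seq_b: str) -> int:
    """Shared-sequence length between two inserts, orientation-blind."""
    return max(longest_common_substring(seq_a, seq_b),
               longest_common_substring(seq_a, revcomp(seq_b)))


def group_by_lcs(inserts, min_overlap: int) -> list[frozenset]:
    """Region partition from brute-force pairwise LCS + transitive closure."""
    ids = [c.clone_id for c in inserts]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(len(inserts)):
        for j in range(i + 1, len(inserts)):
            if overlap_by_lcs(inserts[i].sequence, inserts[j].sequence) > min_overlap:
                parent[find(ids[j])] = find(ids[i])
    comps: dict[str, set] = {}
    for cid in ids:
        comps.setdefault(find(cid), set()).add(cid)
    return sorted((frozenset(v) for v in comps.values()), key=min)


def gotoh_local_score(a: str, b: str, matrix, gap_open: float = 12.0,
                      gap_extend: float = 1.0) -> float:
    """Smith-Waterman score with affine gaps: a gap of length g costs
    gap_open + (g-1)*gap_extend, matching the aligner's parameterization."""
    n, m = len(a), len(b)
    neg = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, Ix[i - 1][j - 1] + s,
                          Iy[i - 1][j - 1] + s)
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return best


def six_frame_orfs(seq: str, min_len: int) -> set[tuple[int, int, str]]:
    """(start, end, strand) of maximal ATG->stop frames, forward coords."""
    out = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, L - 2, 3)]
            seg_start = 0  # codon index where the current inter-stop segment begins
            for ci, codon in enumerate(codons):
                if codon in STOPS:
                    segment = codons[seg_start:ci]
                    for k, c in enumerate(segment):
                        if c == "ATG":
                            start = frame + (seg_start + k) * 3
                            end = frame + (ci + 1) * 3
                            if end - start >= min_len:
                                if strand == "-":
                                    start, end = L - end, L - start
                                out.add((start, end, strand))
                            break
                    seg_start = ci + 1
    return out


def local_maxima(img: np.ndarray, threshold: float, radius: int = 2) -> list[tuple[int, int]]:
    """Exhaustive scan: pixels above threshold that are strict maxima of
    their (2r+1)^2 neighborhood."""
    peaks = []
    H, W = img.shape
    for y in range(H):
        for x in range(W):
            v = img[y, x]
            if v <= threshold:
                continue
            y0, y1 = max(0, y - radius), min(H, y + radius + 1)
            x0, x1 = max(0, x - radius), min(W, x + radius + 1)
            patch = img[y0:y1, x0:x1]
            if v >= patch.max():
                peaks.append((y, x))
    return peaks
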