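"""Low-level DNA/protein sequence helpers shared across the pipeline.

Sequences are plain Python strings over {A,C,G,T} (DNA) or the 20 standard
amino-acid letters (protein). K-mers are packed 2 bits per base into uint64,
which caps k at 31 — exactly the default used by the overlap estimator.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# base -> 2-bit code; 255 marks a non-ACGT byte so we can detect bad input
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA_ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to a uint8 array of 2-bit base codes.

    Raises ValueError on characters outside {A,C,G,T} (case-insensitive).
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if codes.max(initial=0) == 255:
        bad = chr(raw[codes == 255][0])
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return codes


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """All overlapping k-mers of ``seq`` packed into uint64, in order.

    Returns an empty array when the sequence is shorter than k.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31] for 2-bit uint64 packing")
    codes = encode_bases(seq)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.uint64)
    weights = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    return windows @ weights


def unique_kmer_positions(seq: str, k: int) -> dict[int, int]:
    """Map each k-mer occurring exactly once in ``seq`` to its start position."""
    kmers = kmer_codes(seq, k)
    if kmers.size == 0:
        return {}
    vals, first, counts = np.unique(kmers, return_index=True, return_counts=True)
    keep = counts == 1
    return dict(zip(vals[keep].tolist(), first[keep].tolist()))


def canonical_kmer_set(seq: str, k: int) -> np.ndarray:
    """Sorted array of strand-canonical k-mer codes (min of k-mer and its RC)."""
    fwd = kmer_codes(seq, k)
    if fwd.size == 0:
        return fwd
    rev = kmer_codes(revcomp(seq), k)[::-1]
    return np.unique(np.minimum(fwd, rev))


_DNA_BYTES = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
_AA_BYTES = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA with the requested expected GC fraction."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return bytes(_DNA_BYTES[idx]).decode("ascii")


def random_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein, uniform over the 20 standard residues."""
    idx = rng.integers(0, len(AA_ALPHABET), size=length)
    return bytes(_AA_BYTES[idx]).decode("ascii")
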