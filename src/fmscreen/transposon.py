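"""Transposon-insertion mapping and effector-gene nomination.

A cosmid clone's activity is abolished when a transposon lands inside the
gene responsible for it. Given per-mutant flanking reads (Sanger-style,
long and accurate) and replicate activity readouts, this module locates
each insertion on the insert by exact seed match, classifies each mutant
as active or inactive against the empty-vector control distribution, and
attributes inactivating insertions to predicted ORFs to nominate candidate
effector genes. When every inactivating insertion falls in one gene the
nomination is unambiguous; knockouts spread across several consecutive
genes produce the operon-wide pattern seen for polycistronic effectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .screening import PlateStats
from .seqs import revcomp

MIN_ORF_NT = 150
SEED_LEN = 30
STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_STARTS = ("ATG",)


@dataclass
class ORFCall:
    """A predicted ORF; coordinates are 0-based half-open on the insert's
    forward strand regardless of coding strand."""

    orf_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    protein: str

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TnMutant:
    mutant_id: str
    insertion_pos: int | None  # None when unmapped
    activities: list[float]
    zscores: list[float] = field(default_factory=list)
    inactive: bool = False
    ambiguous: bool = False


@dataclass
class EffectorNomination:
    candidate_genes: list[str]
    inactivating_counts: dict[str, int]
    tolerated_counts: dict[str, int]
    n_intergenic_inactivating: int
    unambiguous: bool


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------

def find_orfs(insert: str, min_len: int = MIN_ORF_NT,
              starts: tuple[str, ...] = DEFAULT_STARTS) -> list[ORFCall]:
    """All maximal start->stop ORFs of length >= ``min_len`` nt (stop codon
    included), on both strands, translated with the bacterial code.

    Maximal means the ORF begins at the first start codon after the
    previous in-frame stop, so nested starts do not spawn sub-ORFs.
    Coordinates are always reported on the forward strand.
    """
    orfs: list[tuple[int, int, str, str]] = []
    L = len(insert)
    for strand, seq in (("+", insert), ("-", revcomp(insert))):
        for frame in range(3):
            start: int | None = None
            for i in range(frame, L - 2, 3):
                codon = seq[i:i + 3]
                if start is None and codon in starts:
                    start = i
                elif codon in STOP_CODONS and start is not None:
                    end = i + 3
                    if end - start >= min_len:
                        protein = str(Seq(seq[start:end]).translate(table=11))
                        orfs.append((start, end, strand, protein.rstrip("*")))
                    start = None
                elif codon in STOP_CODONS:
                    start = None
    calls = []
    for start, end, strand, protein in orfs:
        if strand == "-":
            start, end = L - end, L - start
        calls.append((start, end, strand, protein))
    calls.sort(key=lambda t: (t[0], t[1], t[2]))
    return [ORFCall(f"orf{i + 1:04d}", s, e, st, p)
            for i, (s, e, st, p) in enumerate(calls)]


# ---------------------------------------------------------------------------
# insertion mapping
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def locate_insertion(insert: str, flanking_read: str,
                     seed_len: int = SEED_LEN) -> tuple[int | None, bool]:
    """Map a flanking read onto the insert by exact seed match.

    The read is the sequence immediately 3' of the insertion point, in
    either orientation; the first ``seed_len`` bases of the read and of its
    reverse complement are both searched. Returns (position, ambiguous):
    a unique match gives the insertion coordinate, no match gives
    (None, False), multiple matches give (None, True).
    """
    if len(flanking_read) < seed_len:
        raise ValueError("flanking read shorter than seed_len")
    probes = {flanking_read[:seed_len], revcomp(flanking_read)[:seed_len]}
    matches: set[int] = set()
    for probe in probes:
        matches.update(_find_all(insert, probe))
    if len(matches) == 1:
        return matches.pop(), False
    return None, len(matches) > 1


# ---------------------------------------------------------------------------
# activity classification and nomination
# ---------------------------------------------------------------------------

def classify_mutant_activity(
    mutants: list[TnMutant],
    plate_stats: PlateStats,
    z_threshold: float = 3.0,
    min_fail: int | None = None,
) -> list[TnMutant]:
    """Flag mutants as inactive against the control distribution.

    Each replicate readout becomes a Z-score against ``plate_stats``; a
    mutant is inactive when at least ``min_fail`` replicates have
    z <= z_threshold. The default ``min_fail`` is a strict majority, so an
    even split is broken toward active.
    """
    for m in mutants:
        if not m.activities:
            raise ValueError(f"mutant {m.mutant_id} has no replicate activities")
        z = [(a - plate_stats.mean_control) / plate_stats.sd_control
             for a in m.activities]
        m.zscores = z
        need = min_fail if min_fail is not None else len(z) // 2 + 1
        m.inactive = sum(1 for v in z if v <= z_threshold) >= need
    return mutants


def nominate_effector_genes(mutants: list[TnMutant],
                            orfs: list[ORFCall]) -> EffectorNomination:
    """Attribute insertions to ORFs and nominate candidate effector genes.

    Each mapped insertion is assigned to the single ORF containing its
    coordinate (ties between overlapping ORFs broken toward the longest,
    then by id) or to intergenic space. Candidates are ORFs carrying at
    least one inactivating insertion; the nomination is unambiguous when
    there is exactly one candidate and no intergenic inactivating
    insertion.
    """
    inact: dict[str, int] = {}
    toler: dict[str, int] = {}
    n_intergenic_inact = 0
    for m in mutants:
        if m.insertion_pos is None:
            continue
        containing = [o for o in orfs if o.contains(m.insertion_pos)]
        target = max(containing, key=lambda o: (len(o), o.orf_id), default=None)
        if target is None:
            if m.inactive:
                n_intergenic_inact += 1
            continue
        table = inact if m.inactive else toler
        table[target.orf_id] = table.get(target.orf_id, 0) + 1
    candidates = sorted(inact)
    if not candidates:
        warnings.warn("no inactivating insertions; nomination is empty",
                      stacklevel=2)
    return EffectorNomination(
        candidate_genes=candidates,
        inactivating_counts=inact,
        tolerated_counts=toler,
        n_intergenic_inactivating=n_intergenic_inact,
        unambiguous=len(candidates) == 1 and n_intergenic_inact == 0,
    )


def orfs_to_gff3(orfs: list[ORFCall], seqid: str) -> str:
    """GFF3 text for ORF calls (1-based inclusive coordinates on output)."""
    lines = ["##gff-version 3"]
    for o in orfs:
        lines.append("\t".join([
            seqid, "fmscreen", "CDS", str(o.start + 1), str(o.end), ".",
            o.strand, "0", f"ID={o.orf_id}",
        ]))
    return "\n".join(lines) + "\n"
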