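"""Effector-protein prevalence across patient protein catalogs.

Each query effector protein is aligned (Smith-Waterman local alignment,
BLOSUM62, affine gaps with BLAST-style cost 11 + 1 per residue) against
every protein in each patient catalog. An alignment is a match when its
percent identity is strictly above 90 (identical columns over all
alignment columns, gap columns included in the denominator) and its query
coverage is strictly above 70 (aligned query span over query length).
Prevalence is then the per-query count of patients carrying at least one
match, and the fraction of patients carrying any matching query.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio import Align
from Bio.Align import substitution_matrices

from .seqs import AA_ALPHABET

MIN_IDENTITY_PCT = 90.0
MIN_COVERAGE_PCT = 70.0
GAP_OPEN = 11
GAP_EXTEND = 1
PREFILTER_K = 5

_AA_SET = set(AA_ALPHABET)


@dataclass
class ProteinMatch:
    """Summary of the best local alignment between a query and a subject."""

    query_id: str
    subject_id: str | None
    identity_pct: float
    coverage_pct: float
    score: float
    is_match: bool

    @staticmethod
    def no_match(query_id: str) -> "ProteinMatch":
        return ProteinMatch(query_id, None, 0.0, 0.0, 0.0, False)


@dataclass
class PrevalenceTable:
    per_query_counts: dict[str, int]
    n_patients: int
    n_patients_any: int
    pct_any: int


def _make_aligner(gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND,
                  matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST charges open + extend*g for a gap of g residues; PairwiseAligner
    # charges open for the first residue and extend for each further one
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} sequence must be non-empty")
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(f"invalid residues in {name}: {sorted(bad)}")


def align_protein_pair(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
    min_identity: float = MIN_IDENTITY_PCT,
    min_coverage: float = MIN_COVERAGE_PCT,
    aligner: Align.PairwiseAligner | None = None,
) -> ProteinMatch:
    """Best local alignment of one query/subject pair, with the
    identity/coverage match verdict."""
    _check_protein(query, "query")
    _check_protein(subject, "subject")
    if aligner is None:
        aligner = _make_aligner()
    alignments = aligner.align(query, subject)
    try:
        aln = alignments[0]
    except IndexError:
        return ProteinMatch.no_match(query_id)
    qblocks, sblocks = aln.aligned
    if len(qblocks) == 0:
        return ProteinMatch.no_match(query_id)
    identical = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        aligned_cols += qe - qs
        identical += sum(1 for i in range(qe - qs) if query[qs + i] == subject[ss + i])
    gap_cols = 0
    for idx in range(1, len(qblocks)):
        gap_cols += qblocks[idx][0] - qblocks[idx - 1][1]
        gap_cols += sblocks[idx][0] - sblocks[idx - 1][1]
    total_cols = aligned_cols + gap_cols
    identity = 100.0 * identical / total_cols if total_cols else 0.0
    span = qblocks[-1][1] - qblocks[0][0]
    coverage = 100.0 * span / len(query)
    return ProteinMatch(
        query_id=query_id,
        subject_id=subject_id,
        identity_pct=identity,
        coverage_pct=coverage,
        score=float(aln.score),
        is_match=identity > min_identity and coverage > min_coverage,
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def screen_catalog(
    query: str,
    catalog: list[tuple[str, str]],
    query_id: str = "query",
    prefilter_k: int = PREFILTER_K,
    min_identity: float = MIN_IDENTITY_PCT,
    min_coverage: float = MIN_COVERAGE_PCT,
) -> ProteinMatch:
    """Best match for a query against one patient's proteins.

    Only catalog entries sharing at least one ``prefilter_k``-mer with the
    query are aligned. The best candidate is ranked by (is_match,
    identity, coverage); an empty or fully filtered catalog yields a
    non-match.
    """
    qkmers = _kmer_set(query, prefilter_k)
    aligner = _make_aligner()
    best = ProteinMatch.no_match(query_id)
    for sid, seq in catalog:
        if qkmers.isdisjoint(_kmer_set(seq, prefilter_k)):
            continue
        m = align_protein_pair(query, seq, query_id, sid,
                               min_identity, min_coverage, aligner=aligner)
        if (m.is_match, m.identity_pct, m.coverage_pct) > \
           (best.is_match, best.identity_pct, best.coverage_pct):
            best = m
    return best


def compute_prevalence(
    queries: dict[str, str],
    catalogs: list[list[tuple[str, str]]],
    prefilter_k: int = PREFILTER_K,
    min_identity: float = MIN_IDENTITY_PCT,
    min_coverage: float = MIN_COVERAGE_PCT,
) -> PrevalenceTable:
    """Per-query patient counts and the any-query prevalence percentage.

    ``pct_any`` is rounded to the nearest integer (half away from zero),
    matching how such prevalences are conventionally printed.
    """
    counts = {qid: 0 for qid in queries}
    n_any = 0
    for catalog in catalogs:
        any_hit = False
        for qid, qseq in queries.items():
            m = screen_catalog(qseq, catalog, qid, prefilter_k,
                               min_identity, min_coverage)
            if m.is_match:
                counts[qid] += 1
                any_hit = True
        n_any += any_hit
    n = len(catalogs)
    pct = int(Decimal(repr(100.0 * n_any / n)).quantize(
        Decimal(1), rounding=ROUND_HALF_UP)) if n else 0
    return PrevalenceTable(counts, n, n_any, pct)
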