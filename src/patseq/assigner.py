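"""Transcript assignment of gene-derived fragments.

Seed-chain-extend stand-in for a BLAT-style aligner: exact k-mer seeding,
diagonal chaining to pick candidate transcripts, then banded local alignment
(via Biopython's C pairwise aligner) scored as

    score = n_matches - n_mismatches - gap_open_penalty * n_gap_opens

with a gap extension cost of zero, so the published score threshold keeps
its meaning. Acceptance filters mirror the published pipeline: tail length
strictly greater than ``min_pat``, score at least ``min_score``, optional
pass-count and mitochondrial filters.
"""
from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from Bio import Align

from .io_model import CCSRead, TailRecord, TranscriptDB
from .tail_caller import TailCall

__all__ = [
    "Assignment",
    "KmerIndex",
    "build_index",
    "assign_fragment",
    "apply_filters",
    "filter_tail_records",
    "FilterResult",
]

GAP_OPEN_PENALTY = 1


@dataclass(frozen=True)
class Assignment:
    transcript_id: Optional[str]
    gene_id: Optional[str]
    score: float
    aln_start: int
    aln_end: int
    n_matches: int
    n_mismatches: int
    n_gap_opens: int
    status: str  # accepted | low_score | ambiguous | unaligned


UNALIGNED = Assignment(
    transcript_id=None,
    gene_id=None,
    score=0.0,
    aln_start=0,
    aln_end=0,
    n_matches=0,
    n_mismatches=0,
    n_gap_opens=0,
    status="unaligned",
)


class KmerIndex:
    """Exact k-mer postings over a transcript database."""

    def __init__(self, k: int, postings: dict[str, list[tuple[str, int]]]):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.k = k
        self.postings = postings


def build_index(db: TranscriptDB, k: int = 13) -> KmerIndex:
    if k < 8:
        raise ValueError("k must be >= 8")
    if len(db) == 0:
        raise ValueError("empty transcript database")
    postings: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for tx in db:
        seq = tx.sequence
        if len(seq) < k:
            warnings.warn(
                f"transcript {tx.transcript_id!r} shorter than k={k}; skipped"
            )
            continue
        for off in range(len(seq) - k + 1):
            postings[seq[off : off + k]].append((tx.transcript_id, off))
    return KmerIndex(k=k, postings=dict(postings))


def _make_aligner() -> Align.PairwiseAligner:
    # Gap extension is penalized during alignment *selection* only (otherwise
    # zero-cost extensions chain chance di-nucleotide matches through long
    # jumps); the reported score ignores extension, keeping the
    # matches - mismatches - gap_opens convention behind the threshold.
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -GAP_OPEN_PENALTY
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def _alignment_counts(alignment, target: str, query: str) -> tuple[int, int, int]:
    """(n_matches, n_mismatches, n_gap_opens) from an alignment's blocks."""
    t_blocks, q_blocks = alignment.aligned
    n_match = 0
    n_mismatch = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b and a != "N" and b != "N":
                n_match += 1
            else:
                n_mismatch += 1
    n_gap_opens = max(0, len(t_blocks) - 1)
    return n_match, n_mismatch, n_gap_opens


def _candidate_transcripts(
    fragment: str, index: KmerIndex, max_candidates: int, band: int
) -> list[tuple[str, int, int, int]]:
    """Rank transcripts by chained-seed support on a common diagonal band.

    Returns (transcript_id, support, tmin, tmax) sorted by support desc.
    """
    k = index.k
    seeds: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for qpos in range(0, len(fragment) - k + 1):
        for tid, tpos in index.postings.get(fragment[qpos : qpos + k], ()):
            seeds[tid].append((qpos, tpos))
    ranked = []
    for tid, hits in seeds.items():
        diags = sorted(tpos - qpos for qpos, tpos in hits)
        # best number of seeds whose diagonals lie within one band
        best = 0
        j = 0
        for i in range(len(diags)):
            while diags[i] - diags[j] > 2 * band:
                j += 1
            best = max(best, i - j + 1)
        # expected alignment span on the transcript, from seed diagonals
        tmin = min(tpos - qpos for qpos, tpos in hits)
        tmax = max(tpos - qpos for qpos, tpos in hits)
        ranked.append((tid, best, tmin, tmax))
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked[:max_candidates]


def _align_candidate(
    fragment: str,
    tx_seq: str,
    tmin: int,
    tmax: int,
    band: int,
) -> tuple[float, int, int, int, int, int]:
    """Align fragment to a seeded transcript window.

    Returns (score, aln_start, aln_end, n_matches, n_mismatches, n_gap_opens)
    with alignment coordinates on the full transcript.
    """
    lo = max(0, tmin - band)
    hi = min(len(tx_seq), tmax + len(fragment) + band)
    window = tx_seq[lo:hi]
    alignments = _ALIGNER.align(window, fragment)
    alignment = alignments[0]
    if len(alignment.aligned[0]) == 0:
        return 0.0, 0, 0, 0, 0, 0
    n_match, n_mismatch, n_gaps = _alignment_counts(alignment, window, fragment)
    score = n_match - n_mismatch - GAP_OPEN_PENALTY * n_gaps
    t_blocks = alignment.aligned[0]
    aln_start = lo + int(t_blocks[0][0])
    aln_end = lo + int(t_blocks[-1][1])
    return float(score), aln_start, aln_end, n_match, n_mismatch, n_gaps


def assign_fragment(
    fragment_seq: str,
    index: KmerIndex,
    db: TranscriptDB,
    min_score: float = 50,
    band: int = 15,
    max_candidates: int = 8,
) -> Assignment:
    """Assign a fragment to its best-scoring transcript.

    Status is ``unaligned`` with no seed hits, ``ambiguous`` when the top two
    transcripts of *different* genes tie on score, ``low_score`` below
    ``min_score`` and ``accepted`` otherwise.
    """
    if not fragment_seq:
        return UNALIGNED
    candidates = _candidate_transcripts(fragment_seq, index, max_candidates, band)
    if not candidates:
        return UNALIGNED
    results = []
    for tid, _support, tmin, tmax in candidates:
        tx = db[tid]
        score, s, e, nm, nx, ng = _align_candidate(fragment_seq, tx.sequence, tmin, tmax, band)
        results.append((score, tid, s, e, nm, nx, ng))
    results.sort(key=lambda item: (-item[0], item[1]))
    best = results[0]
    best_tx = db[best[1]]
    status = "accepted" if best[0] >= min_score else "low_score"
    if len(results) > 1:
        runner = results[1]
        if runner[0] == best[0] and db[runner[1]].gene_id != best_tx.gene_id:
            status = "ambiguous"
    return Assignment(
        transcript_id=best[1],
        gene_id=best_tx.gene_id,
        score=best[0],
        aln_start=best[2],
        aln_end=best[3],
        n_matches=best[4],
        n_mismatches=best[5],
        n_gap_opens=best[6],
        status=status,
    )


@dataclass
class FilterResult:
    accepted: list[TailRecord]
    tally: dict[str, int]


_FILTER_REASONS = ("short_pat", "unaligned", "ambiguous", "low_score", "few_passes", "mito")


def _empty_tally() -> dict[str, int]:
    return {reason: 0 for reason in _FILTER_REASONS}


def apply_filters(
    calls: Iterable[tuple[TailCall, Assignment, CCSRead]],
    db: TranscriptDB,
    min_pat: int = 10,
    min_score: float = 50,
    min_passes: Optional[int] = 3,
    drop_mito: bool = False,
    condition: str = "",
    timepoint_min: Optional[float] = None,
) -> FilterResult:
    """Apply the acceptance filters to (tail call, assignment, read) triples.

    A read is kept when its tail is strictly longer than ``min_pat``, its
    assignment is accepted with score >= ``min_score``, its pass count (when
    present) is >= ``min_passes`` and, if ``drop_mito``, its gene is not
    mitochondrial. The first failing check determines the tallied reason.
    """
    tally = _empty_tally()
    accepted: list[TailRecord] = []
    for call, assignment, read in calls:
        reason = _rejection_reason(
            call.pat_length,
            assignment,
            read.num_passes,
            db,
            min_pat=min_pat,
            min_score=min_score,
            min_passes=min_passes,
            drop_mito=drop_mito,
        )
        if reason is not None:
            tally[reason] += 1
            continue
        accepted.append(
            TailRecord(
                read_id=read.read_id,
                transcript_id=assignment.transcript_id,
                gene_id=assignment.gene_id,
                pat_length=call.pat_length,
                n_disruptions=call.n_disruptions,
                orientation=call.orientation,
                score=assignment.score,
                condition=condition,
                timepoint_min=timepoint_min,
            )
        )
    return FilterResult(accepted=accepted, tally=tally)


def _rejection_reason(
    pat_length: int,
    assignment: Assignment,
    num_passes: Optional[int],
    db: TranscriptDB,
    min_pat: int,
    min_score: float,
    min_passes: Optional[int],
    drop_mito: bool,
) -> Optional[str]:
    if pat_length <= min_pat:  # "longer than 10 bp" is strict
        return "short_pat"
    if assignment.status == "unaligned":
        return "unaligned"
    if assignment.status == "ambiguous":
        return "ambiguous"
    if assignment.score < min_score:
        return "low_score"
    if min_passes is not None and num_passes is not None and num_passes < min_passes:
        return "few_passes"
    if drop_mito and assignment.transcript_id is not None:
        if db[assignment.transcript_id].is_mitochondrial:
            return "mito"
    return None


def filter_tail_records(
    records: Iterable[TailRecord],
    mito_genes: Optional[set[str]] = None,
    min_pat: int = 10,
    min_score: float = 50,
    drop_mito: bool = False,
) -> list[TailRecord]:
    """Re-apply the record-level acceptance filters; idempotent on its own
    output."""
    mito = mito_genes or set()
    kept = []
    for rec in records:
        if rec.pat_length <= min_pat:
            continue
        if rec.score < min_score:
            continue
        if drop_mito and rec.gene_id in mito:
            continue
        kept.append(rec)
    return kept
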