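"""Read orientation by adapter detection and nucleotide-resolution poly(A)
tract extraction.

The tract rule: scanning 5'-ward from the base immediately before the
adapter junction, the accepted tract is the maximal extension in which every
non-A base is an isolated single-base disruption bracketed by at least two
consecutive A bases on each side *within the tract*. Disruption bases count
toward the reported tail length (the tract is measured end to end). Two
adjacent non-A bases, or a disruption whose bracketing A's never
materialise, terminate the tract at the last valid boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_model import CCSRead

__all__ = [
    "AdapterConfig",
    "AdapterHit",
    "TailCall",
    "Rejection",
    "DEFAULT_ADAPTERS",
    "revcomp",
    "find_adapter",
    "orient_read",
    "call_tail",
    "process_read",
    "duplicate_fraction",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AdapterConfig:
    """Adapter sequences and ungapped-match tolerances.

    ``splint_adapter_seq`` is the mRNA-sense sequence of the 3'-side adapter
    ligated after the tail (the splint's templated T overhang belongs to the
    adapter, not the tail). ``fragment_adapter_seq`` is the hexamer-side
    adapter at the fragment 5' end.
    """

    splint_adapter_seq: str
    fragment_adapter_seq: str
    min_anchor_len: int = 12
    max_mismatch_frac: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mismatch_frac <= 0.25:
            raise ConfigError("max_mismatch_frac must be within [0, 0.25]")
        for name in ("splint_adapter_seq", "fragment_adapter_seq"):
            seq = getattr(self, name)
            if len(seq) < self.min_anchor_len:
                raise ConfigError(f"{name} shorter than min_anchor_len")
            object.__setattr__(self, name, seq.upper())


DEFAULT_ADAPTERS = AdapterConfig(
    splint_adapter_seq="GATCGGTCGAGCGTCGTGTCG",
    fragment_adapter_seq="CTGCACGACGCTCTTCCGTACT",
)


@dataclass(frozen=True)
class AdapterHit:
    start: int
    end: int
    strand: str  # forward | reverse
    n_mismatches: int
    which: str  # splint | fragment


@dataclass(frozen=True)
class TailCall:
    orientation: str
    junction: int
    tract_start: int
    tract_end: int
    pat_length: int
    n_disruptions: int
    fragment_seq: str


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # no_adapter | no_tail


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_counts(seq_arr: np.ndarray, adapter: str) -> np.ndarray:
    """Mismatches of ``adapter`` at every ungapped offset of ``seq_arr``."""
    m = len(adapter)
    windows = sliding_window_view(seq_arr, m)
    return (windows != _encode(adapter)).sum(axis=1)


def find_adapter(
    sequence: str, adapter: str, cfg: AdapterConfig, which: str = "splint"
) -> Optional[AdapterHit]:
    """Best ungapped hit of ``adapter`` or its reverse complement.

    All full-length placements on both strands are scored by mismatch count;
    qualifying hits have mismatch fraction <= ``cfg.max_mismatch_frac``. Ties
    are broken by lowest start coordinate, then forward strand.
    """
    adapter = adapter.upper()
    if len(adapter) < cfg.min_anchor_len:
        raise ConfigError("adapter shorter than min_anchor_len")
    m = len(adapter)
    if len(sequence) < m:
        return None
    max_mm = int(np.floor(cfg.max_mismatch_frac * m))
    arr = _encode(sequence.upper())
    best: Optional[tuple[int, int, int]] = None  # (n_mm, start, strand_rank)
    for strand_rank, (strand, probe) in enumerate(
        [("forward", adapter), ("reverse", revcomp(adapter))]
    ):
        counts = _mismatch_counts(arr, probe)
        idx = int(np.argmin(counts))
        n_mm = int(counts[idx])
        if n_mm > max_mm:
            continue
        # argmin already takes the lowest qualifying start on this strand
        cand = (n_mm, idx, strand_rank)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    n_mm, start, strand_rank = best
    strand = "forward" if strand_rank == 0 else "reverse"
    return AdapterHit(start=start, end=start + m, strand=strand, n_mismatches=n_mm, which=which)


def orient_read(
    read: CCSRead, cfg: AdapterConfig
) -> Optional[tuple[str, str, int]]:
    """Locate the splint adapter and return the mRNA-sense view of the read.

    Returns ``(oriented_sequence, orientation, junction)`` where ``junction``
    is the 0-based position of the first adapter base on the oriented read,
    or ``None`` when no qualifying adapter hit exists.
    """
    hit = find_adapter(read.sequence, cfg.splint_adapter_seq, cfg, which="splint")
    if hit is None:
        return None
    if hit.strand == "forward":
        return read.sequence, "forward", hit.start
    oriented = revcomp(read.sequence)
    junction = len(read.sequence) - hit.end
    return oriented, "reverse", junction


def _scan_tract(seq: str, junction: int) -> tuple[int, int]:
    """Return (tract_start, n_disruptions) of the maximal valid tract ending
    at ``junction``; tract_start == junction means no tract.

    Greedy leftward scan with rollback: a non-A is provisionally entered when
    it has >= 2 A immediately to its right inside the tract, and the tract
    boundary only advances once >= 2 A have accumulated on its left.
    """
    valid_start = junction
    valid_dis = 0
    cur_dis = 0
    a_run = 0
    pending = False
    for i in range(junction - 1, -1, -1):
        if seq[i] == "A":
            a_run += 1
            if pending and a_run >= 2:
                pending = False
            if not pending:
                valid_start = i
                valid_dis = cur_dis
        else:
            if pending or a_run < 2:
                break
            pending = True
            cur_dis += 1
            a_run = 0
    return valid_start, valid_dis


def call_tail(oriented_seq: str, junction: int) -> Optional[TailCall]:
    """Extract the adapter-abutting poly(A) tract on an oriented read.

    Returns ``None`` (reason ``no_tail``) when the base at ``junction - 1``
    cannot start a tract, i.e. the tail length would be zero.
    """
    if not 0 < junction <= len(oriented_seq):
        raise ValueError(f"junction {junction} out of range for read of length {len(oriented_seq)}")
    start, n_dis = _scan_tract(oriented_seq, junction)
    if start == junction:
        return None
    return TailCall(
        orientation="forward",
        junction=junction,
        tract_start=start,
        tract_end=junction,
        pat_length=junction - start,
        n_disruptions=n_dis,
        fragment_seq=oriented_seq[:start],
    )


def process_read(read: CCSRead, cfg: AdapterConfig) -> TailCall | Rejection:
    """Orient a read and call its tail; returns a reason-coded rejection when
    either stage fails."""
    oriented = orient_read(read, cfg)
    if oriented is None:
        return Rejection(read.read_id, "no_adapter")
    seq, orientation, junction = oriented
    if junction == 0:
        return Rejection(read.read_id, "no_tail")
    call = call_tail(seq, junction)
    if call is None:
        return Rejection(read.read_id, "no_tail")
    return TailCall(
        orientation=orientation,
        junction=call.junction,
        tract_start=call.tract_start,
        tract_end=call.tract_end,
        pat_length=call.pat_length,
        n_disruptions=call.n_disruptions,
        fragment_seq=call.fragment_seq,
    )


def duplicate_fraction(reads: Iterable[CCSRead]) -> float:
    """Fraction of reads whose full sequence repeats an earlier read's."""
    seen: set[str] = set()
    total = 0
    dups = 0
    for read in reads:
        total += 1
        if read.sequence in seen:
            dups += 1
        else:
            seen.add(read.sequence)
    if total == 0:
        raise ValueError("duplicate_fraction of an empty collection")
    return dups / total
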