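"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: tract calling by full
enumeration, adapter search by per-offset scanning, and local alignment by
an explicit three-state dynamic program.
"""
from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def tract_is_valid(tract: str) -> bool:
    """A tract is valid when every non-A base has >= 2 consecutive A
    immediately on both sides within the tract (implies no adjacent non-A)."""
    n = len(tract)
    for i, base in enumerate(tract):
        if base == "A":
            continue
        if i < 2 or i > n - 3:
            return False
        if tract[i - 2 : i] != "AA" or tract[i + 1 : i + 3] != "AA":
            return False
    return True


def brute_force_tail(seq: str, junction: int) -> tuple[int, int]:
    """Longest valid adapter-abutting tract by enumerating every start.

    Returns (pat_length, n_disruptions); (0, 0) when no valid tract exists.
    """
    for start in range(0, junction):
        tract = seq[start:junction]
        if tract_is_valid(tract):
            return junction - start, sum(1 for b in tract if b != "A")
    return 0, 0


def brute_force_adapter(
    seq: str, adapter: str, max_mismatch_frac: float
) -> tuple[int, int, str] | None:
    """Best ungapped adapter hit over all offsets and both strands.

    Returns (start, n_mismatches, strand) with ties broken by fewest
    mismatches, then lowest start, then forward strand; None if nothing
    qualifies.
    """
    import math

    m = len(adapter)
    max_mm = math.floor(max_mismatch_frac * m)
    candidates = []
    for strand_rank, (strand, probe) in enumerate(
        [("forward", adapter), ("reverse", rc(adapter))]
    ):
        for start in range(0, len(seq) - m + 1):
            n_mm = sum(1 for a, b in zip(seq[start : start + m], probe) if a != b)
            if n_mm <= max_mm:
                candidates.append((n_mm, start, strand_rank, strand))
    if not candidates:
        return None
    n_mm, start, _, strand = min(candidates)
    return start, n_mm, strand


def local_align_score(a: str, b: str, gap_open: float = 1.0, gap_extend: float = 0.5) -> float:
    """Best local alignment score with match +1, mismatch -1, ``gap_open``
    for the first position of each gap run and ``gap_extend`` for each
    further gapped position (same affine convention as the package's
    aligner). For alignments whose gaps are all single-base, this equals
    matches - mismatches - gap_opens."""
    NEG = float(-(10**9))
    n, m = len(a), len(b)
    best = 0.0
    prev_m = [0.0] * (m + 1)
    prev_x = [NEG] * (m + 1)
    prev_y = [NEG] * (m + 1)
    for i in range(1, n + 1):
        cur_m = [0.0] * (m + 1)
        cur_x = [NEG] * (m + 1)
        cur_y = [NEG] * (m + 1)
        for j in range(1, m + 1):
            s = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else -1
            cur_m[j] = max(0.0, prev_m[j - 1], prev_x[j - 1], prev_y[j - 1]) + s
            cur_x[j] = max(
                prev_m[j] - gap_open, prev_x[j] - gap_extend, prev_y[j] - gap_open
            )
            cur_y[j] = max(
                cur_m[j - 1] - gap_open, cur_y[j - 1] - gap_extend, cur_x[j - 1] - gap_open
            )
            best = max(best, cur_m[j])
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return best
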