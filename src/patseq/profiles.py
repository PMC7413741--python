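"""Tail-length analytics: fraction and cumulative profiles, sliding-window
smoothing, per-gene medians, gene-set averages, decile bins, Welch tests,
TPM conversion and rank correlation."""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .io_model import GeneSet, TailRecord

__all__ = [
    "PATHistogram",
    "PATProfile",
    "GeneSummary",
    "SetAverage",
    "WelchResult",
    "CorrelationResult",
    "histogram",
    "to_profile",
    "smooth",
    "per_gene_medians",
    "set_averages",
    "decile_bins",
    "welch_ttest",
    "tpm",
    "rank_correlation",
]

logger = logging.getLogger(__name__)

L_MAX_DEFAULT = 350


def _gene_ids(subset) -> Optional[frozenset[str]]:
    if subset is None:
        return None
    if isinstance(subset, GeneSet):
        return subset.gene_ids
    return frozenset(subset)


@dataclass
class PATHistogram:
    """Integer tail-length counts over lengths 1..L_max (index L-1)."""

    counts: np.ndarray
    condition: str
    n_reads: int
    l_max: int
    n_overflow: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.l_max,):
            raise ValueError("counts must have one entry per length 1..L_max")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if int(self.counts.sum()) != self.n_reads:
            raise ValueError("sum(counts) != n_reads")


@dataclass
class PATProfile:
    """Fraction f(L) and cumulative F(L) over lengths 1..L_max."""

    fraction: np.ndarray
    cumulative: np.ndarray
    l_max: int
    condition: str = ""
    smoothed: Optional[np.ndarray] = None

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(1, self.l_max + 1)


@dataclass(frozen=True)
class GeneSummary:
    gene_id: str
    n_reads: int
    median_pat: float
    mean_pat: float


@dataclass(frozen=True)
class SetAverage:
    set_name: str
    n_genes: int
    n_reads: int
    mean_pat: float
    sem_pat: float  # read-level sd/sqrt(n_reads); primary convention
    sem_pat_gene: float  # gene-level alternative (sd of gene means / sqrt(n_genes))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    spearman_rho: float
    spearman_rho2: float
    pearson_r2_log: float


def histogram(
    records: Iterable[TailRecord],
    subset=None,
    condition: str = "",
    l_max: int = L_MAX_DEFAULT,
) -> PATHistogram:
    """Count records per integer tail length; lengths beyond ``l_max`` are
    truncated into the top bin (logged)."""
    genes = _gene_ids(subset)
    counts = np.zeros(l_max, dtype=np.int64)
    n_overflow = 0
    n = 0
    for rec in records:
        if genes is not None and rec.gene_id not in genes:
            continue
        n += 1
        length = rec.pat_length
        if length > l_max:
            n_overflow += 1
            length = l_max
        counts[length - 1] += 1
    if n_overflow:
        logger.warning("%d tail lengths > %d truncated into top bin", n_overflow, l_max)
    return PATHistogram(counts=counts, condition=condition, n_reads=n, l_max=l_max, n_overflow=n_overflow)


def to_profile(h: PATHistogram) -> PATProfile:
    if h.n_reads == 0:
        raise ValueError("cannot build a profile from an empty histogram")
    fraction = h.counts / h.n_reads
    cumulative = np.cumsum(fraction)
    return PATProfile(fraction=fraction, cumulative=cumulative, l_max=h.l_max, condition=h.condition)


def smooth(fraction: Sequence[float], half_window: int = 5) -> np.ndarray:
    """Sliding +/- ``half_window`` averaging with truncated edge windows,
    rescaled so total mass is preserved."""
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    f = np.asarray(fraction, dtype=float)
    if half_window == 0:
        return f.copy()
    n = len(f)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n, i + half_window + 1)
        out[i] = f[lo:hi].mean()
    total_before = f.sum()
    total_after = out.sum()
    if total_after > 0:
        out *= total_before / total_after
    return out


def per_gene_medians(
    records: Iterable[TailRecord], min_reads: int = 10
) -> list[GeneSummary]:
    """Per-gene tail-length summaries for genes with >= ``min_reads`` reads.

    Median uses the order-statistic convention (mean of the central pair for
    even counts). Output sorted by gene id for determinism.
    """
    by_gene: dict[str, list[int]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec.pat_length)
    out = []
    for gene_id in sorted(by_gene):
        lengths = by_gene[gene_id]
        if len(lengths) < min_reads:
            continue
        arr = np.asarray(lengths, dtype=float)
        out.append(
            GeneSummary(
                gene_id=gene_id,
                n_reads=len(lengths),
                median_pat=float(np.median(arr)),
                mean_pat=float(arr.mean()),
            )
        )
    return out


def set_averages(
    records: Sequence[TailRecord], sets: Iterable[GeneSet]
) -> list[SetAverage]:
    """Mean tail length over each gene set's member reads.

    The primary SEM is read-level (sd over member reads / sqrt(n_reads)); a
    gene-level SEM over per-gene means is reported alongside. Sets with no
    member reads are emitted with n_reads=0 and NaN statistics.
    """
    out = []
    for gs in sets:
        member = [r for r in records if r.gene_id in gs.gene_ids]
        genes = sorted({r.gene_id for r in member})
        if not member:
            out.append(SetAverage(gs.name, 0, 0, math.nan, math.nan, math.nan))
            continue
        lengths = np.asarray([r.pat_length for r in member], dtype=float)
        sem_read = float(lengths.std(ddof=1) / math.sqrt(len(lengths))) if len(lengths) > 1 else math.nan
        gene_means = np.asarray(
            [np.mean([r.pat_length for r in member if r.gene_id == g]) for g in genes]
        )
        sem_gene = (
            float(gene_means.std(ddof=1) / math.sqrt(len(gene_means)))
            if len(gene_means) > 1
            else math.nan
        )
        out.append(
            SetAverage(
                set_name=gs.name,
                n_genes=len(genes),
                n_reads=len(member),
                mean_pat=float(lengths.mean()),
                sem_pat=sem_read,
                sem_pat_gene=sem_gene,
            )
        )
    return out


def decile_bins(
    records: Sequence[TailRecord], n_bins: int = 10
) -> list[list[TailRecord]]:
    """Partition records into ``n_bins`` bins by descending tail length.

    Bin 0 holds the longest tails; bin sizes differ by at most one (longer
    bins first); ties keep stable input order.
    """
    records = list(records)
    if len(records) < n_bins:
        raise ValueError(f"need >= {n_bins} records, got {len(records)}")
    lengths = np.asarray([-r.pat_length for r in records])
    order = np.argsort(lengths, kind="stable")
    ordered = [records[i] for i in order]
    base, rem = divmod(len(ordered), n_bins)
    bins = []
    start = 0
    for i in range(n_bins):
        size = base + (1 if i < rem else 0)
        bins.append(ordered[start : start + size])
        start += size
    return bins


def welch_ttest(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-sided Welch's t-test with unequal variances.

    t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny); df by Welch-Satterthwaite;
    p from the t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_ttest needs >= 2 observations per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        raise ValueError("welch_ttest undefined for zero pooled variance")
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def tpm(
    read_counts: Mapping[str, float], effective_lengths: Mapping[str, float]
) -> dict[str, float]:
    """Length-normalized transcripts-per-million from raw read counts."""
    ids = list(read_counts)
    rates = {}
    for tid in ids:
        length = effective_lengths[tid]
        if length <= 0:
            raise ValueError(f"non-positive effective length for {tid!r}")
        rates[tid] = read_counts[tid] / length
    total = sum(rates.values())
    if total == 0:
        raise ValueError("all read counts are zero")
    return {tid: rate / total * 1e6 for tid, rate in rates.items()}


def rank_correlation(a: Sequence[float], b: Sequence[float]) -> CorrelationResult:
    """Spearman rho (average ranks for ties) plus companion Pearson r^2 on
    log-scale values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho = float(stats.spearmanr(a, b).statistic)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("rank_correlation expects strictly positive abundances")
    r = float(stats.pearsonr(np.log(a), np.log(b)).statistic)
    return CorrelationResult(spearman_rho=rho, spearman_rho2=rho**2, pearson_r2_log=r**2)
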