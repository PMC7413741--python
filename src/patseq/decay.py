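"""Time-course analytics after transcription shutoff: per-timepoint tail
profiles, length-decile bins over time, log-linear half-life fitting and
phasing peak detection."""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .io_model import TailRecord
from .profiles import PATProfile, decile_bins, histogram, smooth, to_profile

__all__ = [
    "TimeCourse",
    "PeakSet",
    "HalfLifeFit",
    "timecourse_profiles",
    "binned_timecourse",
    "half_life",
    "peak_detect",
    "phasing_period",
]


@dataclass
class TimeCourse:
    """Timepoint-labelled tail records (or normalized signals for blot-style
    input)."""

    condition: str
    timepoints_min: tuple[float, ...]
    records_by_time: Optional[dict[float, list[TailRecord]]] = None
    signal_by_time: Optional[dict[float, float]] = None

    def __post_init__(self) -> None:
        tps = tuple(self.timepoints_min)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.records_by_time is None and self.signal_by_time is None:
            raise ValueError("a TimeCourse needs records_by_time or signal_by_time")
        if self.signal_by_time is not None and 0 not in [float(t) for t in tps]:
            raise ValueError("normalized-signal time courses require t=0")
        self.timepoints_min = tps


@dataclass(frozen=True)
class PeakSet:
    positions: tuple[int, ...]  # nt, within 1..L_max
    prominences: tuple[float, ...]
    half_window: int


@dataclass(frozen=True)
class HalfLifeFit:
    t_half_hours: float  # NaN when flagged
    slope_per_min: float
    r_squared: float
    flagged_no_decay: bool


def timecourse_profiles(
    tc: TimeCourse,
    subset=None,
    exclude_genes: Optional[Iterable[str]] = None,
    l_max: int = 350,
    half_window: int = 5,
) -> dict[float, PATProfile]:
    """One within-timepoint-normalized profile per timepoint.

    ``subset`` restricts to a gene set; ``exclude_genes`` (e.g. the
    mitochondrial genes) are dropped first. Raises on a timepoint left empty
    after filtering, naming it.
    """
    if tc.records_by_time is None:
        raise ValueError("timecourse_profiles requires a record-mode TimeCourse")
    excluded = set(exclude_genes or ())
    out: dict[float, PATProfile] = {}
    for t in tc.timepoints_min:
        records = [r for r in tc.records_by_time[t] if r.gene_id not in excluded]
        h = histogram(records, subset=subset, condition=f"{tc.condition}_t{t:g}", l_max=l_max)
        if h.n_reads == 0:
            raise ValueError(f"timepoint {t:g} min has no records after filtering")
        profile = to_profile(h)
        profile.smoothed = smooth(profile.fraction, half_window)
        out[t] = profile
    return out


def binned_timecourse(tc: TimeCourse, n_bins: int = 10) -> pd.DataFrame:
    """Decile bins by descending tail length within each timepoint.

    Returns one row per (timepoint, bin) with n, median and quartiles.
    """
    if tc.records_by_time is None:
        raise ValueError("binned_timecourse requires a record-mode TimeCourse")
    rows = []
    for t in tc.timepoints_min:
        bins = decile_bins(tc.records_by_time[t], n_bins=n_bins)
        for i, bin_records in enumerate(bins):
            lengths = np.asarray([r.pat_length for r in bin_records], dtype=float)
            rows.append(
                {
                    "timepoint_min": t,
                    "bin": i,
                    "n": len(bin_records),
                    "median_pat": float(np.median(lengths)),
                    "q1_pat": float(np.percentile(lengths, 25)),
                    "q3_pat": float(np.percentile(lengths, 75)),
                }
            )
    return pd.DataFrame(rows)


def half_life(signal_by_time: Mapping[float, float]) -> HalfLifeFit:
    """Half-life from a least-squares fit of ln(signal) against time.

    Times are minutes, the result hours: t_half = ln(2)/|slope| / 60. A
    non-negative slope is flagged (no decay; t_half undefined).
    """
    items = sorted((float(t), float(s)) for t, s in signal_by_time.items())
    if len(items) < 3:
        raise ValueError("half_life needs >= 3 timepoints")
    times = np.asarray([t for t, _ in items])
    signals = np.asarray([s for _, s in items])
    if (signals <= 0).any():
        raise ValueError("half_life requires strictly positive signals")
    y = np.log(signals)
    slope, intercept = np.polyfit(times, y, 1)
    fitted = slope * times + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if slope >= 0:
        return HalfLifeFit(math.nan, float(slope), r2, flagged_no_decay=True)
    t_half_hours = math.log(2) / abs(slope) / 60.0
    return HalfLifeFit(float(t_half_hours), float(slope), r2, flagged_no_decay=False)


def peak_detect(
    smoothed: Sequence[float],
    min_prominence: float = 0.002,
    min_separation: int = 15,
    half_window: int = 5,
) -> PeakSet:
    """Local maxima of a smoothed profile with prominence and separation
    thresholds; positions are tail lengths (1-based)."""
    f = np.asarray(smoothed, dtype=float)
    idx, props = signal.find_peaks(f, prominence=min_prominence, distance=max(1, min_separation))
    return PeakSet(
        positions=tuple(int(i) + 1 for i in idx),
        prominences=tuple(float(p) for p in props["prominences"]),
        half_window=half_window,
    )


def phasing_period(peaks: PeakSet) -> float:
    """Median spacing between successive peaks."""
    if len(peaks.positions) < 2:
        raise ValueError("phasing_period needs >= 2 peaks")
    spacings = np.diff(sorted(peaks.positions))
    return float(np.median(spacings))
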