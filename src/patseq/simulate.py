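"""Synthetic transcriptomes, tailed molecules, deadenylation time courses and
library-faithful reads with truth tables.

Every operation is deterministic under its seed. Two constraints keep the
truth table exact for an ideal caller: internal A-homopolymers of 8+ nt are
suppressed inside transcript bodies, and the last two transcript bases are
forced non-A so the genomic 3' end can never merge into the synthetic tail.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_model import CCSRead, Transcript, TranscriptDB
from .tail_caller import DEFAULT_ADAPTERS, AdapterConfig, revcomp

__all__ = [
    "SimParams",
    "Molecule",
    "TruthRecord",
    "simulate_transcriptome",
    "simulate_molecules",
    "simulate_deadenylation",
    "simulate_library",
]

_BASES = np.array(list("ACGT"))
_NON_A = np.array(list("CGT"))


@dataclass(frozen=True)
class SimParams:
    n_genes: int = 20
    transcript_length_range: tuple[int, int] = (500, 2000)
    # expected reads per gene ~ LogNormal(ln(abundance_mean_reads), abundance_sigma)
    abundance_mean_reads: float = 100.0
    abundance_sigma: float = 0.5
    # initial tail model: "normal", "point" or "phased"
    pat_mode: str = "normal"
    pat_mean: float = 250.0
    pat_sd: float = 30.0
    pat_point: int = 40
    phased_modes: tuple[int, ...] = (27, 54, 81)
    phased_sd: float = 1.5
    # deadenylation machinery
    footprint_period: int = 27
    protection_factor: float = 1.0
    base_deadenylation_rate: float = 0.5  # nt/min
    regime_switch_length: int = 110
    short_tail_multiplier: float = 1.0  # rate multiplier once tail < regime_switch_length
    protected_edge_width: int = 3  # nt above each footprint boundary that deadenylate slowly
    decay_prob: float = 0.5  # removal probability once a tail shortens below 10 nt
    # library prep
    error_rate: float = 0.0
    adapters: AdapterConfig = DEFAULT_ADAPTERS
    fragment_len_mean: float = 150.0
    fragment_len_sd: float = 40.0
    fragment_len_min: int = 30

    def __post_init__(self) -> None:
        lo, hi = self.transcript_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid transcript_length_range")
        for name in (
            "abundance_mean_reads",
            "pat_mean",
            "base_deadenylation_rate",
            "footprint_period",
            "fragment_len_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.protection_factor < 1:
            raise ValueError("protection_factor must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.pat_mode not in {"normal", "point", "phased"}:
            raise ValueError(f"unknown pat_mode {self.pat_mode!r}")


@dataclass(frozen=True)
class Molecule:
    molecule_id: str
    transcript_id: str
    gene_id: str
    pat_length: int


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    gene_id: str
    pat_length: int
    timepoint_min: Optional[float]
    n_errors: int


def _suppress_a_runs(bases: np.ndarray, rng: np.random.Generator, max_run: int = 7) -> None:
    """Break A-homopolymers longer than ``max_run`` in place (left-to-right)."""
    run = 0
    for i in range(len(bases)):
        if bases[i] == "A":
            run += 1
            if run > max_run:
                bases[i] = _NON_A[rng.integers(0, 3)]
                run = 0
        else:
            run = 0


def simulate_transcriptome(params: SimParams, seed: int) -> TranscriptDB:
    """Random transcripts (uniform composition) with internal A-homopolymers
    suppressed and non-A 3' termini; one transcript per gene."""
    rng = np.random.default_rng(seed)
    lo, hi = params.transcript_length_range
    transcripts = []
    for i in range(params.n_genes):
        length = int(rng.integers(lo, hi + 1))
        bases = _BASES[rng.integers(0, 4, size=length)]
        _suppress_a_runs(bases, rng)
        for j in (length - 2, length - 1):  # keep the 3' terminus out of the tail
            if j >= 0 and bases[j] == "A":
                bases[j] = _NON_A[rng.integers(0, 3)]
        gid = f"GENE{i + 1:04d}"
        transcripts.append(
            Transcript(
                transcript_id=f"TX{i + 1:04d}",
                sequence="".join(bases),
                gene_id=gid,
                gene_symbol=f"SYM{i + 1:04d}",
            )
        )
    return TranscriptDB(transcripts)


def _draw_pat(params: SimParams, rng: np.random.Generator) -> int:
    if params.pat_mode == "point":
        return max(1, int(params.pat_point))
    if params.pat_mode == "phased":
        mode = params.phased_modes[rng.integers(0, len(params.phased_modes))]
        return max(1, int(round(rng.normal(mode, params.phased_sd))))
    return max(1, int(round(rng.normal(params.pat_mean, params.pat_sd))))


def simulate_molecules(
    db: TranscriptDB, params: SimParams, seed: int
) -> list[Molecule]:
    """Per-gene molecule counts from the log-normal/Poisson abundance model,
    with tail lengths drawn from the configured initial tail model."""
    rng = np.random.default_rng(seed)
    molecules: list[Molecule] = []
    counter = 0
    for tx in db:
        expected = rng.lognormal(math.log(params.abundance_mean_reads), params.abundance_sigma)
        count = int(rng.poisson(expected))
        for _ in range(count):
            counter += 1
            molecules.append(
                Molecule(
                    molecule_id=f"mol{counter:07d}",
                    transcript_id=tx.transcript_id,
                    gene_id=tx.gene_id,
                    pat_length=_draw_pat(params, rng),
                )
            )
    return molecules


def _removal_rate(length: int, params: SimParams) -> float:
    rate = params.base_deadenylation_rate
    if length < params.regime_switch_length:
        rate *= params.short_tail_multiplier
    if params.protection_factor > 1 and length % params.footprint_period < params.protected_edge_width:
        rate /= params.protection_factor
    return rate


def simulate_deadenylation(
    molecules: Sequence[Molecule],
    timepoints: Sequence[float],
    params: SimParams,
    seed: int,
) -> dict[float, list[Molecule]]:
    """Stochastic 3'-exonucleolytic shortening of each molecule's tail.

    Nucleotides are removed one at a time with exponential waiting times at
    a per-minute rate that is divided by ``protection_factor`` while the 3'
    end sits within ``protected_edge_width`` nt above a footprint boundary
    (footprints tiled every ``footprint_period`` nt), and multiplied by
    ``short_tail_multiplier`` once the tail is below
    ``regime_switch_length``. A molecule whose tail drops below 10 nt is
    destroyed with probability ``decay_prob`` (absent from later
    timepoints).
    """
    timepoints = [float(t) for t in timepoints]
    if not timepoints or timepoints[0] < 0:
        raise ValueError("timepoints must start at >= 0")
    if any(b <= a for a, b in zip(timepoints, timepoints[1:])):
        raise ValueError("timepoints must be strictly increasing")
    rng = np.random.default_rng(seed)
    out: dict[float, list[Molecule]] = {t: [] for t in timepoints}
    for mol in molecules:
        length = mol.pat_length
        tau = 0.0
        destroyed_at = math.inf
        trajectory: list[tuple[float, int]] = [(0.0, length)]
        t_max = timepoints[-1]
        while length > 0 and tau <= t_max and not math.isfinite(destroyed_at):
            rate = _removal_rate(length, params)
            tau += rng.exponential(1.0 / rate)
            if tau > t_max:
                break
            length -= 1
            trajectory.append((tau, length))
            if length == 9 and rng.random() < params.decay_prob:
                destroyed_at = tau
        for t in timepoints:
            if t >= destroyed_at:
                continue
            # tail length at time t = last trajectory entry not after t
            current = trajectory[0][1]
            for when, value in trajectory:
                if when > t:
                    break
                current = value
            if current > 0:
                out[t].append(replace(mol, pat_length=current))
    return out


def _inject_errors(
    seq: str, error_rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    if error_rate == 0:
        return seq, 0
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), int(len(hits))


def simulate_library(
    molecules: Sequence[Molecule],
    db: TranscriptDB,
    params: SimParams,
    seed: int,
    timepoint_min: Optional[float] = None,
    read_prefix: str = "read",
) -> tuple[list[CCSRead], list[TruthRecord]]:
    """Emit one CCS-style read per molecule with its truth record.

    Read layout (mRNA sense): fragment-side adapter, 3'-anchored transcript
    fragment of sampled length, poly(A) of the molecule's true length, then
    the splint adapter. Strand is flipped with probability 0.5 and
    substitutions injected at ``error_rate``.
    """
    rng = np.random.default_rng(seed)
    cfg = params.adapters
    reads: list[CCSRead] = []
    truths: list[TruthRecord] = []
    for i, mol in enumerate(molecules):
        tx = db[mol.transcript_id]
        frag_len = int(round(rng.normal(params.fragment_len_mean, params.fragment_len_sd)))
        frag_len = max(params.fragment_len_min, min(frag_len, len(tx.sequence)))
        fragment = tx.sequence[-frag_len:]
        sense = (
            cfg.fragment_adapter_seq
            + fragment
            + "A" * mol.pat_length
            + cfg.splint_adapter_seq
        )
        flipped = bool(rng.random() < 0.5)
        seq = revcomp(sense) if flipped else sense
        seq, n_errors = _inject_errors(seq, params.error_rate, rng)
        num_passes = int(rng.integers(3, 25))
        read_id = f"{read_prefix}{i + 1:07d}"
        reads.append(CCSRead(read_id=read_id, sequence=seq, num_passes=num_passes))
        truths.append(
            TruthRecord(
                read_id=read_id,
                gene_id=mol.gene_id,
                pat_length=mol.pat_length,
                timepoint_min=timepoint_min,
                n_errors=n_errors,
            )
        )
    return reads, truths
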