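from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from patseq import simulate
from patseq.cli import RunConfig
from patseq.io_model import TailRecord, Transcript, TranscriptDB


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def sim_params() -> simulate.SimParams:
    return simulate.SimParams(n_genes=10, abundance_mean_reads=30.0)


@pytest.fixture(scope="session")
def sim_db(sim_params) -> TranscriptDB:
    return simulate.simulate_transcriptome(sim_params, seed=11)


@pytest.fixture
def toy_db() -> TranscriptDB:
    rng = np.random.default_rng(7)
    bases = "ACGT"

    def seq(n, r):
        return "".join(bases[i] for i in r.integers(0, 4, size=n))

    return TranscriptDB(
        [
            Transcript("T1", seq(400, rng), "G1", "S1"),
            Transcript("T2", seq(400, rng), "G2", "S2"),
            Transcript("T3", seq(400, rng), "G3", "S3"),
        ]
    )


def make_record(
    read_id="r1",
    gene_id="G1",
    pat_length=50,
    transcript_id="T1",
    score=60.0,
    condition="",
    timepoint_min=None,
    n_disruptions=0,
) -> TailRecord:
    return TailRecord(
        read_id=read_id,
        transcript_id=transcript_id,
        gene_id=gene_id,
        pat_length=pat_length,
        n_disruptions=n_disruptions,
        orientation="forward",
        score=score,
        condition=condition,
        timepoint_min=timepoint_min,
    )
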