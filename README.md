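# patseq

Nucleotide-resolution poly(A)-tail (PAT) length calling from single-molecule
long reads, transcript assignment with acceptance filtering, tail-length
analytics (profiles, medians, gene-set averages, decile bins, Welch tests,
TPM, rank correlation), transcription-shutoff decay analytics (per-timepoint
profiles, half-life fitting, phasing peak detection), and a fully seeded
simulator that generates transcriptomes, tailed molecules, deadenylation
time courses and library-faithful reads with truth tables.

## How it works

Each read is oriented by locating the splint adapter (ungapped search, both
strands, configurable mismatch tolerance). The poly(A) tract is then
extracted leftward from the adapter junction at single-nucleotide
resolution: any number of single-base disruptions are tolerated provided
each non-A base is bracketed by at least two consecutive A bases on both
sides within the tract; two adjacent non-A bases end the tract. Disruption
bases count toward the reported length. The gene-derived fragment upstream
of the tract is assigned to a transcript by k-mer seeding, diagonal
chaining and banded local alignment scored as
`matches - mismatches - gap_opens`. Accepted records require a tail
strictly longer than 10 nt and an assignment score of at least 50;
optional pass-count and mitochondrial filters apply on top.

## Layout

- `src/patseq/io_model.py` — domain types; FASTA/FASTQ readers, transcript
  DB and GMT loaders, tail-table TSV round-trip
- `src/patseq/tail_caller.py` — adapter search, read orientation, tract
  extraction, duplicate-read QC
- `src/patseq/assigner.py` — k-mer index, fragment assignment, acceptance
  filters
- `src/patseq/profiles.py` — histograms/profiles, smoothing, medians,
  set averages, decile bins, Welch test, TPM, rank correlation
- `src/patseq/decay.py` — time-course profiles, binned time courses,
  half-life fit, peak detection, phasing period
- `src/patseq/simulate.py` — synthetic transcriptome/molecules/
  deadenylation/library generators with truth records
- `src/patseq/cli.py` — `patseq` command group wiring the stages

## CLI

```sh
# generate a synthetic data set (optionally a decay time course)
patseq simulate -o run/sim --seed 1 --timepoints 0,120,240

# call tails and assign transcripts
patseq call -r run/sim/reads.fasta -t run/sim/transcripts.fasta -o run/call

# profiles, per-gene medians, gene-set averages, pairwise Welch tests
patseq profile --table wt=run/call/tail_table.tsv --gene-sets sets.gmt -o run/prof

# decay analytics from a manifest (record mode: condition, timepoint_min,
# table_path; signal mode: condition, timepoint_min, signal)
patseq decay --manifest manifest.tsv -o run/decay
```

Every command echoes its effective configuration (`config.yaml`) into the
output directory and is byte-for-byte reproducible given the same inputs,
config and seed. Thresholds (min tail length, min score, smoothing window,
bin count, adapter sequences, mitochondrial denylist, ...) live in a YAML
config passed via `--config`.

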