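# tdnascope

Reconstruction of transgene (T-DNA) integration architectures from long
reads: tandem multi-fragment concatemers, chromosomal translocations,
truncations, and depth-based loss calls — together with a rearranged-genome
simulator so that every stage can be verified against a machine-readable
truth set.

## What it does

- **`tdnascope.simulate`** — builds random references and a vector stand-in,
  plants integration architectures (intact border-to-border insertions,
  one-ended truncations, vector-bridged and bare translocations, deletions)
  on a diploid genome, realizing junction repair signatures exactly
  (micro-homology, filler DNA, long homology), and emits a `TruthSet`.
- **`tdnascope.presets`** — a bundled benchmark architecture with two
  concatemer bridges (four and six fragments, tract lengths 11,279 and
  15,200 bp), 22-bp/3-bp fillers, a 254-bp homology pair, and 4–7 bp
  micro-homologies.
- **`tdnascope.reads`** — deterministic long-read simulation (log-normal
  lengths, per-base substitution/indel errors) with a per-read origin log.
- **`tdnascope.align`** — local alignment: exact affine Smith–Waterman
  (via Biopython) for small problems, a vectorized seed–chain–extend engine
  at read scale; PAF/SAM ingestion and PAF output.
- **`tdnascope.segment`** — selects vector-containing reads and tiles each
  read into an ordered walk of vector/genome segments.
- **`tdnascope.junctions`** — clusters per-read breakpoints into supported
  junctions, reconstructs concatemer architectures by context-aware walking
  along supporting reads, builds the chromosome fragment graph, and
  classifies integration events (intact insertion / truncation /
  translocation / bare translocation).
- **`tdnascope.signature`** — classifies each junction's repair signature
  from a read consensus (blunt, micro-homology, filler, long homology).
- **`tdnascope.depth`** — binned depth profiles and mutant/control
  depth-ratio loss calls (heterozygous ≈ 0.5×, homozygous ≈ 0×).
- **`tdnascope.pipeline`** — end-to-end orchestration with on-disk
  intermediates, a JSON + text report, and truth-set scoring.

## CLI

```sh
# simulate the bundled benchmark (reference, vector, haplotypes, reads,
# control reads, truth set)
tdna-scope simulate --preset yl-replica --out sim/ --seed 1

# run the full analysis
tdna-scope run --reads sim/reads.fastq --reference sim/reference.fasta \
    --vector sim/vector.fasta --control-reads sim/control.fastq --out out/

# score the report against the planted truth
tdna-scope score --report out/report.json --truth sim/truth.json
```

`tdna-scope run --config config.yaml` accepts a YAML config exposing every
module threshold. `tdna-scope align` and `tdna-scope segment` run single
stages on files; pre-computed PAF/SAM alignments can be supplied via the
config (`alignments:` / `alignments_format:`).

## Conventions

- Internal coordinates are 0-based half-open; reports print 1-based
  inclusive coordinates alongside.
- Vector fragments are written in 1-based inclusive coordinates with
  `start > end` encoding reverse orientation; tract length is
  `sum(|end - start|)` over fragments.
- Alignment scoring is fixed: match +2, mismatch −4, gap of length *g*
  −(4 + 2·*g*).
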