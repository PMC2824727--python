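# bacomap

Comparative BAC-mapping toolkit: BAC-end-sequence (BES) mate-pair
anchoring against a reference genome, conserved-synteny map
construction, BAC-library statistics, exact multichromosomal genome
rearrangement distance, and a synthetic rearranged-genome simulator
that makes every stage testable with known ground truth.

## Modules

| module | what it does |
|---|---|
| `bacomap.simulate` | ancestor marker grids, random inversion/translocation/fusion/fission histories with an exactly replayable event log, BAC clone sampling (truncated-normal inserts), BLAST-tabular mate-pair alignments with unmapped/multi-map noise, BES FASTA, Poisson probe-screening tables, FISH-style marker tables |
| `bacomap.anchor` | BLAST outfmt-6 parsing, 0/1/>1 mappability classes, mate-driven rescue of multi-mapped ends, per-clone concordant/discordant calls (indel / inversion / translocation / large-or-complex) |
| `bacomap.libstats` | fold coverage (nL/G), locus-recovery probability (1 − e^−c), observed screening depth with clone exclusion, GC content, size-weighted chromosome-distribution chi-square (male X/Y correction) |
| `bacomap.syntenymap` | marker-table loading with deterministic tie rule, conserved-synteny blocks, chromosome correspondence, condensation to signed segments, GRIMM genome-text I/O |
| `bacomap.rearrange` | exact minimum rearrangement distance (reversals + translocations + fusions + fissions) via IDA* with a DCJ lower bound, an independent BFS oracle, deterministic parsimonious sorting scenarios, ambiguous-sign optimization |
| `bacomap.pipeline` / `bacomap.cli` | strict YAML config validation and the staged simulate → anchor → stats → synteny → distance run with a consolidated JSON report |

## CLI

```sh
# synthetic dataset with 3 rearrangement events and full ground truth
bacomap simulate --seed 7 --n-events 3 --outdir out/sim

# classify mate pairs
bacomap anchor --alignments out/sim/alignments.tsv --out out/calls.tsv

# library statistics
bacomap stats --n-clones 194267 --mean-insert 139000 --genome-size 2.8e9 \
    --fasta out/sim/bes.fasta

# synteny blocks + GRIMM-format genomes from a marker table
bacomap synteny --markers out/sim/markers.tsv --outdir out/syn

# exact rearrangement distance and one optimal scenario
bacomap distance --genomes out/syn/genomes.grimm.txt --scenario

# everything at once from a config
bacomap run --config config.yaml --outdir out/run
```

A minimal config:

```yaml
mode: synthetic
seed: 7
n_events: 3
sim:
  n_chromosomes: 5
  chrom_lengths: [240000000, 240000000, 240000000, 240000000, 240000000]
  n_clones: 200
thresholds:
  concordant_min: 90000
  concordant_max: 200000
```

Unknown config keys are rejected, and two runs with the same config and
seed produce byte-identical artifacts.

## File formats

- **BLAST tabular**: 12 columns (`qseqid sseqid pident length mismatch
  gapopen qstart qend sstart send evalue bitscore`), subject coordinates
  1-based inclusive, minus strand encoded by `sstart > send`; read ids
  are `{clone}_{T7|SP6}`.
- **Marker TSV**: `clone_id, query_chrom, query_rank, target_chrom,
  target_pos`; ranks are cytogenetic (ties allowed, no orientation).
- **GRIMM genome text**: `>name` header, then one line of signed
  integers per chromosome terminated by `$`.
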