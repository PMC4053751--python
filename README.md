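# haplasm

Haploid-guided whole-genome shotgun assembly at desk scale.

Very large conifer genomes have been assembled by exploiting a quirk of
gymnosperm seeds: the megagametophyte tissue is haploid and derived from a
single meiotic product, so reads sequenced from it carry exactly one
haplotype. A k-mer database built from those haploid reads becomes an oracle
for the rest of the project — it corrects sequencing errors, filters out
reads from the divergent second haplotype in diploid libraries, and collapses
error-corrected read pairs into a drastically smaller set of *super-reads*
that an overlap-layout-consensus assembler can handle. `haplasm`
re-implements that strategy end to end at a scale that runs on a laptop, with
a synthetic-data module that generates diploid genomes, organelles, planted
repeats and reads with complete ground truth, so that every stage can be
tested against an exact oracle.

The package covers:

- **`haplasm.synth`** — synthetic diploid genomes (SNPs/indels, clustered or
  uniform), organelle sequences at elevated copy number and distinct GC,
  planted tandem/interspersed/telomere/centromere repeats, and simulated
  paired-end / mate-pair / ditag reads with full per-read provenance.
- **`haplasm.kmers`** — canonical k-mer counting, solid-threshold selection
  from the count histogram, single-base error correction, and
  haploid-spectrum filtering of diploid reads.
- **`haplasm.superreads`** — unique-extension graph, read extension, and
  reduction of read pairs into containment-free super-reads with provenance.
- **`haplasm.olc`** — exact suffix–prefix overlap detection on both strands,
  conservative unitigging into contigs, mate-pair scaffolding with link
  bundling and gap estimation, and transcript-evidence scaffolding.
- **`haplasm.organelle`** — per-scaffold GC/depth/alignment profiling,
  rule-based binning into nuclear / mitochondrial / chloroplast / ambiguous,
  and iterative read-pair recruitment and reassembly of the mitochondrial bin.
- **`haplasm.qc`** — N50 and assembly statistics, a seeded banded aligner,
  validation against independent long contigs, transcript classification at
  identity/coverage thresholds, and a core-gene completeness scan.
- **`haplasm.repeats`** — deterministic tandem-repeat scanning (unit sizes
  1–100 by default), multimer/overlap filtering, telomere- and
  centromere-motif array counting, library-based masking, and a
  repeat-landscape summary.

## Quick start (Python API)

Simulate a 50 kbp haploid read set with sequencing errors and run the whole
pipeline — correction, super-read reduction, overlap assembly:

```python
import json
import haplasm as H

truth = H.gen_diploid_genome(50_000, seed=7)
reads = H.sim_reads(truth, "paired_end", depth=40, read_len=100,
                    insert_mean=300, insert_sd=25, error_rate=0.002,
                    source="haploid", seed=7)
result = H.haploid_assemble(reads, k=21)

print("corrected reads:   ", result.correction_tally)
print("super-reads:       ", len(result.super_reads))
print("reduction factor:  ", round(result.reduction.reduction_factor, 1))
print("contigs:           ", len(result.contigs))
print(json.dumps(H.assembly_stats(result.contigs).to_dict(), indent=2))
```

Output:

```
corrected reads:    {'solid': 16434, 'corrected': 3551, 'uncorrectable': 15, 'too_short': 0}
super-reads:        1
reduction factor:   19970.0
contigs:            1
{
  "n_contigs": 1,
  "n_scaffolds": 1,
  "contig_n50": 50000,
  "scaffold_n50": 50000,
  "total_contig_bp": 50000,
  "total_scaffold_span": 50000,
  "gc_fraction": 0.382
}
```

20,000 reads collapse into a single super-read that *is* the genome: with
solid-k-mer error correction and unique extension, an error-free repeat-free
region reconstructs exactly.

## Quick start (CLI)

The same pipeline as shell commands; every subcommand prints a small JSON
report to stdout:

```console
$ haplasm simulate --length 20000 --depth 30 --seed 5 --error-rate 0.002 --outdir sim
{ "length": 20000, "n_reads": 6000, "source": "haploid" }
$ haplasm kmerdb sim/reads.fastq -k 21 --out db.tsv
{ "k": 21, "distinct_kmers": 39215, "solid_threshold": 4 }
$ haplasm correct sim/reads.fastq db.tsv --out corrected.fastq
{ "solid": 4913, "corrected": 1084, "uncorrectable": 3, "too_short": 0 }
$ haplasm assemble corrected.fastq -k 21 --outdir asm
{ "n_super_reads": 1, "reduction_factor": 5994.0, "n_contigs": 1, ... }
$ haplasm validate asm/contigs.fasta sim/haplotype_A.fasta --min-len 15000
{ "covered_fraction": 1.0, "n_high_similarity": 1, "implied_error_rate": 0.0, ... }
```

Further subcommands: `filter` (haploid-spectrum filtering of diploid reads),
`scaffold` (mate-pair scaffolding), `stats`, `classify-transcripts`,
`core-scan`, `organelle` (profiling + binning + recruitment), and `repeats`
(tandem/motif landscape). `haplasm --help` lists them all.

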