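# Methods

This note describes the model behind each stage of `haplasm`, the default
parameters and the reasoning behind them, the scope of the synthetic-data
generator, and known limitations. Problem sizes quoted here (tens of kbp to
1 Mbp genomes) are the package's own choice: large enough that every
statistical signal the pipeline relies on (k-mer histogram bimodality,
mate-pair link bundles, depth contrast) is present, small enough that the
full test suite runs in minutes on one CPU.

## 1. Synthetic data (`haplasm.synth`)

`gen_diploid_genome` draws haplotype A as i.i.d. bases at a target GC
(default 0.382, a typical conifer nuclear value), then derives haplotype B by
applying SNPs and short (≤ 5 bp) indels at per-base rates, optionally
confined to listed regions to model clustered haplotype divergence. The
variant list is stored so that B is exactly re-derivable from A — every
downstream claim about haplotype identity has a ground-truth oracle.

Repeat families are planted into A at randomly chosen, mutually separated
positions. Two generator details matter for exact-span recovery of perfect
tandem arrays:

- **Flank periodicity breaking.** After planting a perfect array, the three
  bases immediately outside each end are forced to break the array's period.
  The scanner bridges interruptions of up to 2 bp, so without this a chance
  flank match would legitimately extend the detected span past the planted
  interval.
- **Separation margin.** Planted loci keep a 130 bp margin from each other —
  more than the largest scanned unit (100 bp) — so two copies of the same
  element cannot create a spurious cross-locus periodicity.

Organelle sequences are generated at their own GC targets (mitochondrial
0.44, chloroplast 0.395 by default) and carry a copy number; read simulation
with `source="mixed_with_organelle"` samples templates proportionally to
copy number, reproducing the depth contrast the binner exploits.

`sim_reads` samples insert positions uniformly with clamping at the template
ends (so coverage is flat to the very first base), orients pairs innie for
paired-end and outie for mate-pair/ditag libraries, applies i.i.d.
substitution errors, and records per-read provenance
(template, start, end, strand). All randomness flows from
`numpy.random.default_rng([seed, stream])` child streams, so outputs are
bit-reproducible and adding one stage never perturbs another.

## 2. k-mer database, correction, filtering (`haplasm.kmers`)

K-mers are counted canonically (lexicographic min of a k-mer and its reverse
complement); k must be odd so no k-mer equals its own reverse complement.
The library default is k = 79 — long enough that a random genome of desk
scale contains essentially no repeated k-mers; the pipeline and tests use
k = 21, which has the same uniqueness property at 10⁴–10⁶ bp and keeps the
error-free coverage per k-mer high at moderate read depth.

`suggest_solid_threshold` exploits the bimodal count histogram of a deep read
set: an error peak at count ≈ 1 and a coverage peak near the depth. The
valley between them is the threshold; counts strictly above it are *solid*.
With shallow data (no coverage peak) it falls back to 2.

`error_correct` scans a read for non-solid k-mers and tries single-base
substitutions that make every window covering the base solid, up to
`max_corrections = 3` per read — the expected error count of a 100 bp read
at ~1% error with headroom; reads needing more are flagged uncorrectable.

`filter_diploid_reads` keeps a read when ≥ 90% of its k-mers are solid in
the haploid database (`min_fraction = 0.9`). Membership is defined as
*solid*, not merely present: with an error-containing haploid read set, raw
presence would let singleton error k-mers rescue divergent reads. The 0.9
fraction tolerates an isolated sequencing error (one error kills ≤ k of the
~80 windows of a 100 bp read) while a single haplotype SNP in mid-read kills
k = 21 consecutive windows and drags the fraction well below 0.9. Pairs are
kept jointly — one divergent mate removes both — because downstream
super-read construction consumes pairs.

## 3. Super-reads (`haplasm.superreads`)

The extension graph maps each solid (k−1)-mer to the set of solid bases that
can follow (and precede) it. A read is extended outward while the extension
is *unique*; by construction the extension of every read reaching the same
maximal sequence is identical, so reads collapse onto a small set of
canonical extended strings. A pair whose two mates land on the same extended
string is *resolved* and recorded in that super-read's provenance. Extended
strings contained in another string (either strand) are removed, so the
final set is containment-free — this is checked brute-force in the tests.
The reduction report counts input reads per output super-read; on clean data
at depth ≥ 40 the factor is in the thousands.

## 4. Overlap-layout-consensus and scaffolding (`haplasm.olc`)

Overlaps are exact suffix–prefix matches of length ≥ `min_overlap`
(default 2k−1: long enough that a chance exact overlap is vanishingly
unlikely, short enough that adjacent super-reads sharing a (k−1)-mer seam
plus context still overlap) over all four strand combinations, deduplicated
to one record per unordered junction. Unitigging is conservative: two
super-reads join only when each is the other's unique best partner at the
facing ends; cycles are broken with a union-find check. Contigs are emitted
on a canonical strand with their layout retained, so
`Contig.reconstruct(super_reads)` reproduces the sequence exactly.

Mate-pair scaffolding places each mate by unique exact 31-mers on contig
ends, normalizes innie/outie geometry, and bundles links per ordered
contig-end pair. A join needs `min_links = 3` concordant pairs — one chance
mis-mapping cannot create a join, and at the depths used genuine adjacent
contigs receive far more. The gap is the median over links of
(insert mean − observed flank distances), floored at 1 bp; contradictory
joins cancel. Transcript scaffolding uses the same end-walker with
`min_links = 1`, because a single transcript spanning two contig ends at
0.98 identity / 0.95 coverage is strong evidence by itself.

## 5. Organelle binning (`haplasm.organelle`)

Each scaffold gets a profile: length, GC, mean read depth (by unique 31-mer
placement), and an alignment class against mitochondrial/chloroplast
reference panels (a panel hit = identity ≥ 0.9 over ≥ min(500 bp, 90% of
the scaffold)). Classification rules, in order: panel-exclusive hits win;
both-panel hits are chloroplast when depth > 100 and otherwise ambiguous;
unaligned scaffolds are mitochondrial when length ≥ 1 kb, GC ≥ 0.44 and
depth in [8, 50]; everything else is nuclear. The GC/depth window is the
fallback for mitochondrial sequence absent from the panel — mitochondrial GC
runs well above nuclear, and organellar copy number puts its depth in a band
nuclear single-copy sequence (≈ 1×) and chloroplast (> 100×) both miss.

`recruit_and_reassemble` iterates: recruit read pairs with a mate placed on
the current bin, reassemble the recruited reads, rescaffold, and stop when
(scaffold count, total span, N50) repeats or `max_rounds` is hit. Each round
can extend an end by roughly one library insert length, so gaps wider than a
few inserts need proportionally many rounds. Total span is kept monotone: a
round whose reassembly shrinks the span is discarded and iteration stops.

## 6. QC (`haplasm.qc`)

`seeded_align` is a seed-and-extend aligner: exact 15-mer seeds (15 keeps the
chance hit rate in a 10⁵ bp target below one per query) are clustered by
diagonal band (width 50) and target proximity; each cluster's query window,
padded by the band, is aligned to the corresponding target window by edit
distance (edlib, infix mode); the best local segment of the resulting cigar
is selected by Kadane's algorithm with +1 per match and −2 per error column,
then greedily extended outward over exactly matching flanking bases (edit
paths are not unique, and a co-optimal path can park boundary bases as
flanking indels — the extension reclaims them). Overlapping hits on the same
target keep only the best.

On top of it: `validate_against` aligns independent contigs ≥ 20 kb and
reports covered fraction, the count at ≥ 0.995 best-hit identity, and the
implied error rate (1 − length-weighted mean identity);
`classify_transcripts` counts unique/multi/unaligned placements at
(identity 0.98, coverage 0.95) for de novo transcripts and (0.98, 0.98) for
curated ESTs; `core_gene_scan` labels core genes full-length at ≥ 0.95
coverage. `n50` is the standard weighted median and is tested against its
brute-force definition.

## 7. Repeat landscape (`haplasm.repeats`)

For every period d in [min_unit, max_unit] (defaults 1–100), the scanner
computes the boolean profile `seq[i] == seq[i+d]` (vectorized for d ≤ 12;
seeded by spaced 12-mer recurrences for 13 ≤ d ≤ 100), extracts maximal runs
with purity ≥ `min_purity` (default 0.8) bridging interruptions ≤ 2 bp, and
refines each candidate: build the per-position consensus unit, trim terminal
mismatching columns, and fall back to the best-scoring sub-segment when the
whole window misses the purity floor. A candidate whose consensus unit is
itself periodic with a smaller scanned period is rejected — the smaller
period's scan reports that locus at its exact span, and without the
rejection an AT array would also surface at periods 4, 6, 8… with chance
flank extensions. Units are reported as their lexicographically minimal
rotation; loci are classified microsatellite (unit 1–9), minisatellite
(10–100), satellite (> 100). `filter_multimeric` drops loci nested inside
another locus and flags loci mostly covered by an interspersed-repeat mask;
flagged loci are excluded from tandem coverage.

Motif arrays (telomeric `TTTAGGG`, a 27 bp centromeric candidate) are counted
separately by exact/rotated motif matching on both strands with a divergence
allowance, since motif identity — not just periodicity — is the claim of
interest. `summarize` reports per-unit-size locus densities per Mbp, mean
array lengths, class totals, motif totals and tandem coverage; mononucleotide
runs can be excluded to match cross-species microsatellite conventions.

## Numerical choices

- All integer spans are 0-based half-open; strands are `+`/`-`; reverse
  complement mapping of a span [s, e) on length L is [L−e, L−s).
- Purity is matching columns / total columns of the refined array; copy
  number is span / unit length and may be fractional.
- Randomness: `numpy` `default_rng` with `[seed, stream]` keys; no global
  state. Identical inputs and seed give byte-identical outputs everywhere.
- Alignment scoring inside `seeded_align` (+1 match, −2 error) makes a
  segment worth keeping only when it is > 2/3 matches locally, which at the
  identity thresholds used (≥ 0.9) never truncates a genuine hit.

## Limitations

- The tandem scanner's degenerate path (purity < 1) bridges interruptions
  greedily left-to-right; the reported span of an *imperfect* array is not
  guaranteed to be identical on the reverse complement. Perfect-array spans
  and the landscape summary are strand-invariant, and this is what the
  acceptance suite asserts.
- Overlap detection is exact-match only; the assembler therefore requires
  error correction to have succeeded (uncorrectable reads are dropped by
  default). This matches the design — correction precedes assembly — but
  means residual errors fragment contigs rather than producing consensus
  disagreements.
- `sim_reads` models substitution errors only; indel sequencing errors are
  out of scope (the corrector is substitution-based).
- Interspersed-repeat *discovery* is out of scope; `mask_by_library` masks
  against a provided library only.
- The organelle GC/depth window assumes the mitochondrial-vs-nuclear GC and
  depth contrasts hold; a nuclear region of organellar GC at elevated
  apparent depth (e.g. a collapsed repeat) would be mis-binned, which is why
  panel alignment takes precedence whenever a panel covers the sequence.
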