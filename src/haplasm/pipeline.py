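"""End-to-end haploid assembly convenience wrapper.

Runs the canonical stage order: k-mer counting on the haploid pool with a
histogram-derived solid threshold, spectrum error correction, solid-k-mer
extension graph, super-read reduction, and overlap-layout-consensus
assembly.  Scaffolding is left to the caller because it needs a linking
library.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kmers import KmerDB, correct_readset, count_kmers, subset_readset, suggest_solid_threshold
from .olc import Contig, assemble
from .superreads import ReductionReport, SuperRead, build_extension_graph, join_and_reduce
from .synth import ReadSet


@dataclass
class AssemblyResult:
    contigs: list[Contig]
    super_reads: list[SuperRead]
    reduction: ReductionReport
    db: KmerDB
    correction_tally: dict


def haploid_assemble(
    reads: ReadSet,
    k: int = 21,
    min_overlap: int | None = None,
    max_corrections: int = 3,
    drop_uncorrectable: bool = True,
) -> AssemblyResult:
    """Correct, reduce and assemble a haploid paired-end read set.

    ``min_overlap`` defaults to 2k−1.  Reads the corrector flags
    uncorrectable are dropped before super-read construction by default:
    their residual errors cannot seed super-reads (their k-mers are not
    solid) and they would otherwise linger as junk singletons.
    """
    min_overlap = min_overlap or (2 * k - 1)
    db = count_kmers(reads, k)
    db.solid_threshold = suggest_solid_threshold(db)
    corrected, tally, statuses = correct_readset(reads, db, max_corrections)
    if drop_uncorrectable and (tally["uncorrectable"] or tally["too_short"]):
        good_set = {rid for rid, st in statuses.items() if st in ("solid", "corrected")}
        good = [r.id for r in corrected.reads
                if r.id in good_set and (r.mate_id is None or r.mate_id in good_set)]
        corrected = subset_readset(corrected, good)
    graph = build_extension_graph(corrected, k, db)
    supers, report = join_and_reduce(corrected, graph)
    contigs = assemble(supers, min_overlap)
    return AssemblyResult(contigs, supers, report, db, tally)
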