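"""Organelle scaffold binning and iterative mitochondrial reassembly.

Mitochondrial sequence in a whole-genome shotgun pool stands out three ways:
it aligns to known plant mitochondria, its read depth is elevated (organelle
copy number per cell far exceeds the nuclear genome's), and its GC content is
higher than the nuclear background.  Chloroplast sequence is deeper still.
The classifier mirrors that evidence: panel-exclusive alignment wins
outright; otherwise an unaligned scaffold of sufficient length is called
mitochondrial when its GC and depth fall inside the mitochondrial window.
The recruit-and-reassemble loop then pulls in every read pair with a mate on
the current mitochondrial set and reassembles until the assembly stops
improving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._seq import gc_fraction
from .kmers import subset_readset
from .olc import SeqIndex, scaffold as scaffold_contigs
from .pipeline import haploid_assemble
from .qc import n50, seeded_align
from .synth import ReadSet

logger = logging.getLogger("haplasm.organelle")


@dataclass
class ScaffoldProfile:
    scaffold_id: str
    length: int
    gc: float
    depth: float
    align_class: str  # mito_exclusive | chloro_exclusive | both | none


@dataclass
class BinDecision:
    scaffold_id: str
    label: str  # mitochondrial | chloroplast | nuclear | ambiguous
    reason: str


def _panel_hit(seq: str, panel: dict[str, str], min_identity: float, min_span: int) -> bool:
    if not panel:
        return False
    hits = seeded_align(seq, panel)
    return any(
        h.identity >= min_identity and h.aligned_query_bp >= min(min_span, int(0.9 * len(seq)))
        for h in hits
    )


def profile_scaffolds(
    scaffolds: dict[str, str] | list[tuple[str, str]],
    reads: ReadSet,
    mito_panel: dict[str, str],
    chloro_panel: dict[str, str],
    min_panel_identity: float = 0.9,
    min_panel_span: int = 500,
    seed_len: int = 31,
) -> list[ScaffoldProfile]:
    """Per-scaffold GC, mean mapped-read depth, and organelle panel class.

    Depth is total mapped read bases / scaffold length, from the same read
    subset later used for reassembly.  A scaffold is panel-exclusive when it
    has a qualifying alignment (identity >= 0.9 over >= 500 bp, or 90% of a
    shorter scaffold) to exactly one of the two panels.
    """
    if isinstance(scaffolds, list):
        scaffolds = dict(scaffolds)
    index = SeqIndex(scaffolds, seed_len)
    mapped_bp = {name: 0 for name in scaffolds}
    for r in reads.reads:
        hit = index.place(r.sequence)
        if hit is not None:
            mapped_bp[hit[0]] += len(r.sequence)
    profiles = []
    for name, seq in scaffolds.items():
        mito = _panel_hit(seq, mito_panel, min_panel_identity, min_panel_span)
        chloro = _panel_hit(seq, chloro_panel, min_panel_identity, min_panel_span)
        align_class = (
            "both" if mito and chloro
            else "mito_exclusive" if mito
            else "chloro_exclusive" if chloro
            else "none"
        )
        profiles.append(
            ScaffoldProfile(name, len(seq), gc_fraction(seq), mapped_bp[name] / len(seq), align_class)
        )
    return profiles


def classify(
    profile: ScaffoldProfile,
    gc_min: float = 0.44,
    depth_min: float = 8.0,
    depth_max: float = 50.0,
    chloro_depth_min: float = 100.0,
    min_len: int = 1000,
) -> BinDecision:
    """Label one scaffold mitochondrial / chloroplast / nuclear / ambiguous.

    Defaults are the production thresholds: mitochondrial when panel-exclusive
    or when unaligned with length >= 1 kb, GC >= 44% and depth in [8, 50];
    chloroplast when chloroplast-exclusive or chloroplast-aligned at depth
    > 100; both-panel alignment is ambiguous; everything else nuclear.
    """
    if not (0 < depth_min < depth_max < chloro_depth_min):
        raise ValueError("need 0 < depth_min < depth_max < chloro_depth_min")
    p = profile
    if p.align_class == "both":
        if p.depth > chloro_depth_min:
            return BinDecision(
                p.scaffold_id, "chloroplast",
                f"aligned to both panels, depth > {chloro_depth_min}",
            )
        return BinDecision(p.scaffold_id, "ambiguous", "aligned to both organelle panels")
    if p.align_class == "mito_exclusive":
        return BinDecision(p.scaffold_id, "mitochondrial", "mito-exclusive panel alignment")
    if p.align_class == "chloro_exclusive":
        return BinDecision(p.scaffold_id, "chloroplast", "chloro-exclusive panel alignment")
    if p.length >= min_len and p.gc >= gc_min and depth_min <= p.depth <= depth_max:
        return BinDecision(
            p.scaffold_id,
            "mitochondrial",
            f"unaligned, len>={min_len}, GC>={gc_min}, depth in [{depth_min},{depth_max}]",
        )
    return BinDecision(p.scaffold_id, "nuclear", "no organelle evidence")


def classify_all(profiles: list[ScaffoldProfile], **thresholds) -> list[BinDecision]:
    """Classify every profile (a total function; order-independent)."""
    return [classify(p, **thresholds) for p in profiles]


def recruit_and_reassemble(
    binned_scaffolds: dict[str, str] | list[tuple[str, str]],
    reads: ReadSet,
    max_rounds: int = 5,
    k: int = 21,
    min_overlap: int | None = None,
    min_links: int = 3,
    linking_reads: ReadSet | None = None,
    seed_len: int = 31,
) -> tuple[list, list[dict]]:
    """Iteratively recruit read pairs matching the mitochondrial set and
    reassemble until (scaffold count, total span, N50) stop changing or
    ``max_rounds`` is hit.

    Each round: place reads on the current mitochondrial sequences; recruit
    every pair with at least one mapped mate; correct, build super-reads,
    OLC-assemble and rescaffold.  Total span is monotone: a round whose
    reassembly shrinks the span is discarded and iteration stops.
    Returns (final scaffolds, per-round log).
    """
    if isinstance(binned_scaffolds, list):
        binned_scaffolds = dict(binned_scaffolds)
    if not binned_scaffolds:
        raise ValueError(
            "empty mitochondrial bin: no scaffold passed classify() thresholds "
            "(panel alignment, or GC/depth/length window)"
        )
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    min_overlap = min_overlap or (2 * k - 1)

    current: dict[str, str] = dict(binned_scaffolds)
    current_scaffolds: list = []
    log: list[dict] = []
    prev_metrics = None
    for rnd in range(1, max_rounds + 1):
        index = SeqIndex(current, seed_len)
        recruited_ids: list[str] = []
        for r1, r2 in reads.pairs():
            if index.place(r1.sequence) is not None or index.place(r2.sequence) is not None:
                recruited_ids.extend((r1.id, r2.id))
        if not recruited_ids:
            logger.info("round %d: no pairs recruited; stopping", rnd)
            break
        sub = subset_readset(reads, recruited_ids)
        result = haploid_assemble(sub, k=k, min_overlap=min_overlap)
        contigs = result.contigs
        links = linking_reads if linking_reads is not None else sub
        scaffolds = scaffold_contigs(contigs, links, min_links=min_links)
        span = sum(s.span for s in scaffolds)
        metrics = (len(scaffolds), span, n50([s.span for s in scaffolds]) if scaffolds else 0)
        entry = {
            "round": rnd,
            "n_recruited_pairs": len(recruited_ids) // 2,
            "n_scaffolds": metrics[0],
            "total_span": metrics[1],
            "n50": metrics[2],
        }
        if prev_metrics is not None and span < prev_metrics[1]:
            entry["discarded"] = True
            log.append(entry)
            logger.info("round %d shrank the assembly; keeping previous round", rnd)
            break
        log.append(entry)
        current_scaffolds = scaffolds
        current = {s.id: s.sequence for s in scaffolds}
        if metrics == prev_metrics:
            break
        prev_metrics = metrics
    return current_scaffolds, log
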