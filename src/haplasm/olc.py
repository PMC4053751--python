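"""Overlap-layout-consensus assembly of super-reads and scaffolding.

The overlap stage finds exact suffix-prefix overlaps (both strands) between
containment-free super-reads; the layout stage merges unambiguous overlap
chains conservatively (a branch splits the chain), which is a unitig-style
policy appropriate for corrected haploid input where the only sources of
ambiguity are genuine repeats.  Scaffolding bundles mate-pair/long-insert
links between contigs, estimates gaps from the library insert size, and joins
contig ends supported by at least ``min_links`` concordant pairs; transcript
alignments can add further joins between scaffold ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median

from ._seq import canonical, revcomp
from .synth import ReadSet

logger = logging.getLogger("haplasm.olc")


# ---------------------------------------------------------------------------
# overlaps


@dataclass(frozen=True)
class Overlap:
    """Exact suffix-prefix overlap: the last ``length`` bases of oriented a
    equal the first ``length`` bases of oriented b.  orientation is a two
    letter code over {F, R} for (a, b)."""

    a_id: str
    b_id: str
    length: int
    orientation: str


def find_overlaps(super_reads: dict[str, str], min_overlap: int) -> list[Overlap]:
    """All maximal exact suffix-prefix overlaps >= min_overlap, both strands.

    Complete and symmetric: if a(F) overlaps b(F) then b(R) overlaps a(R).
    Self-overlaps are not reported.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seqs = {(i, "F"): s for i, s in super_reads.items()}
    seqs.update({(i, "R"): revcomp(s) for i, s in super_reads.items()})

    # index of each oriented prefix seed of length min_overlap
    prefix_index: dict[str, list[tuple[str, str]]] = {}
    for (i, o), s in seqs.items():
        if len(s) >= min_overlap:
            prefix_index.setdefault(s[:min_overlap], []).append((i, o))

    out: list[Overlap] = []
    for (a, oa), sa in seqs.items():
        if len(sa) < min_overlap:
            continue
        # candidate partners: every occurrence of some prefix seed within sa's suffix
        seen: dict[tuple[str, str], int] = {}
        for p in range(len(sa) - min_overlap, -1, -1):
            seed = sa[p : p + min_overlap]
            for b, ob in prefix_index.get(seed, ()):
                if b == a:
                    continue
                ov = len(sa) - p
                sb = seqs[(b, ob)]
                if ov <= len(sb) and sa[p:] == sb[:ov]:
                    key = (b, ob)
                    if ov > seen.get(key, 0):
                        seen[key] = ov
        for (b, ob), ov in seen.items():
            out.append(Overlap(a, b, ov, oa + ob))
    return sorted(out, key=lambda o: (o.a_id, o.b_id, o.orientation))


# ---------------------------------------------------------------------------
# layout and consensus


@dataclass
class Contig:
    id: str
    sequence: str
    layout: list[tuple[str, int, str]]  # (super_read_id, offset, strand)

    def __len__(self) -> int:
        return len(self.sequence)

    def reconstruct(self, super_reads: dict[str, str]) -> str:
        """Rebuild the consensus from the layout; must equal ``sequence``."""
        buf = bytearray(b"?" * len(self.sequence))
        for sr_id, off, strand in self.layout:
            s = super_reads[sr_id]
            if strand == "-":
                s = revcomp(s)
            buf[off : off + len(s)] = s.encode()
        return buf.decode()


def _junctions(overlaps: list[Overlap]):
    """Collapse mirror overlaps into undirected junctions between node ends.

    A junction is ((a, end_a), (b, end_b), flip, length); end is 'L'/'R' in
    each node's forward coordinates; flip says the two nodes run on opposite
    strands across the junction."""
    seen = {}
    for ov in overlaps:
        oa, ob = ov.orientation
        end_a = "R" if oa == "F" else "L"
        end_b = "L" if ob == "F" else "R"
        key = tuple(sorted(((ov.a_id, end_a), (ov.b_id, end_b))))
        flip = oa != ob
        prev = seen.get(key)
        if prev is None or ov.length > prev[2]:
            seen[key] = ((ov.a_id, end_a), (ov.b_id, end_b), ov.length, flip)
    return list(seen.values())


def layout_and_consensus(
    super_reads: dict[str, str], overlaps: list[Overlap]
) -> list[Contig]:
    """Merge non-branching overlap chains into contigs (conservative
    unitigging): a junction is used only when both participating node ends
    have exactly one overlap partner.  Cyclic chains are broken at their
    smallest overlap.  Every super-read lands in exactly one contig."""
    junctions = _junctions(overlaps)
    end_degree: dict[tuple[str, str], int] = {}
    for (na, ea), (nb, eb), _l, _f in junctions:
        end_degree[(na, ea)] = end_degree.get((na, ea), 0) + 1
        end_degree[(nb, eb)] = end_degree.get((nb, eb), 0) + 1

    usable = [
        j for j in junctions
        if end_degree[(j[0][0], j[0][1])] == 1 and end_degree[(j[1][0], j[1][1])] == 1
        and j[0][0] != j[1][0]
    ]
    usable.sort(key=lambda j: (-j[2], j[0], j[1]))

    parent: dict[str, str] = {n: n for n in super_reads}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adj: dict[tuple[str, str], tuple[tuple[str, str], int, bool]] = {}
    for (na, ea), (nb, eb), length, flip in usable:
        if find(na) == find(nb):
            logger.info("cycle broken at overlap %s%s-%s%s len=%d", na, ea, nb, eb, length)
            continue
        parent[find(na)] = find(nb)
        adj[(na, ea)] = ((nb, eb), length, flip)
        adj[(nb, eb)] = ((na, ea), length, flip)

    # walk each component from a free end
    contigs: list[Contig] = []
    assigned: set[str] = set()
    order = sorted(super_reads)
    for start in order:
        if start in assigned:
            continue
        # find a terminal end of this chain
        node, entry = start, "L"
        steps = 0
        while (node, "L" if entry == "L" else "R") in adj and steps <= len(super_reads):
            # move to the neighbour through this node's 'entry' side
            (nnode, nend), _l, _f = adj[(node, entry)]
            node, entry = nnode, ("R" if nend == "L" else "L")
            # entry now names the far side of nnode; loop continues leftwards
            steps += 1
        # walk rightwards from (node) leaving through the side opposite 'entry'
        chain: list[tuple[str, str, int]] = []  # (node, strand, overlap_into_node)
        strand = "+" if entry == "L" else "-"
        chain.append((node, strand, 0))
        cur, cur_strand = node, strand
        while True:
            out_end = "R" if cur_strand == "+" else "L"
            nxt = adj.get((cur, out_end))
            if nxt is None:
                break
            (nnode, nend), length, flip = nxt
            n_strand = "+" if nend == "L" else "-"
            chain.append((nnode, n_strand, length))
            cur, cur_strand = nnode, n_strand
            if cur == node and len(chain) > len(super_reads):
                break
        seq_parts: list[str] = []
        layout: list[tuple[str, int, str]] = []
        offset = 0
        for sr_id, strand, ov_len in chain:
            s = super_reads[sr_id] if strand == "+" else revcomp(super_reads[sr_id])
            if not seq_parts:
                seq_parts.append(s)
            else:
                offset = sum(len(p) for p in seq_parts) - ov_len
                seq_parts.append(s[ov_len:])
            layout.append((sr_id, offset, strand))
            assigned.add(sr_id)
        seq = "".join(seq_parts)
        if revcomp(seq) < seq:  # canonical strand for reproducibility
            L = len(seq)
            layout = [
                (sr_id, L - off - len(super_reads[sr_id]), "-" if st == "+" else "+")
                for sr_id, off, st in layout
            ][::-1]
            seq = revcomp(seq)
        contigs.append(Contig("", seq, layout))
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    for i, c in enumerate(contigs):
        c.id = f"ctg{i:05d}"
    return contigs


def assemble(super_reads: list, min_overlap: int) -> list[Contig]:
    """Convenience wrapper: overlaps + layout from SuperRead objects or
    (id, sequence) mappings."""
    if isinstance(super_reads, dict):
        seqs = super_reads
    else:
        seqs = {f"sr{i:06d}": (sr.sequence if hasattr(sr, "sequence") else sr)
                for i, sr in enumerate(super_reads)}
    return layout_and_consensus(seqs, find_overlaps(seqs, min_overlap))


# ---------------------------------------------------------------------------
# read placement (shared by scaffolding and organelle binning)


class SeqIndex:
    """Exact-seed placement of reads on a set of named sequences."""

    def __init__(self, sequences: dict[str, str], seed_len: int = 31):
        self.seed_len = seed_len
        self.seqs = sequences
        self._idx: dict[str, list[tuple[str, int, str]]] = {}
        for name, seq in sequences.items():
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i : i + seed_len]
                if "N" in kmer:
                    continue
                c = canonical(kmer)
                strand = "+" if c == kmer else "-"
                self._idx.setdefault(c, []).append((name, i, strand))

    def place(self, read: str, max_seeds: int = 5) -> tuple[str, int, str] | None:
        """Unique placement (target, 0-based start of the read, strand) or
        None when no seed places the read uniquely."""
        L = self.seed_len
        if len(read) < L:
            return None
        step = max(1, (len(read) - L) // max(1, max_seeds - 1)) if len(read) > L else 1
        offsets = list(range(0, len(read) - L + 1, step))[:max_seeds]
        for off in offsets:
            seed = read[off : off + L]
            if "N" in seed:
                continue
            c = canonical(seed)
            hits = self._idx.get(c)
            if not hits or len(hits) > 1:
                continue
            name, pos, idx_strand = hits[0]
            read_strand = "+" if canonical(seed) == seed else "-"
            if read_strand == idx_strand:
                start = pos - off
                strand = "+"
            else:
                start = pos + L - (len(read) - off)
                strand = "-"
            return name, start, strand
        return None


# ---------------------------------------------------------------------------
# scaffolding


@dataclass
class Scaffold:
    """Ordered, oriented contigs joined across estimated N-gaps."""

    id: str
    parts: list[tuple[Contig, str]]  # (contig, strand)
    gaps: list[int] = field(default_factory=list)  # len == len(parts) - 1, each >= 1
    link_support: list[int] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        chunks = []
        for i, (ctg, strand) in enumerate(self.parts):
            if i:
                chunks.append("N" * self.gaps[i - 1])
            chunks.append(ctg.sequence if strand == "+" else revcomp(ctg.sequence))
        return "".join(chunks)

    @property
    def span(self) -> int:
        return sum(len(c.sequence) for c, _ in self.parts) + sum(self.gaps)


def _bundle_links(
    contigs: list[Contig], linking_reads: ReadSet, seed_len: int = 31
) -> dict[tuple[tuple[str, str], tuple[str, str]], list[float]]:
    """Map mate pairs onto contigs and bundle them into inter-contig end
    links with per-link gap estimates."""
    index = SeqIndex({c.id: c.sequence for c in contigs}, seed_len)
    lengths = {c.id: len(c.sequence) for c in contigs}
    outie = linking_reads.library_kind in {"mate_pair", "ditag"}
    mean_ins = linking_reads.insert_mean

    bundles: dict[tuple, list[float]] = {}
    for r1, r2 in linking_reads.pairs():
        p1 = index.place(r1.sequence)
        p2 = index.place(r2.sequence)
        if p1 is None or p2 is None:
            continue
        c1, s1pos, s1 = p1
        c2, s2pos, s2 = p2
        if c1 == c2:
            continue
        if outie:  # normalize to innie
            s1 = "+" if s1 == "-" else "-"
            s2 = "+" if s2 == "-" else "-"
        # innie: r1 points into the gap from the left, r2 from the right
        if s1 == "+":
            o1, d1 = "+", lengths[c1] - s1pos
        else:
            o1, d1 = "-", s1pos + len(r1.sequence)
        if s2 == "-":
            o2, d2 = "+", s2pos + len(r2.sequence)
        else:
            o2, d2 = "-", lengths[c2] - s2pos
        gap = mean_ins - d1 - d2
        end1 = (c1, "R" if o1 == "+" else "L")
        end2 = (c2, "L" if o2 == "+" else "R")
        key = tuple(sorted((end1, end2)))
        bundles.setdefault(key, []).append(gap)
    return bundles


def _join_ends(
    units: dict[str, object],
    edges: list[tuple[tuple[str, str], tuple[str, str], int, int]],
    min_links: int,
) -> list[list[tuple[str, str, int, int]]]:
    """Greedy end-joining shared by mate-pair and transcript scaffolding.

    edges: (end_a, end_b, support, gap).  Returns chains of
    (unit_id, strand, gap_before, support_before)."""
    edges = [e for e in edges if e[2] >= min_links]
    # contradictory 2-cycles: both relative orders supported
    pair_edges: dict[tuple[str, str], list] = {}
    for e in edges:
        pair = tuple(sorted((e[0][0], e[1][0])))
        pair_edges.setdefault(pair, []).append(e)
    kept_edges = []
    for pair, es in pair_edges.items():
        if len(es) > 1:
            logger.warning("contradictory links between %s and %s: no join", *pair)
            continue
        kept_edges.extend(es)
    kept_edges.sort(key=lambda e: (-e[2], e[0], e[1]))

    used_ends: set[tuple[str, str]] = set()
    parent = {u: u for u in units}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adj: dict[tuple[str, str], tuple[tuple[str, str], int, int]] = {}
    for ea, eb, support, gap in kept_edges:
        if ea in used_ends or eb in used_ends:
            logger.info("dropping lower-support link %s-%s (end in use)", ea, eb)
            continue
        if find(ea[0]) == find(eb[0]):
            logger.info("dropping link %s-%s (would close a cycle)", ea, eb)
            continue
        used_ends.update((ea, eb))
        parent[find(ea[0])] = find(eb[0])
        adj[ea] = (eb, support, gap)
        adj[eb] = (ea, support, gap)

    chains = []
    done: set[str] = set()
    for uid in sorted(units):
        if uid in done:
            continue
        node, entry = uid, "L"
        steps = 0
        while (node, entry) in adj and steps <= len(units):
            (nnode, nend), _s, _g = adj[(node, entry)]
            node, entry = nnode, ("R" if nend == "L" else "L")
            steps += 1
        chain = []
        strand = "+" if entry == "L" else "-"
        chain.append((node, strand, 0, 0))
        done.add(node)
        cur, cur_strand = node, strand
        while True:
            out_end = "R" if cur_strand == "+" else "L"
            nxt = adj.get((cur, out_end))
            if nxt is None:
                break
            (nnode, nend), support, gap = nxt
            n_strand = "+" if nend == "L" else "-"
            chain.append((nnode, n_strand, gap, support))
            done.add(nnode)
            cur, cur_strand = nnode, n_strand
        chains.append(chain)
    return chains


def scaffold(
    contigs: list[Contig],
    linking_reads: ReadSet,
    min_links: int = 3,
    seed_len: int = 31,
) -> list[Scaffold]:
    """Join contigs supported by >= min_links concordant mate pairs.

    Gap length is the median over links of (insert_mean − observed flank
    distances), floored at 1 bp (negative estimates are not merged — the join
    is kept conservative).  Conflicting joins at a contig end keep the
    higher-support edge; contradictory orders between the same two contigs
    cancel each other.
    """
    bundles = _bundle_links(contigs, linking_reads, seed_len)
    edges = [
        (ea, eb, len(gaps), max(1, int(round(median(gaps)))))
        for (ea, eb), gaps in bundles.items()
    ]
    by_id = {c.id: c for c in contigs}
    chains = _join_ends(by_id, edges, min_links)
    scaffolds = []
    for i, chain in enumerate(sorted(chains, key=lambda ch: -sum(len(by_id[u].sequence) for u, *_ in ch))):
        parts = [(by_id[u], st) for u, st, _g, _s in chain]
        gaps = [g for _u, _st, g, _s in chain[1:]]
        support = [s for _u, _st, _g, s in chain[1:]]
        scaffolds.append(Scaffold(f"scf{i:05d}", parts, gaps, support))
    return scaffolds


def transcript_scaffold(
    scaffolds: list[Scaffold],
    transcripts: list[tuple[str, str]],
    min_identity: float = 0.98,
    min_coverage: float = 0.95,
    min_links: int = 1,
    end_tolerance: int = 200,
) -> list[Scaffold]:
    """Add joins supported by transcripts spanning two scaffold ends.

    A transcript links two scaffolds when its alignments (identity >=
    min_identity) cover >= min_coverage of it across exactly two scaffolds,
    each aligned segment reaching within ``end_tolerance`` of a scaffold end,
    with consistent orientation.  Multi-mapping transcripts (a second full
    placement within 2% identity of the best) are excluded.
    """
    from .qc import seeded_align  # local import to avoid a cycle

    seqs = {s.id: s.sequence for s in scaffolds}
    lengths = {k: len(v) for k, v in seqs.items()}

    link_votes: dict[tuple, list[int]] = {}
    for tid, tseq in transcripts:
        hits = [h for h in seeded_align(tseq, seqs) if h.identity >= min_identity]
        if not hits:
            continue
        full = [h for h in hits if h.query_coverage >= min_coverage]
        if len(full) >= 1:
            # fully placed (possibly multi-mapped): no join evidence
            continue
        by_target: dict[str, object] = {}
        for h in hits:
            cur = by_target.get(h.target_id)
            if cur is None or h.query_coverage > cur.query_coverage:
                by_target[h.target_id] = h
        best = sorted(by_target.values(), key=lambda h: -h.query_coverage)[:2]
        if len(best) < 2:
            continue
        h1, h2 = sorted(best, key=lambda h: h.query_span[0])
        cov = (h1.query_span[1] - h1.query_span[0] + h2.query_span[1] - h2.query_span[0]) / len(tseq)
        if cov < min_coverage or h1.target_id == h2.target_id:
            continue
        # each piece must reach a scaffold end pointing across the junction
        def end_of(h, leading: bool):
            # orientation of the scaffold in transcript coordinates
            fwd = h.strand == "+"
            ts, te = h.target_span
            tl = lengths[h.target_id]
            if leading:  # transcript continues to the right of this piece
                near_right_end = (tl - te <= end_tolerance) if fwd else (ts <= end_tolerance)
                if not near_right_end:
                    return None
                return (h.target_id, "R" if fwd else "L"), ("+" if fwd else "-")
            near_left_end = (ts <= end_tolerance) if fwd else (tl - te <= end_tolerance)
            if not near_left_end:
                return None
            return (h.target_id, "L" if fwd else "R"), ("+" if fwd else "-")

        e1 = end_of(h1, leading=True)
        e2 = end_of(h2, leading=False)
        if e1 is None or e2 is None:
            continue
        gap = max(1, h2.query_span[0] - h1.query_span[1])
        key = tuple(sorted((e1[0], e2[0])))
        link_votes.setdefault(key, []).append(gap)

    edges = [
        (ea, eb, len(gaps), max(1, int(round(median(gaps)))))
        for (ea, eb), gaps in link_votes.items()
    ]
    by_id = {s.id: s for s in scaffolds}
    chains = _join_ends(by_id, edges, min_links)
    out: list[Scaffold] = []
    for i, chain in enumerate(chains):
        parts: list[tuple[Contig, str]] = []
        gaps: list[int] = []
        support: list[int] = []
        for j, (uid, st, gap, sup) in enumerate(chain):
            scf = by_id[uid]
            if j:
                gaps.append(gap)
                support.append(sup)
            sparts = scf.parts if st == "+" else [
                (c, "-" if s == "+" else "+") for c, s in reversed(scf.parts)
            ]
            sgaps = scf.gaps if st == "+" else list(reversed(scf.gaps))
            ssup = scf.link_support if st == "+" else list(reversed(scf.link_support))
            parts.extend(sparts)
            gaps.extend(sgaps)
            support.extend(ssup)
        out.append(Scaffold(f"tscf{i:05d}", parts, gaps, support))
    out.sort(key=lambda s: -s.span)
    for i, s in enumerate(out):
        s.id = f"scf{i:05d}"
    return out
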