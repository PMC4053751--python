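"""Assembly statistics, seeded alignment, validation against independent
contigs, transcript classification, and core-gene completeness scanning.

The shared aligner (`seeded_align`) is a seed-chain-extend design: exact seed
matches are clustered colinearly per diagonal band, the chained region is
aligned with banded edit distance (edlib), and the best local segment of that
alignment is reported with identity (matches / aligned columns, gaps
included) and query coverage.  Any pair sharing an exact stretch of at least
``seed_len`` bases is found, which is the completeness contract this package
relies on at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from ._seq import gc_fraction, revcomp


# ---------------------------------------------------------------------------
# basic statistics


def n50(lengths: list[int]) -> int:
    """Largest L such that elements of length >= L sum to >= half the total."""
    if not lengths:
        raise ValueError("n50 of an empty list is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    return min(lengths)  # unreachable


@dataclass
class AssemblyStats:
    n_contigs: int
    n_scaffolds: int
    contig_n50: int
    scaffold_n50: int
    total_contig_bp: int
    total_scaffold_span: int
    gc_fraction: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def assembly_stats(contigs, scaffolds=None, min_contig_len: int = 64) -> AssemblyStats:
    """Table-style assembly metrics.

    Contigs shorter than ``min_contig_len`` (default 64 bp) are excluded from
    contig accounting; scaffold span counts contig bases plus N-gaps.  GC is
    computed over contig bases, excluding N.
    """
    cseqs = [c.sequence if hasattr(c, "sequence") else c for c in contigs]
    cseqs = [s for s in cseqs if len(s) > min_contig_len]
    if scaffolds is None:
        spans = [len(s) for s in cseqs]
    else:
        spans = [s.span if hasattr(s, "span") else len(s) for s in scaffolds]
    all_bases = "".join(cseqs)
    return AssemblyStats(
        n_contigs=len(cseqs),
        n_scaffolds=len(spans),
        contig_n50=n50([len(s) for s in cseqs]) if cseqs else 0,
        scaffold_n50=n50(spans) if spans else 0,
        total_contig_bp=sum(len(s) for s in cseqs),
        total_scaffold_span=sum(spans),
        gc_fraction=gc_fraction(all_bases),
    )


# ---------------------------------------------------------------------------
# seeded alignment


@dataclass
class AlignmentHit:
    query_id: str
    target_id: str
    query_span: tuple[int, int]  # 0-based half-open, forward query coords
    target_span: tuple[int, int]
    strand: str  # '+' or '-'
    identity: float  # matches / aligned columns (gaps included)
    query_coverage: float  # aligned query bp / query length

    @property
    def aligned_query_bp(self) -> int:
        return self.query_span[1] - self.query_span[0]


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    runs, n = [], 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            runs.append((n, ch))
            n = 0
    return runs


def _best_local_segment(runs, match=1, penalty=2):
    """Kadane over cigar runs: maximal-scoring contiguous run slice.

    Returns (start_run, end_run) half-open, or None."""
    best, best_span = 0, None
    cur, cur_start = 0, 0
    for i, (n, op) in enumerate(runs):
        score = n * (match if op == "=" else -penalty)
        if cur <= 0:
            cur, cur_start = 0, i
        cur += score
        if cur > best:
            best, best_span = cur, (cur_start, i + 1)
    return best_span


def _segment_metrics(runs, seg):
    """Identity and query/target consumption for a run slice, plus the
    query/target offsets of the slice start within the full alignment."""
    q_off = t_off = 0
    for n, op in runs[: seg[0]]:
        if op in ("=", "X", "I"):
            q_off += n
        if op in ("=", "X", "D"):
            t_off += n
    matches = columns = q_len = t_len = 0
    for n, op in runs[seg[0] : seg[1]]:
        columns += n
        if op == "=":
            matches += n
        if op in ("=", "X", "I"):
            q_len += n
        if op in ("=", "X", "D"):
            t_len += n
    return matches, columns, q_off, t_off, q_len, t_len


def _cluster_matches(matches, band, max_gap):
    """Group (qpos, tpos) seed matches into colinear clusters by diagonal
    band and target proximity (O(n log n))."""
    buckets: dict[int, list[tuple[int, int]]] = {}
    for qpos, tpos in matches:
        buckets.setdefault((tpos - qpos) // max(1, band), []).append((qpos, tpos))
    clusters: list[list[tuple[int, int]]] = []
    for bucket in buckets.values():
        bucket.sort(key=lambda m: m[1])
        cur = [bucket[0]]
        for m in bucket[1:]:
            if m[1] - cur[-1][1] <= max_gap:
                cur.append(m)
            else:
                clusters.append(cur)
                cur = [m]
        clusters.append(cur)
    return clusters


def seeded_align(
    query: str,
    targets: dict[str, str] | list[tuple[str, str]],
    seed_len: int = 15,
    band: int = 50,
    max_gap: int = 1000,
    query_id: str = "query",
    min_segment: int = 20,
) -> list[AlignmentHit]:
    """Align a query against a set of named targets, both strands.

    Exact ``seed_len``-mers shared between query and target are chained per
    diagonal band; each chain's region (padded by ``band``) is aligned by
    edit distance and the best local segment reported.  No hit -> empty list.
    """
    if seed_len < 15:
        raise ValueError("seed_len must be >= 15")
    if isinstance(targets, list):
        targets = dict(targets)
    qlen = len(query)
    if qlen < seed_len:
        return []

    hits: list[AlignmentHit] = []
    for tname, tseq in targets.items():
        tindex: dict[str, list[int]] = {}
        for i in range(len(tseq) - seed_len + 1):
            tindex.setdefault(tseq[i : i + seed_len], []).append(i)
        for strand, q in (("+", query), ("-", revcomp(query))):
            matches = []
            for qpos in range(qlen - seed_len + 1):
                for tpos in tindex.get(q[qpos : qpos + seed_len], ()):
                    matches.append((qpos, tpos))
            if not matches:
                continue
            if len(matches) > 200_000:  # highly repetitive pairing: subsample
                matches = matches[:: len(matches) // 200_000 + 1]
            for cl in _cluster_matches(matches, band, max_gap):
                q0 = min(m[0] for m in cl)
                q1 = max(m[0] for m in cl) + seed_len
                t0 = min(m[1] for m in cl)
                t1 = max(m[1] for m in cl) + seed_len
                # align the cluster's query window only (padded by band):
                # HW mode frees the target flanks but charges for every query
                # base, so query sequence outside the cluster must be excluded
                qw0 = max(0, q0 - band)
                qw1 = min(qlen, q1 + band)
                w0 = max(0, t0 - (q0 - qw0) - band)
                w1 = min(len(tseq), t1 + (qw1 - q1) + band)
                res = edlib.align(q[qw0:qw1], tseq[w0:w1], mode="HW", task="path")
                if res["editDistance"] < 0 or not res.get("cigar"):
                    continue
                runs = _parse_cigar(res["cigar"])
                seg = _best_local_segment(runs)
                if seg is None:
                    continue
                m, cols, q_off, t_off, q_used, t_used = _segment_metrics(runs, seg)
                if q_used < min_segment:
                    continue
                ts = w0 + res["locations"][0][0] + t_off
                qs, qe, te = qw0 + q_off, qw0 + q_off + q_used, None
                te = ts + t_used
                # greedy exact extension: co-optimal edit paths can park
                # boundary bases as flanking indels; reclaim matching ones
                while qs > 0 and ts > 0 and q[qs - 1] == tseq[ts - 1]:
                    qs -= 1
                    ts -= 1
                    m += 1
                    cols += 1
                while qe < qlen and te < len(tseq) and q[qe] == tseq[te]:
                    qe += 1
                    te += 1
                    m += 1
                    cols += 1
                q_used, t_used, t_start = qe - qs, te - ts, ts
                if strand == "-":
                    qs, qe = qlen - qe, qlen - qs
                hits.append(
                    AlignmentHit(
                        query_id, tname, (qs, qe), (t_start, t_start + t_used),
                        strand, m / cols if cols else 0.0, q_used / qlen,
                    )
                )

    # deduplicate overlapping hits on the same target, keeping the best
    hits.sort(key=lambda h: (-(h.identity * h.aligned_query_bp), h.target_id))
    kept: list[AlignmentHit] = []
    for h in hits:
        dup = False
        for k in kept:
            if k.target_id != h.target_id or k.strand != h.strand:
                continue
            ov_q = min(k.query_span[1], h.query_span[1]) - max(k.query_span[0], h.query_span[0])
            ov_t = min(k.target_span[1], h.target_span[1]) - max(k.target_span[0], h.target_span[0])
            if ov_q > 0.5 * h.aligned_query_bp and ov_t > 0:
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# validation against independent contigs


@dataclass
class ValidationReport:
    n_candidates: int
    n_passing_min_len: int
    total_validated_bp: int
    covered_fraction: float
    n_high_similarity: int
    n_aligned: int
    implied_error_rate: float
    degenerate: bool = False  # no contig passed min_len

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def validate_against(
    assembly: dict[str, str] | list[tuple[str, str]],
    validation_contigs: list[tuple[str, str]],
    min_len: int = 20_000,
    high_sim: float = 0.995,
    seed_len: int = 15,
) -> ValidationReport:
    """Align independent validation contigs (>= min_len) to the assembly.

    Reports the fraction of validated bases covered by assembly alignments,
    the count of contigs at >= ``high_sim`` identity, and the implied error
    rate (1 − mean identity of aligned portions, length-weighted).
    """
    if isinstance(assembly, list):
        assembly = dict(assembly)
    passing = [(n, s) for n, s in validation_contigs if len(s) >= min_len]
    if not passing:
        return ValidationReport(len(validation_contigs), 0, 0, 0.0, 0, 0, 0.0, True)
    total = sum(len(s) for _, s in passing)
    covered = 0
    n_high = n_aligned = 0
    id_weight = id_sum = 0.0
    for name, seq in passing:
        hits = seeded_align(seq, assembly, seed_len=seed_len, query_id=name)
        if not hits:
            continue
        n_aligned += 1
        intervals = sorted(h.query_span for h in hits)
        merged_bp, cur_s, cur_e = 0, *intervals[0]
        for s, e in intervals[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged_bp += cur_e - cur_s
                cur_s, cur_e = s, e
        merged_bp += cur_e - cur_s
        covered += merged_bp
        best = max(hits, key=lambda h: h.aligned_query_bp * h.identity)
        if best.identity >= high_sim and best.query_coverage >= 0.5:
            n_high += 1
        for h in hits:
            id_sum += h.identity * h.aligned_query_bp
            id_weight += h.aligned_query_bp
    return ValidationReport(
        n_candidates=len(validation_contigs),
        n_passing_min_len=len(passing),
        total_validated_bp=total,
        covered_fraction=covered / total,
        n_high_similarity=n_high,
        n_aligned=n_aligned,
        implied_error_rate=1.0 - (id_sum / id_weight) if id_weight else 0.0,
    )


# ---------------------------------------------------------------------------
# transcript classification and core-gene completeness


def classify_transcripts(
    transcripts: list[tuple[str, str]],
    assembly: dict[str, str] | list[tuple[str, str]],
    min_identity: float = 0.98,
    min_coverage: float = 0.95,
    seed_len: int = 15,
) -> dict[str, int]:
    """Count transcripts as aligned_unique / multi / unaligned.

    A transcript is aligned_unique iff exactly one placement meets both the
    identity and coverage thresholds.  The standard preset pairs are
    (0.98, 0.95) for de novo transcripts and (0.98, 0.98) for ESTs.
    """
    if isinstance(assembly, list):
        assembly = dict(assembly)
    counts = {"aligned_unique": 0, "multi": 0, "unaligned": 0}
    for name, seq in transcripts:
        hits = seeded_align(seq, assembly, seed_len=seed_len, query_id=name)
        full = [
            h for h in hits
            if h.identity >= min_identity and h.query_coverage >= min_coverage
        ]
        if len(full) == 1:
            counts["aligned_unique"] += 1
        elif len(full) > 1:
            counts["multi"] += 1
        else:
            counts["unaligned"] += 1
    return counts


def core_gene_scan(
    core_seqs: list[tuple[str, str]],
    assembly: dict[str, str] | list[tuple[str, str]],
    full_threshold: float = 0.7,
    min_identity: float = 0.7,
    seed_len: int = 15,
) -> dict:
    """Sequence-level completeness scan over a conserved core-gene set.

    Per core sequence: full_length when the best hit covers >=
    ``full_threshold`` of it at identity >= ``min_identity``; partial when
    some hit exists below that coverage; absent otherwise.  The summary
    reports the full-length fraction of all annotated (full + partial).
    """
    if not core_seqs:
        raise ValueError("core_seqs must be nonempty")
    if not (0 < full_threshold <= 1):
        raise ValueError("full_threshold must lie in (0, 1]")
    if isinstance(assembly, list):
        assembly = dict(assembly)
    counts = {"full_length": 0, "partial": 0, "absent": 0}
    per_gene = {}
    for name, seq in core_seqs:
        hits = [
            h for h in seeded_align(seq, assembly, seed_len=seed_len, query_id=name)
            if h.identity >= min_identity
        ]
        if not hits:
            label = "absent"
        else:
            best = max(hits, key=lambda h: h.query_coverage)
            label = "full_length" if best.query_coverage >= full_threshold else "partial"
        counts[label] += 1
        per_gene[name] = label
    annotated = counts["full_length"] + counts["partial"]
    return {
        **counts,
        "per_gene": per_gene,
        "full_length_fraction": counts["full_length"] / annotated if annotated else 0.0,
    }
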