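"""Canonical k-mer counting, spectrum-based error correction, and
haplotype-divergence filtering of diploid reads.

The k-mer database is built from the haploid read pool (default k = 79, the
production value; tests use smaller odd k — the contracts are k-independent).
A k-mer is *solid* when its count reaches ``solid_threshold``; solid k-mers
define the trusted haploid spectrum used both to correct sequencing errors in
haploid reads and to reject diploid reads whose k-mer content diverges from
the haploid genome (reads sampling the second haplotype across SNP-dense
regions lose a window of k k-mers per mismatch and fall under the fraction
threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

from ._seq import canonical, iter_kmers, revcomp
from .synth import ReadSet


@dataclass
class KmerDB:
    """Canonical k-mer -> count table.

    Every stored key is its own canonical form (lexicographic minimum of the
    k-mer and its reverse complement) and carries a count >= 1.
    """

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    solid_threshold: int = 2

    def get(self, kmer: str) -> int:
        """Count of a k-mer (queried in either orientation); absent -> 0."""
        return self.counts.get(canonical(kmer), 0)

    def is_solid(self, kmer: str) -> bool:
        return self.get(kmer) >= self.solid_threshold

    def total_count(self) -> int:
        return sum(self.counts.values())

    def save(self, path: str | Path) -> None:
        """Sorted two-column TSV with a JSON header line."""
        with open(path, "w") as fh:
            fh.write(json.dumps({"k": self.k, "solid_threshold": self.solid_threshold}) + "\n")
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerDB":
        with open(path) as fh:
            header = json.loads(fh.readline())
            counts = {}
            for line in fh:
                kmer, n = line.split("\t")
                counts[kmer] = int(n)
        return cls(header["k"], counts, header["solid_threshold"])


def count_kmers(
    reads: ReadSet | list[str], k: int = 79, solid_threshold: int = 2
) -> KmerDB:
    """Count canonical k-mers over a read set or plain sequences.

    k must be odd (an odd k has no self-reverse-complement k-mer, so canonical
    counting is unambiguous).  Windows containing N are skipped.
    """
    if not (1 <= k <= 101):
        raise ValueError("k must lie in [1, 101]")
    if k % 2 == 0:
        raise ValueError("k must be odd")
    seqs = reads.sequences() if isinstance(reads, ReadSet) else reads
    counts: dict[str, int] = {}
    for seq in seqs:
        for _, kmer in iter_kmers(seq, k):
            c = canonical(kmer)
            counts[c] = counts.get(c, 0) + 1
    return KmerDB(k, counts, solid_threshold)


def suggest_solid_threshold(db: KmerDB) -> int:
    """Pick a solid threshold from the k-mer count histogram.

    In a deep read set the histogram is bimodal: an error peak at count ~1
    and a coverage peak near the sequencing depth.  The valley between them
    separates error artifacts from genuine genomic k-mers; counts strictly
    above the valley are trusted.  Falls back to 2 when no clear coverage
    peak exists (shallow data)."""
    from collections import Counter

    hist = Counter(db.counts.values())
    if not hist:
        return 2
    maxc = max(hist)
    if maxc < 8:
        return 2
    arr = [hist.get(c, 0) for c in range(maxc + 1)]
    peak = max(range(3, maxc + 1), key=lambda c: arr[c])
    if peak <= 3:
        return 2
    valley = min(range(1, peak), key=lambda c: arr[c])
    return max(2, valley + 1)


# ---------------------------------------------------------------------------
# error correction


@dataclass
class CorrectionResult:
    sequence: str
    n_corrections: int
    status: str  # solid | corrected | uncorrectable | too_short


def error_correct(read: str, db: KmerDB, max_corrections: int = 3) -> CorrectionResult:
    """Greedy left-to-right substitution-only correction.

    Scans windows left to right; at the first non-solid window the mismatch is
    assumed at the window's last base (earlier windows were solid), except at
    the very first window where every position is a candidate.  Each candidate
    substitution must make the current window solid; among those, the one that
    keeps the most subsequent windows solid (lookahead k windows) wins, ties
    broken by base order A<C<G<T.  If no substitution restores solidity or the
    budget is exhausted, the read is returned unchanged and flagged.
    """
    k = db.k
    if len(read) < k:
        return CorrectionResult(read, 0, "too_short")
    seq = bytearray(read, "ascii")
    n_corr = 0
    i = 0
    n_win = len(seq) - k + 1
    while i < n_win:
        window = seq[i : i + k].decode()
        if "N" in window or db.is_solid(window):
            i += 1
            continue
        if n_corr >= max_corrections:
            return CorrectionResult(read, 0, "uncorrectable")
        cand_positions = range(i, i + k) if i == 0 else [i + k - 1]
        best = None  # (lookahead_solid, -pos, base) -> substitution
        for pos in cand_positions:
            orig = seq[pos]
            for b in b"ACGT":
                if b == orig:
                    continue
                seq[pos] = b
                if not db.is_solid(seq[i : i + k].decode()):
                    continue
                ahead = 0
                for j in range(i + 1, min(i + 1 + k, n_win)):
                    w = seq[j : j + k].decode()
                    if "N" in w or db.is_solid(w):
                        ahead += 1
                    else:
                        break
                key = (ahead, -pos, -b)
                if best is None or key > best[0]:
                    best = (key, pos, b)
            seq[pos] = orig
        if best is None:
            return CorrectionResult(read, 0, "uncorrectable")
        _, pos, b = best
        seq[pos] = b
        n_corr += 1
        i += 1
    out = seq.decode()
    return CorrectionResult(out, n_corr, "corrected" if n_corr else "solid")


def correct_readset(
    reads: ReadSet, db: KmerDB, max_corrections: int = 3
) -> tuple[ReadSet, dict, dict[str, str]]:
    """Correct every read in a set.

    Returns (new ReadSet with the same ids/pairing, status tally, per-read
    status).  Uncorrectable and too-short reads pass through unchanged —
    downstream stages treat their unsolid k-mers as branch stops."""
    from dataclasses import replace

    tally = {"solid": 0, "corrected": 0, "uncorrectable": 0, "too_short": 0}
    statuses: dict[str, str] = {}
    new_reads = []
    for r in reads.reads:
        res = error_correct(r.sequence, db, max_corrections)
        tally[res.status] += 1
        statuses[r.id] = res.status
        new_reads.append(replace(r, sequence=res.sequence))
    out = ReadSet(
        new_reads, reads.library_kind, reads.insert_mean, reads.insert_sd,
        reads.error_rate, reads.source, reads.provenance,
    )
    return out, tally, statuses


# ---------------------------------------------------------------------------
# diploid filtering


@dataclass
class FilterReport:
    """Outcome of haplotype-divergence filtering.

    kept and rejected partition the input read ids; per_read_fraction maps
    read id -> fraction of its k-mer windows found solid in the haploid
    database; reasons records the rule that rejected a read."""

    kept: list[str]
    rejected: list[str]
    per_read_fraction: dict[str, float]
    reasons: dict[str, str] = field(default_factory=dict)


def solid_kmer_fraction(read: str, db: KmerDB) -> float:
    """Fraction of a read's k-mer windows present as solid canonical k-mers."""
    n_win = len(read) - db.k + 1
    if n_win <= 0:
        return 0.0
    hits = sum(1 for _, kmer in iter_kmers(read, db.k) if db.is_solid(kmer))
    return hits / n_win


def filter_diploid_reads(
    reads: ReadSet, db: KmerDB, min_fraction: float = 0.9
) -> FilterReport:
    """Keep reads whose solid-k-mer fraction reaches ``min_fraction``.

    Pairs are judged jointly — both mates must pass, since downstream linking
    needs both ends.  Reads shorter than k are rejected with reason
    ``too_short``.  Lowering min_fraction never shrinks the kept set.
    """
    fractions: dict[str, float] = {}
    passes: dict[str, bool] = {}
    reasons: dict[str, str] = {}
    for r in reads.reads:
        if len(r.sequence) < db.k:
            fractions[r.id] = 0.0
            passes[r.id] = False
            reasons[r.id] = "too_short"
            continue
        f = solid_kmer_fraction(r.sequence, db)
        fractions[r.id] = f
        passes[r.id] = f >= min_fraction
        if not passes[r.id]:
            reasons[r.id] = "divergent"
    kept, rejected = [], []
    for r in reads.reads:
        ok = passes[r.id] and (r.mate_id is None or passes.get(r.mate_id, False))
        if ok:
            kept.append(r.id)
        else:
            rejected.append(r.id)
            if r.id not in reasons:
                reasons[r.id] = "mate_failed"
    return FilterReport(kept, rejected, fractions, reasons)


def subset_readset(reads: ReadSet, keep_ids: list[str]) -> ReadSet:
    keep = set(keep_ids)
    sub = [r for r in reads.reads if r.id in keep]
    prov = {r.id: reads.provenance[r.id] for r in sub if r.id in reads.provenance}
    return ReadSet(
        sub, reads.library_kind, reads.insert_mean, reads.insert_sd,
        reads.error_rate, reads.source, prov,
    )
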