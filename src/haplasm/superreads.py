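"""Super-read reduction: condense corrected haploid paired-end reads into a
containment-free set of maximal uniquely-extended sequences.

Each read is extended base by base on both ends through a de Bruijn-style
extension graph while the walk is unambiguous in *both* directions (the
current k-mer has exactly one outgoing extension and the entered k-mer has
exactly one incoming one — consulting the entered k-mer prevents oscillation
next to palindromic context).  A super-read is such a maximal extension; it
contains both ends of every read pair whose mates extend onto the same path,
and no super-read is an exact substring (either strand) of another.  Because
deep read sets share unitigs, the read set collapses by a large factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import canonical, iter_kmers, revcomp
from .synth import ReadSet

_COMP = str.maketrans("ACGT", "TGCA")


class ExtensionGraph:
    """Per canonical k-mer, the sets of observed one-base extensions on the
    left and right of its canonical orientation."""

    def __init__(self, k: int):
        self.k = k
        self._left: dict[str, set[str]] = {}
        self._right: dict[str, set[str]] = {}

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self._right or canonical(kmer) in self._left

    def __len__(self) -> int:
        return len(self._right.keys() | self._left.keys())

    def add_occurrence(self, kmer: str, left: str | None, right: str | None) -> None:
        c = canonical(kmer)
        flip = c != kmer
        self._right.setdefault(c, set())
        self._left.setdefault(c, set())
        if right is not None:
            (self._left[c] if flip else self._right[c]).add(
                right.translate(_COMP) if flip else right
            )
        if left is not None:
            (self._right[c] if flip else self._left[c]).add(
                left.translate(_COMP) if flip else left
            )

    def right_extensions(self, kmer: str) -> set[str]:
        """Extensions continuing an oriented k-mer in its own direction."""
        c = canonical(kmer)
        if c == kmer:
            return self._right.get(c, set())
        return {b.translate(_COMP) for b in self._left.get(c, set())}

    def left_extensions(self, kmer: str) -> set[str]:
        c = canonical(kmer)
        if c == kmer:
            return self._left.get(c, set())
        return {b.translate(_COMP) for b in self._right.get(c, set())}


def build_extension_graph(
    corrected_reads: ReadSet | list[str], k: int, db=None
) -> ExtensionGraph:
    """Record, for every solid k-mer of the corrected reads, the observed
    one-base extensions on each side.  k must be odd.

    When a KmerDB is supplied, only k-mers solid in it enter the graph and an
    extension is recorded only when the adjacent k-mer is also solid; this
    keeps residual sequencing errors from planting spurious branches that
    would stop unique extension early."""
    if k % 2 == 0:
        raise ValueError("k must be odd")
    seqs = corrected_reads.sequences() if isinstance(corrected_reads, ReadSet) else corrected_reads
    g = ExtensionGraph(k)
    for seq in seqs:
        n_win = len(seq) - k + 1
        if n_win <= 0:
            continue
        if db is None:
            ok = [("N" not in seq[i : i + k]) for i in range(n_win)]
        else:
            ok = [
                ("N" not in seq[i : i + k]) and db.is_solid(seq[i : i + k])
                for i in range(n_win)
            ]
        for i in range(n_win):
            if not ok[i]:
                continue
            left = seq[i - 1] if i > 0 and ok[i - 1] else None
            right = seq[i + k] if i + 1 < n_win and ok[i + 1] else None
            g.add_occurrence(seq[i : i + k], left, right)
    return g


@dataclass
class SuperRead:
    """A maximal haploid sequence with provenance of contained reads."""

    sequence: str
    member_pairs: list[str] = field(default_factory=list)
    member_reads: list[str] = field(default_factory=list)
    origin: dict = field(default_factory=dict)


@dataclass
class ReductionReport:
    n_input_reads: int
    n_super_reads: int
    reduction_factor: float
    total_input_bp: int
    total_super_bp: int
    n_resolved_pairs: int = 0
    n_unresolved_pairs: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _walk(seed_kmer: str, graph: ExtensionGraph, visited: set[str]) -> str:
    """Extend an oriented k-mer rightwards while unambiguous; returns the
    appended bases."""
    cur = seed_kmer
    out: list[str] = []
    while True:
        exts = graph.right_extensions(cur)
        if len(exts) != 1:
            break
        (b,) = exts
        nxt = cur[1:] + b
        if len(graph.left_extensions(nxt)) != 1:
            break  # entered k-mer is ambiguous on the incoming side
        if nxt in visited or revcomp(nxt) in visited:
            break  # cycle guard
        visited.add(nxt)
        out.append(b)
        cur = nxt
    return "".join(out)


def extend_read(read: str, graph: ExtensionGraph) -> SuperRead:
    """Uniquely extend a read on both ends through the graph.

    A read containing a k-mer absent from the graph is returned as-is and
    flagged unextendable in ``origin``."""
    k = graph.k
    if len(read) < k:
        return SuperRead(read, origin={"unextendable": True, "reason": "too_short"})
    kmers = [read[i : i + k] for i in range(len(read) - k + 1)]
    if any("N" in km or km not in graph for km in kmers):
        return SuperRead(read, origin={"unextendable": True, "reason": "absent_kmer"})
    visited = {km for km in kmers}
    right = _walk(kmers[-1], graph, visited)
    left = revcomp(_walk(revcomp(kmers[0]), graph, visited))
    seq = left + read + right
    return SuperRead(seq, origin={"left_ext": len(left), "right_ext": len(right)})


def join_and_reduce(pairs: ReadSet, graph: ExtensionGraph) -> tuple[list[SuperRead], ReductionReport]:
    """Extend all reads, merge mates landing on a common extension path, and
    remove exact-substring containment (either strand).

    Every input pair is assigned to exactly one surviving super-read (both
    mates contained) or reported unresolved, in which case each mate is kept
    as a single-end membership of its own super-read.
    """
    # Extend each distinct read once; memoize via a k-mer index of already
    # built super-reads: a read contained in a known super-read extends to
    # that same super-read (unique extension is position-determined), so the
    # walk runs once per unitig, not once per read.
    k = graph.k
    ext_cache: dict[str, str] = {}
    built: dict[str, int] = {}  # canonical super-read sequence -> index
    sr_seqs: list[str] = []
    sr_index: dict[str, tuple[int, int, bool]] = {}  # kmer -> (sr, pos, fwd?)

    def _register(S: str) -> None:
        if S in built:
            return
        idx = len(sr_seqs)
        built[S] = idx
        sr_seqs.append(S)
        for pos in range(len(S) - k + 1):
            kmer = S[pos : pos + k]
            c = canonical(kmer)
            if c not in sr_index:
                sr_index[c] = (idx, pos, c == kmer)

    def _lookup(seq: str) -> str | None:
        if len(seq) < k:
            return None
        kmer = seq[:k]
        c = canonical(kmer)
        hit = sr_index.get(c)
        if hit is None:
            return None
        idx, pos, idx_fwd = hit
        S = sr_seqs[idx]
        seq_fwd = c == kmer
        if seq_fwd == idx_fwd:  # read runs along S forward
            if S[pos : pos + len(seq)] == seq:
                return S
        else:
            start = pos + k - len(seq)
            if start >= 0 and S[start : start + len(seq)] == revcomp(seq):
                return S
        return None

    def extended(seq: str) -> str:
        cached = ext_cache.get(seq)
        if cached is not None:
            return cached
        S = _lookup(seq)
        if S is None:
            s = extend_read(seq, graph).sequence
            S = s if s <= revcomp(s) else revcomp(s)  # canonical strand
            _register(S)
        ext_cache[seq] = S
        return S

    read_to_canon: dict[str, str] = {}
    for r in pairs.reads:
        read_to_canon[r.id] = extended(r.sequence)

    distinct = sorted(set(read_to_canon.values()), key=lambda s: (-len(s), s))

    # containment removal: check each sequence against kept longer ones using
    # an exact k-mer index of the kept set (desk scale)
    k = graph.k
    kept: list[str] = []
    index: dict[str, list[tuple[int, int]]] = {}  # kmer -> [(kept_idx, pos)]
    container: dict[str, str] = {}

    def _contained_in_kept(s: str) -> str | None:
        if len(s) < k:  # shorter than a seed: fall back to direct scan
            for t in kept:
                if s in t or revcomp(s) in t:
                    return t
            return None
        for probe in (s, revcomp(s)):
            seed = probe[:k]
            for idx, pos in index.get(seed, []):
                t = kept[idx]
                if t != s and t[pos : pos + len(probe)] == probe:
                    return t
        return None

    for s in distinct:
        host = _contained_in_kept(s)
        if host is not None:
            container[s] = host
            continue
        kept.append(s)
        ki = len(kept) - 1
        for pos in range(len(s) - k + 1):
            index.setdefault(s[pos : pos + k], []).append((ki, pos))

    def survivor(s: str) -> str:
        while s in container:
            s = container[s]
        return s

    supers: dict[str, SuperRead] = {s: SuperRead(s) for s in kept}

    n_resolved = n_unresolved = 0
    paired_ids: set[str] = set()
    for r1, r2 in pairs.pairs():
        paired_ids.update((r1.id, r2.id))
        s1 = survivor(read_to_canon[r1.id])
        s2 = survivor(read_to_canon[r2.id])
        pair_id = r1.id[:-2]
        if s1 == s2:
            supers[s1].member_pairs.append(pair_id)
            n_resolved += 1
        else:
            supers[s1].member_reads.append(r1.id)
            supers[s2].member_reads.append(r2.id)
            n_unresolved += 1
    for r in pairs.reads:  # unpaired reads
        if r.id not in paired_ids:
            supers[survivor(read_to_canon[r.id])].member_reads.append(r.id)

    out = sorted(supers.values(), key=lambda sr: sr.sequence)
    n_in = len(pairs.reads)
    total_in = pairs.total_bases()
    total_super = sum(len(sr.sequence) for sr in out)
    report = ReductionReport(
        n_input_reads=n_in,
        n_super_reads=len(out),
        reduction_factor=(n_in / len(out)) if out else 0.0,
        total_input_bp=total_in,
        total_super_bp=total_super,
        n_resolved_pairs=n_resolved,
        n_unresolved_pairs=n_unresolved,
    )
    return out, report
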