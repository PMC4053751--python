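"""Synthetic diploid genomes, organelles, planted repeats, and simulated reads.

The simulator emulates a conifer-style study design with two DNA sources: a
haploid tissue (all reads drawn from one haplotype, the megagametophyte case)
and a diploid tissue (reads drawn from both haplotypes).  Organelle sequences
are carried at elevated copy number and, mirroring real tissue, are emitted
into the haploid paired-end pool when a mixed source is requested.  Everything
is generated under a single integer seed with fixed child streams, so any part
of a simulation can be regenerated independently and outputs are bit-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import DNA_ALPHABET, gc_fraction, revcomp

TELOMERE_UNIT = "TTTAGGG"
CENTROMERE_UNIT = "TGGAAACCCCAAATTTTGGGCGCCGGG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed child-stream offsets under the top-level seed
_STREAM_GENOME = 0
_STREAM_VARIANTS = 1
_STREAM_ORGANELLE = 2
_STREAM_READS = 3


@dataclass(frozen=True)
class RepeatFamily:
    """Specification of one planted repeat family.

    ``kind`` is one of tandem / interspersed / telomere / centromere.  For
    tandem-like kinds ``unit`` is the repeating unit (telomere and centromere
    presets fill it in) and ``copies`` the copies per array; interspersed
    families are defined by ``element_length``.  ``n_loci`` arrays/copies are
    planted, each with per-base substitution ``divergence``.
    """

    family_id: str
    kind: str = "tandem"
    unit: str | None = None
    copies: int = 10
    element_length: int = 1000
    n_loci: int = 1
    divergence: float = 0.0

    def __post_init__(self):
        if self.kind not in {"tandem", "interspersed", "telomere", "centromere"}:
            raise ValueError(f"unknown repeat kind: {self.kind}")
        if self.kind == "telomere" and self.unit is None:
            object.__setattr__(self, "unit", TELOMERE_UNIT)
        if self.kind == "centromere" and self.unit is None:
            object.__setattr__(self, "unit", CENTROMERE_UNIT)
        if self.kind != "interspersed" and not self.unit:
            raise ValueError("tandem family needs a unit")


@dataclass(frozen=True)
class OrganelleSpec:
    name: str  # "mito" or "chloroplast"
    length: int
    gc: float
    copy_number: int


@dataclass
class GenomeTruth:
    """Ground truth for one simulated diploid genome.

    ``variant_positions`` holds (position_on_A, type, (ref, alt)) and applying
    them to haplotype_A reproduces haplotype_B exactly.  Planted repeat
    intervals are 0-based half-open on haplotype_A.
    """

    haplotype_A: str
    haplotype_B: str
    variant_positions: list[tuple[int, str, tuple[str, str]]]
    planted_repeats: list[tuple[int, int, str, str]]
    organelles: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.haplotype_A)

    def apply_variants(self) -> str:
        """Re-derive haplotype_B from haplotype_A and the variant list."""
        out = []
        prev = 0
        for pos, _vtype, (ref, alt) in sorted(self.variant_positions):
            out.append(self.haplotype_A[prev:pos])
            assert self.haplotype_A[pos : pos + len(ref)] == ref
            out.append(alt)
            prev = pos + len(ref)
        out.append(self.haplotype_A[prev:])
        return "".join(out)


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence with exact GC composition (deviation < 1 base)."""
    n_gc = int(round(gc * n))
    arr = np.empty(n, dtype=np.uint8)
    gc_part = rng.integers(0, 2, size=n_gc)  # G or C
    at_part = rng.integers(0, 2, size=n - n_gc)  # A or T
    arr[:n_gc] = np.where(gc_part == 0, ord("G"), ord("C"))
    arr[n_gc:] = np.where(at_part == 0, ord("A"), ord("T"))
    rng.shuffle(arr)
    return arr.tobytes().decode()


def _diverge(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = bytearray(seq, "ascii")
    n_sub = rng.binomial(len(arr), rate)
    for pos in rng.choice(len(arr), size=min(n_sub, len(arr)), replace=False):
        choices = [b for b in b"ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return arr.decode()


def _break_flank_periodicity(seq: bytearray, start: int, end: int, period: int) -> None:
    """Adjust the bases flanking a planted tandem array so the periodic run
    ends exactly at the recorded interval.  A randomly matching flank base
    would legitimately extend the true array, and a scanner tolerant of short
    degenerate gaps can bridge up to two mismatching positions — so the three
    positions immediately outside each end are forced to break period."""
    for j in (1, 2, 3):
        pos = start - j
        if pos >= 0 and seq[pos] == seq[pos + period]:
            seq[pos] = next(b for b in b"ACGT" if b != seq[pos + period])
    for j in (0, 1, 2):
        pos = end + j
        if pos < len(seq) and pos - period >= 0 and seq[pos] == seq[pos - period]:
            seq[pos] = next(b for b in b"ACGT" if b != seq[pos - period])


def gen_diploid_genome(
    length: int,
    gc_target: float = 0.382,
    snp_rate: float = 0.0,
    indel_rate: float = 0.0,
    repeat_spec: list[RepeatFamily] | None = None,
    organelle_spec: list[OrganelleSpec] | None = None,
    seed: int = 0,
    snp_regions: list[tuple[int, int]] | None = None,
) -> GenomeTruth:
    """Generate a diploid genome with known ground truth.

    haplotype_A is the primary (haploid-source) sequence; haplotype_B is
    derived from it by SNPs at ``snp_rate`` and short (<=5 bp) indels at
    ``indel_rate`` per base.  When ``snp_regions`` (0-based half-open on A) is
    given, variants are confined to those regions — this models clustered
    haplotype divergence.  Repeats and organelles are planted per spec.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if length < 10_000:
        raise ValueError("length must be >= 10 kbp")
    if not (0.2 < gc_target < 0.8):
        raise ValueError("gc_target must lie in (0.2, 0.8)")
    for r in (snp_rate, indel_rate):
        if not (0.0 <= r <= 0.05):
            raise ValueError("variant rates must lie in [0, 0.05]")

    rng = np.random.default_rng([seed, _STREAM_GENOME])
    hap = bytearray(_random_seq(length, gc_target, rng), "ascii")

    planted: list[tuple[int, int, str, str]] = []
    occupied: list[tuple[int, int]] = []

    # keep planted loci well separated: flank-periodicity edits reach 3 bp
    # outside an array, and two copies of the same element closer than the
    # largest scanned tandem unit (100 bp) would seed a spurious cross-locus
    # periodicity, so a generous 130 bp margin is enforced
    _MARGIN = 130

    def _free_slot(size: int) -> int | None:
        for _ in range(200):
            s = int(rng.integers(_MARGIN, length - size - _MARGIN))
            if all(s + size + _MARGIN <= a or s >= b + _MARGIN for a, b in occupied):
                return s
        return None

    elements: dict[str, str] = {}
    for fam in repeat_spec or []:
        for _ in range(fam.n_loci):
            if fam.kind == "interspersed":
                if fam.family_id not in elements:
                    elements[fam.family_id] = _random_seq(fam.element_length, gc_target, rng)
                ins = _diverge(elements[fam.family_id], fam.divergence, rng)
                period = None
            else:
                ins = _diverge(fam.unit * fam.copies, fam.divergence, rng)
                period = len(fam.unit)
            start = _free_slot(len(ins))
            if start is None:
                raise ValueError(f"no room to plant repeat family {fam.family_id}")
            end = start + len(ins)
            hap[start:end] = ins.encode()
            if period is not None and fam.divergence == 0:
                _break_flank_periodicity(hap, start, end, period)
            kind = fam.kind if fam.kind != "interspersed" else "interspersed"
            planted.append((start, end, fam.family_id, kind))
            occupied.append((start, end))

    haplotype_A = hap.decode()

    # variants A -> B
    vrng = np.random.default_rng([seed, _STREAM_VARIANTS])
    if snp_regions is None:
        eligible = np.arange(length)
    else:
        eligible = np.concatenate(
            [np.arange(max(0, s), min(length, e)) for s, e in snp_regions]
        ) if snp_regions else np.array([], dtype=int)
    variants: list[tuple[int, str, tuple[str, str]]] = []
    if eligible.size:
        n_snp = vrng.binomial(eligible.size, snp_rate) if snp_rate > 0 else 0
        n_ind = vrng.binomial(eligible.size, indel_rate) if indel_rate > 0 else 0
        pos_all = vrng.choice(eligible, size=min(n_snp + n_ind, eligible.size), replace=False)
        pos_all = np.sort(pos_all)
        kinds = np.array(["snp"] * n_snp + ["indel"] * max(0, len(pos_all) - n_snp))
        vrng.shuffle(kinds)
        last_end = -1
        for pos, vtype in zip(pos_all.tolist(), kinds.tolist()):
            if pos <= last_end:  # keep variants non-overlapping
                continue
            ref_base = haplotype_A[pos]
            if vtype == "snp":
                bases = [b for b in DNA_ALPHABET if b != ref_base]
                alt = bases[int(vrng.integers(0, 3))]
                variants.append((pos, "snp", (ref_base, alt)))
                last_end = pos
            else:
                size = int(vrng.integers(1, 6))  # <=5 bp
                if vrng.integers(0, 2) == 0 and pos + size < length:  # deletion
                    ref = haplotype_A[pos : pos + size]
                    variants.append((pos, "indel", (ref, "")))
                    last_end = pos + size - 1
                else:  # insertion
                    ins = _random_seq(size, gc_target, vrng)
                    variants.append((pos, "indel", ("", ins)))
                    last_end = pos

    truth = GenomeTruth(haplotype_A, "", variants, planted, [])
    truth.haplotype_B = truth.apply_variants()

    orng = np.random.default_rng([seed, _STREAM_ORGANELLE])
    for spec in organelle_spec or []:
        if spec.copy_number < 1:
            raise ValueError("organelle copy_number must be >= 1")
        truth.organelles.append((spec.name, _random_seq(spec.length, spec.gc, orng), spec.copy_number))

    return truth


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class Read:
    id: str
    sequence: str
    quality: str
    mate_id: str | None = None


@dataclass
class ReadSet:
    """Simulated reads plus per-read truth provenance.

    ``provenance`` maps read id -> (template name, start, end, strand) on the
    source sequence; it exists for oracle checks and is never consulted by the
    assembly pipeline itself.
    """

    reads: list[Read]
    library_kind: str
    insert_mean: float
    insert_sd: float
    error_rate: float
    source: str
    provenance: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    def pairs(self) -> list[tuple[Read, Read]]:
        by_id = {r.id: r for r in self.reads}
        out = []
        for r in self.reads:
            if r.mate_id and r.id.endswith("/1"):
                out.append((r, by_id[r.mate_id]))
        return out

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.reads]

    def total_bases(self) -> int:
        return sum(len(r.sequence) for r in self.reads)


def sim_reads(
    truth: GenomeTruth,
    library_kind: str = "paired_end",
    depth: float = 30.0,
    read_len: int = 100,
    insert_mean: float = 400.0,
    insert_sd: float = 40.0,
    error_rate: float = 0.0,
    source: str = "haploid",
    seed: int = 0,
    id_prefix: str = "r",
) -> ReadSet:
    """Simulate paired reads from a GenomeTruth.

    ``source`` selects the templates: haploid -> haplotype_A only; diploid ->
    both haplotypes at equal weight; mixed_with_organelle -> haplotype_A at
    ``depth`` plus each organelle at depth x copy_number.  paired_end pairs
    point inward (innie, FR); mate_pair and ditag pairs point outward (outie,
    RF).  Base qualities are constant Q30.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if read_len >= insert_mean:
        raise ValueError("read_len must be smaller than insert_mean")
    if library_kind not in {"paired_end", "mate_pair", "ditag"}:
        raise ValueError(f"unknown library_kind: {library_kind}")

    if source == "haploid":
        templates = [("hapA", truth.haplotype_A, 1)]
    elif source == "diploid":
        templates = [("hapA", truth.haplotype_A, 1), ("hapB", truth.haplotype_B, 1)]
    elif source == "mixed_with_organelle":
        templates = [("hapA", truth.haplotype_A, 1)] + [
            (name, seq, copy) for name, seq, copy in truth.organelles
        ]
    else:
        raise ValueError(f"unknown source: {source}")

    rng = np.random.default_rng([seed, _STREAM_READS])
    qual = chr(33 + 30) * read_len
    outie = library_kind in {"mate_pair", "ditag"}

    reads: list[Read] = []
    prov: dict[str, tuple[str, int, int, str]] = {}
    pair_no = 0
    for tname, tseq, copy in templates:
        tlen = len(tseq)
        n_pairs = int(round(depth * copy * tlen / (2 * read_len)))
        if tlen < read_len:
            continue
        inserts = np.clip(
            np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int),
            read_len,
            tlen,
        )
        # edge-complete sampling: fragment starts drawn over an extended range
        # and clamped at template boundaries, so read coverage stays flat out
        # to the template ends instead of ramping over one insert length
        lo = -(inserts - read_len)
        hi = tlen - read_len
        raw = np.floor(lo + rng.random(n_pairs) * (hi - lo + 1)).astype(int)
        starts = np.clip(raw, 0, tlen - inserts)
        n_errs = rng.binomial(read_len, error_rate, size=2 * n_pairs) if error_rate > 0 else None
        for j in range(n_pairs):
            ins, s = int(inserts[j]), int(starts[j])
            frag_r1 = tseq[s : s + read_len]
            frag_r2 = tseq[s + ins - read_len : s + ins]
            if outie:
                seq1, seq2 = revcomp(frag_r1), frag_r2
                strand1, strand2 = "-", "+"
            else:
                seq1, seq2 = frag_r1, revcomp(frag_r2)
                strand1, strand2 = "+", "-"
            if n_errs is not None:
                seq1 = _apply_subs(seq1, int(n_errs[2 * j]), rng)
                seq2 = _apply_subs(seq2, int(n_errs[2 * j + 1]), rng)
            id1 = f"{id_prefix}{pair_no}/1"
            id2 = f"{id_prefix}{pair_no}/2"
            reads.append(Read(id1, seq1, qual, id2))
            reads.append(Read(id2, seq2, qual, id1))
            prov[id1] = (tname, s, s + read_len, strand1)
            prov[id2] = (tname, s + ins - read_len, s + ins, strand2)
            pair_no += 1

    return ReadSet(reads, library_kind, insert_mean, insert_sd, error_rate, source, prov)


def _apply_subs(seq: str, n: int, rng: np.random.Generator) -> str:
    if n == 0:
        return seq
    arr = bytearray(seq, "ascii")
    for pos in rng.choice(len(arr), size=min(n, len(arr)), replace=False):
        choices = [b for b in b"ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return arr.decode()


def sample_validation_contigs(
    truth: GenomeTruth, n: int, length: int, seed: int = 0
) -> list[tuple[str, str]]:
    """Cut fosmid-like validation contigs directly from haplotype_A."""
    rng = np.random.default_rng([seed, 17])
    out = []
    for i in range(n):
        s = int(rng.integers(0, truth.length - length + 1))
        out.append((f"fosmid_{i}", truth.haplotype_A[s : s + length]))
    return out


def sample_transcripts(
    truth: GenomeTruth, n: int, length: int, seed: int = 0
) -> list[tuple[str, str]]:
    """Cut exonless transcript-like substrings from haplotype_A (random strand)."""
    rng = np.random.default_rng([seed, 19])
    out = []
    for i in range(n):
        s = int(rng.integers(0, truth.length - length + 1))
        seq = truth.haplotype_A[s : s + length]
        if rng.integers(0, 2):
            seq = revcomp(seq)
        out.append((f"tx_{i}", seq))
    return out
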