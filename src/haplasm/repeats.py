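"""Tandem-repeat landscape profiling: periodicity scanning, motif arrays,
library-based masking, and per-unit-size summaries.

Detection is deterministic: small periods (p <= 12) are scanned exhaustively
with a shifted-match array, larger periods are seeded by repeated 12-mers at
matching spacings; candidate arrays are refined against their consensus unit
by a best-local-segment pass, so perfect arrays are always reported at their
exact spans while degenerate arrays are recovered down to the configured
purity.  Units are reported as their lexicographically least rotation.
Classification follows the standard satellite bands: microsatellite unit
1-9 bp, minisatellite 10-100 bp, satellite above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import min_rotation, revcomp
from .qc import seeded_align

TELOMERE_MOTIF = "TTTAGGG"
CENTROMERE_MOTIF = "TGGAAACCCCAAATTTTGGGCGCCGGG"

_SMALL_PERIOD_MAX = 12
_SEED_LEN = 12


@dataclass
class TandemLocus:
    seq_id: str
    start: int
    end: int  # 0-based half-open
    unit: str  # canonical rotation
    unit_len: int
    copies: float
    purity: float  # matching fraction vs the perfect array
    flagged_interspersed: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


def _consensus_unit(seq: str, start: int, end: int, p: int) -> str:
    """Majority base per phase position over the array columns."""
    cols = []
    for j in range(p):
        counts: dict[str, int] = {}
        for i in range(start + j, end, p):
            counts[seq[i]] = counts.get(seq[i], 0) + 1
        cols.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(cols)


def _min_internal_period(unit: str) -> int:
    """Smallest q dividing len(unit) with unit a whole repetition of unit[:q]."""
    p = len(unit)
    for q in range(1, p):
        if p % q == 0 and unit == unit[:q] * (p // q):
            return q
    return p


def _refine(seq: str, a: int, b: int, p: int, min_copies: float, min_purity: float,
            seq_id: str, min_unit: int = 1) -> TandemLocus | None:
    """Refine a candidate array [a, b) of period p: consensus unit, trim
    terminal bases that mismatch the consensus (keeping the span maximal —
    interior mismatches stay), then purity/copies filters.  Falls back to the
    best local segment (match +1, mismatch -purity-odds) when the trimmed
    window is still below the purity floor.  Candidates whose consensus unit
    is itself periodic with a smaller scanned unit are multimeric echoes of a
    shorter-period array and are rejected — the shorter-period scan reports
    that locus at its exact span."""
    unit = _consensus_unit(seq, a, b, p)
    if min_unit <= _min_internal_period(unit) < p:
        return None

    def _match(i: int) -> bool:
        return seq[i] == unit[(i - a) % p]

    s0, e0 = a, b
    while s0 < e0 and not _match(s0):
        s0 += 1
    while e0 > s0 and not _match(e0 - 1):
        e0 -= 1
    if e0 - s0 < 2 * p:
        return None
    matches = sum(1 for i in range(s0, e0) if _match(i))
    purity = matches / (e0 - s0)
    if purity < min_purity:
        # salvage the best-scoring local segment of the candidate
        penalty = max(2, int(round(min_purity / max(1e-9, 1 - min_purity))))
        best = cur = 0
        best_span = None
        cur_start = s0
        for i in range(s0, e0):
            sc = 1 if _match(i) else -penalty
            if cur <= 0:
                cur, cur_start = 0, i
            cur += sc
            if cur > best:
                best, best_span = cur, (cur_start, i + 1)
        if best_span is None:
            return None
        s0, e0 = best_span
        if e0 - s0 < 2 * p:
            return None
        matches = sum(1 for i in range(s0, e0) if _match(i))
        purity = matches / (e0 - s0)
        if purity < min_purity:
            return None
    copies = (e0 - s0) / p
    if copies < min_copies:
        return None
    phase_unit = "".join(unit[(s0 - a + j) % p] for j in range(p))
    return TandemLocus(seq_id, s0, e0, min_rotation(phase_unit), p, copies, purity)


def _runs_from_matches(m: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open intervals."""
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(len(m))
    return list(zip(starts, ends))


def _merge_runs(runs: list[tuple[int, int]], p: int, min_purity: float,
                min_span: int) -> list[tuple[int, int]]:
    """Greedily bridge nearby runs into degenerate-array candidates.

    A single substitution in a period-p array knocks out two isolated
    positions of the shifted-match profile, so gaps of up to 2 are bridged;
    the merged match fraction must stay above the corresponding profile-level
    floor (a base mismatch costs up to two profile positions, hence
    2*min_purity - 1)."""
    merged: list[list[int]] = []  # [start, end, matched]
    floor = max(0.0, 2 * min_purity - 1)
    for s, e in runs:
        if merged:
            ms, me, mm = merged[-1]
            gap = s - me
            if gap <= 2 and (mm + (e - s)) / (e - ms) >= floor:
                merged[-1] = [ms, e, mm + (e - s)]
                continue
        merged.append([s, e, e - s])
    return [(s, e) for s, e, _m in merged if (e - s) + p >= min_span]


def find_tandem(
    seq: str,
    seq_id: str = "seq",
    min_unit: int = 1,
    max_unit: int = 100,
    min_copies: float = 2.0,
    min_purity: float = 0.8,
) -> list[TandemLocus]:
    """Detect tandem arrays with unit length in [min_unit, max_unit].

    Every maximal window whose best period yields >= min_copies copies at
    >= min_purity is reported once with its canonical unit; for a given span
    the smallest qualifying period wins (multimeric echoes are suppressed
    here and again in filter_multimeric).  Perfect arrays are always found at
    exact spans; degenerate arrays are best-effort at the stated purity.
    """
    if not (1 <= min_unit <= max_unit):
        raise ValueError("need 1 <= min_unit <= max_unit")
    L = len(seq)
    if L == 0:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    found: dict[tuple[int, int], TandemLocus] = {}

    def _consider(loc: TandemLocus | None):
        if loc is None:
            return
        key = (loc.start, loc.end)
        prev = found.get(key)
        if prev is None or loc.unit_len < prev.unit_len:
            found[key] = loc

    for p in range(min_unit, min(_SMALL_PERIOD_MAX, max_unit) + 1):
        if L <= p:
            break
        # span must reach both 2 units and min_copies units (purity-adjusted)
        min_span = max(2 * p, int(np.ceil(min_copies * p * min_purity)))
        m = arr[:-p] == arr[p:]
        for s, e in _merge_runs(_runs_from_matches(m), p, min_purity, min_span):
            _consider(_refine(seq, s, e + p, p, min_copies, min_purity, seq_id, min_unit))

    if max_unit > _SMALL_PERIOD_MAX and L > _SEED_LEN:
        # larger units: repeated 12-mers at spacing d seed a period-d check
        last_pos: dict[bytes, int] = {}
        candidates: dict[int, list[int]] = {}
        step_view = arr.tobytes()
        for i in range(L - _SEED_LEN + 1):
            w = step_view[i : i + _SEED_LEN]
            j = last_pos.get(w)
            if j is not None:
                d = i - j
                if _SMALL_PERIOD_MAX < d <= max_unit:
                    candidates.setdefault(d, []).append(j)
            last_pos[w] = i
        for d, seeds in candidates.items():
            min_span = max(2 * d, int(np.ceil(min_copies * d * min_purity)))
            m = arr[:-d] == arr[d:]
            seed_set = sorted(set(seeds))
            for s, e in _merge_runs(_runs_from_matches(m), d, min_purity, min_span):
                # only candidates anchored by a repeated-seed observation
                if any(s <= pos < e for pos in seed_set):
                    _consider(_refine(seq, s, e + d, d, min_copies, min_purity, seq_id, min_unit))

    # suppress same-span multimeric echoes that landed on shifted spans
    loci = sorted(found.values(), key=lambda t: (t.start, t.end, t.unit_len))
    return loci


def filter_multimeric(
    loci: list[TandemLocus],
    interspersed_mask: list[tuple[int, int]] | None = None,
) -> list[TandemLocus]:
    """Collapse whole-multiple duplicate units and resolve nesting; flag loci
    mostly inside interspersed-repeat masks.

    A locus whose unit is a whole-number concatenation of a smaller reported
    unit over the same span is dropped in favour of the smaller unit; fully
    nested spans are dropped in favour of the enclosing locus.  A locus with
    > 50% of its span inside ``interspersed_mask`` is retained but flagged
    (and excluded from tandem coverage totals).  Idempotent.
    """
    by_span: dict[tuple[str, int, int], TandemLocus] = {}
    for loc in sorted(loci, key=lambda t: (t.seq_id, t.start, t.end, t.unit_len)):
        key = (loc.seq_id, loc.start, loc.end)
        prev = by_span.get(key)
        if prev is None:
            by_span[key] = loc
            continue
        big, small = (loc, prev) if loc.unit_len >= prev.unit_len else (prev, loc)
        ratio, rem = divmod(big.unit_len, small.unit_len)
        if rem == 0 and min_rotation(small.unit * ratio) == big.unit:
            by_span[key] = small
        elif loc.unit_len < prev.unit_len:
            by_span[key] = loc

    # drop fully nested spans (keep the enclosing locus)
    out: list[TandemLocus] = []
    for loc in sorted(by_span.values(), key=lambda t: (t.seq_id, t.start, -(t.end))):
        if out and out[-1].seq_id == loc.seq_id and loc.start >= out[-1].start and loc.end <= out[-1].end:
            continue
        out.append(loc)

    if interspersed_mask:
        mask = sorted(interspersed_mask)
        for loc in out:
            ov = sum(
                max(0, min(loc.end, e) - max(loc.start, s)) for s, e in mask
            )
            loc.flagged_interspersed = ov > 0.5 * loc.span
    return out


def tandem_coverage(loci: list[TandemLocus]) -> int:
    """Union bp of unflagged tandem loci."""
    ivals = sorted((t.start, t.end) for t in loci if not t.flagged_interspersed)
    total = 0
    cur_s = cur_e = None
    for s, e in ivals:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        total += cur_e - cur_s
    return total


# ---------------------------------------------------------------------------
# motif arrays (telomere / centromere presets)


@dataclass
class MotifScanResult:
    motif: str
    loci: list[tuple[int, int]]
    n_loci: int
    total_bp: int


def motif_scan(
    seq: str,
    motif: str,
    allow_rotations: bool = True,
    max_divergence: float = 0.0,
) -> MotifScanResult:
    """Count maximal runs of >= 2 tandem motif copies, either strand.

    Any rotation of the motif may start the array when ``allow_rotations``;
    each copy may diverge from the motif by at most ``max_divergence``
    (per-copy mismatch fraction)."""
    if len(motif) < 2:
        raise ValueError("motif length must be >= 2")
    if not (0 <= max_divergence <= 0.2):
        raise ValueError("max_divergence must lie in [0, 0.2]")
    m = len(motif)
    variants: set[str] = set()
    for base in (motif, revcomp(motif)):
        if allow_rotations:
            variants.update(base[i:] + base[:i] for i in range(m))
        else:
            variants.add(base)
    max_mm = int(max_divergence * m)

    def _copy_ok(pos: int, v: str) -> bool:
        w = seq[pos : pos + m]
        if len(w) < m:
            return False
        if max_mm == 0:
            return w == v
        return sum(a != b for a, b in zip(w, v)) <= max_mm

    # exact occurrences of any variant anchor the arrays
    anchors: list[tuple[int, str]] = []
    for v in sorted(variants):
        p = seq.find(v)
        while p != -1:
            anchors.append((p, v))
            p = seq.find(v, p + 1)
    anchors.sort()

    loci: list[tuple[int, int]] = []
    for pos, v in anchors:
        if loci and pos < loci[-1][1]:
            continue
        a = pos
        while a - m >= 0 and _copy_ok(a - m, v):
            a -= m
        b = pos + m
        while _copy_ok(b, v):
            b += m
        if loci and a < loci[-1][1]:
            a = loci[-1][1] if (loci[-1][1] - a) % m else a  # guard re-count
            if a >= b or (b - a) < 2 * m:
                continue
        if (b - a) // m >= 2:
            loci.append((a, b))
    loci = sorted(set(loci))
    total = sum(e - s for s, e in loci)
    return MotifScanResult(motif, loci, len(loci), total)


# ---------------------------------------------------------------------------
# library masking


def mask_by_library(
    seq: str,
    library: list[tuple[str, str]],
    seed_len: int = 15,
    min_identity: float = 0.8,
    min_hit: int = 80,
) -> tuple[list[tuple[int, int]], float]:
    """Similarity masking against a repeat library.

    Returns merged masked intervals on ``seq`` and the masked fraction."""
    if not library:
        raise ValueError("library must be nonempty")
    intervals: list[tuple[int, int]] = []
    targets = {"genome": seq}
    for name, element in library:
        for h in seeded_align(element, targets, seed_len=seed_len, query_id=name):
            if h.identity >= min_identity and (h.target_span[1] - h.target_span[0]) >= min_hit:
                intervals.append(h.target_span)
    intervals.sort()
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    masked = sum(e - s for s, e in merged)
    return merged, masked / len(seq) if seq else 0.0


# ---------------------------------------------------------------------------
# summary


@dataclass
class RepeatSummary:
    genome_bp: int
    per_unit_size: dict[int, dict]  # unit_len -> {n, density_per_mbp, mean_len, bp}
    class_totals: dict[str, dict]  # microsatellite / minisatellite / satellite
    motif_totals: dict[str, dict]  # motif -> {n_loci, bp}
    masked_fraction: float
    tandem_coverage_bp: int
    tandem_fraction: float
    include_mononucleotide: bool = True

    def to_dict(self) -> dict:
        return {
            "genome_bp": self.genome_bp,
            "per_unit_size": {str(k): v for k, v in sorted(self.per_unit_size.items())},
            "class_totals": self.class_totals,
            "motif_totals": self.motif_totals,
            "masked_fraction": self.masked_fraction,
            "tandem_coverage_bp": self.tandem_coverage_bp,
            "tandem_fraction": self.tandem_fraction,
            "include_mononucleotide": self.include_mononucleotide,
        }


def _size_class(unit_len: int) -> str:
    if unit_len <= 9:
        return "microsatellite"
    if unit_len <= 100:
        return "minisatellite"
    return "satellite"


def summarize(
    loci: list[TandemLocus],
    motif_results: list[MotifScanResult] | None,
    masked_fraction: float,
    genome_bp: int,
    include_mononucleotide: bool = True,
) -> RepeatSummary:
    """Per-unit-size densities (loci per Mbp of non-N sequence) and mean
    array lengths, satellite class totals, motif totals, and the tandem
    coverage fraction.  Mononucleotide loci can be excluded, matching the
    convention of cross-species microsatellite comparisons."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    use = [t for t in loci if include_mononucleotide or t.unit_len > 1]
    per_size: dict[int, dict] = {}
    for t in use:
        d = per_size.setdefault(t.unit_len, {"n": 0, "bp": 0})
        d["n"] += 1
        d["bp"] += t.span
    for ul, d in per_size.items():
        d["density_per_mbp"] = d["n"] / (genome_bp / 1e6)
        d["mean_len"] = d["bp"] / d["n"]
    class_totals: dict[str, dict] = {
        c: {"n": 0, "bp": 0} for c in ("microsatellite", "minisatellite", "satellite")
    }
    for t in use:
        c = class_totals[_size_class(t.unit_len)]
        c["n"] += 1
        c["bp"] += t.span
    cov = tandem_coverage(use)
    motif_totals = {
        r.motif: {"n_loci": r.n_loci, "bp": r.total_bp} for r in (motif_results or [])
    }
    return RepeatSummary(
        genome_bp=genome_bp,
        per_unit_size=per_size,
        class_totals=class_totals,
        motif_totals=motif_totals,
        masked_fraction=masked_fraction,
        tandem_coverage_bp=cov,
        tandem_fraction=cov / genome_bp,
        include_mononucleotide=include_mononucleotide,
    )
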