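"""QC metric contracts: N50, seeded alignment, validation, transcript and
core-gene classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import haplasm as H
from haplasm._seq import revcomp
from haplasm.qc import n50, seeded_align, validate_against


def brute_n50(lengths):
    """Direct transcription of the definition: largest L such that elements
    of length >= L sum to >= half the total."""
    total = sum(lengths)
    best = 0
    for L in set(lengths):
        if sum(x for x in lengths if x >= L) * 2 >= total:
            best = max(best, L)
    return best


def test_n50_frozen():
    assert n50([20, 12, 8, 5]) == 12
    assert n50([10]) == 10
    assert n50([1, 1, 1, 1]) == 1
    assert n50([100, 1, 1]) == 100


def test_n50_validation():
    with pytest.raises(ValueError):
        n50([])
    with pytest.raises(ValueError):
        n50([10, 0])


@given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=60))
def test_n50_matches_brute_force(lengths):
    assert n50(lengths) == brute_n50(lengths)


def test_assembly_stats(small_assembly, small_truth):
    stats = H.assembly_stats(small_assembly.contigs)
    assert stats.n_contigs >= 1
    assert stats.total_contig_bp > 0.95 * len(small_truth.haplotype_A)
    assert stats.contig_n50 >= stats.total_contig_bp / (stats.n_contigs or 1) / 2
    assert 0.3 < stats.gc_fraction < 0.5


def test_assembly_stats_min_len_excludes_short():
    stats = H.assembly_stats(["A" * 1000, "C" * 50])
    assert stats.n_contigs == 1 and stats.total_contig_bp == 1000


# ---------------------------------------------------------------------------
# seeded aligner


def test_align_exact_substring(small_truth):
    g = small_truth.haplotype_A
    q = g[3_000:3_500]
    (h,) = seeded_align(q, {"g": g[2_000:5_000]})
    assert h.strand == "+"
    assert h.identity == 1.0 and h.query_coverage == 1.0
    assert h.target_span == (1_000, 1_500)
    assert h.query_span == (0, 500)


def test_align_reverse_strand(small_truth):
    g = small_truth.haplotype_A
    q = revcomp(g[3_000:3_500])
    (h,) = seeded_align(q, {"g": g[2_000:5_000]})
    assert h.strand == "-"
    assert h.identity == 1.0
    assert h.target_span == (1_000, 1_500)


def test_align_with_substitutions(small_truth):
    g = small_truth.haplotype_A
    q = list(g[3_000:3_500])
    for pos in (100, 250, 400):
        q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
    (h,) = seeded_align("".join(q), {"g": g[2_000:5_000]})
    assert h.query_coverage > 0.99
    assert abs(h.identity - 497 / 500) < 0.004


def test_align_partial_query(small_truth):
    """Only the query's second half matches: the hit must report that half,
    not a clipped or shifted fragment (regression for HW whole-query mode)."""
    g = small_truth.haplotype_A
    rng = np.random.default_rng(0)
    junk = "".join(rng.choice(list("ACGT"), size=800))
    q = junk + g[4_000:4_800]
    (h,) = seeded_align(q, {"g": g[2_000:6_000]})
    # boundaries may shift by a couple of bases when flanking junk matches
    # the target by chance; the match core must be reported intact
    assert abs(h.target_span[0] - 2_000) <= 3 and abs(h.target_span[1] - 2_800) <= 3
    assert abs(h.query_span[0] - 800) <= 3 and abs(h.query_span[1] - 1_600) <= 3
    assert h.identity > 0.99
    assert abs(h.query_coverage - 0.5) < 0.01


def test_align_no_hit(small_truth):
    assert seeded_align("ACGT" * 30, {"g": "TTTT" * 300}) == []


def test_align_seed_len_validation():
    with pytest.raises(ValueError):
        seeded_align("A" * 100, {"g": "A" * 100}, seed_len=10)


def test_align_two_separate_hits(small_truth):
    g = small_truth.haplotype_A
    q = g[1_000:1_400] + g[8_000:8_400]
    hits = seeded_align(q, {"g": g})
    spans = sorted(h.target_span for h in hits)
    assert len(spans) == 2
    assert abs(spans[0][0] - 1_000) <= 3 and abs(spans[0][1] - 1_400) <= 3
    assert abs(spans[1][0] - 8_000) <= 3 and abs(spans[1][1] - 8_400) <= 3


# ---------------------------------------------------------------------------
# validation report


def test_validate_self_consistent(small_truth):
    g = small_truth.haplotype_A
    assembly = {"c0": g[:11_000], "c1": g[11_000:]}
    rep = validate_against(assembly, [("v0", g)], min_len=20_000)
    assert rep.n_passing_min_len == 1
    assert rep.total_validated_bp == len(g)  # regression: bp, not tuple count
    assert rep.covered_fraction > 0.99
    assert rep.n_high_similarity == 1
    assert rep.implied_error_rate < 0.005
    assert not rep.degenerate


def test_validate_min_len_gate(small_truth):
    g = small_truth.haplotype_A
    rep = validate_against({"c0": g}, [("v0", g[:5_000])], min_len=20_000)
    assert rep.degenerate and rep.n_passing_min_len == 0


def test_validate_unrelated_contig(small_truth):
    g = small_truth.haplotype_A
    rng = np.random.default_rng(1)
    other = "".join(rng.choice(list("ACGT"), size=25_000))
    rep = validate_against({"c0": g}, [("v0", other)], min_len=20_000)
    assert rep.n_aligned == 0 and rep.covered_fraction < 0.05


# ---------------------------------------------------------------------------
# transcript classification boundaries


def _mutated(seq, n, seed=0):
    rng = np.random.default_rng(seed)
    s = list(seq)
    for pos in rng.choice(len(s), size=n, replace=False):
        s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
    return "".join(s)


def test_classify_transcripts_thresholds(small_truth):
    g = small_truth.haplotype_A
    assembly = {"c0": g}
    perfect = g[2_000:3_000]
    # identity ~0.985: passes 0.98 identity in both presets
    near = _mutated(perfect, 15)
    # coverage 0.96: passes min_coverage 0.95, fails 0.98
    chopped = g[2_000:2_960] + "ACGT" * 10
    counts_de_novo = H.classify_transcripts(
        [("a", perfect), ("b", near), ("c", chopped)], assembly,
        min_identity=0.98, min_coverage=0.95)
    assert counts_de_novo == {"aligned_unique": 3, "multi": 0, "unaligned": 0}
    counts_est = H.classify_transcripts(
        [("a", perfect), ("b", near), ("c", chopped)], assembly,
        min_identity=0.98, min_coverage=0.98)
    assert counts_est == {"aligned_unique": 2, "multi": 0, "unaligned": 1}


def test_classify_transcripts_multi_and_unaligned(small_truth):
    g = small_truth.haplotype_A
    seg = g[2_000:3_000]
    assembly = {"c0": g, "c1": seg}  # duplicate region -> multi
    rng = np.random.default_rng(2)
    junk = "".join(rng.choice(list("ACGT"), size=1_000))
    counts = H.classify_transcripts([("dup", seg), ("junk", junk)], assembly)
    assert counts == {"aligned_unique": 0, "multi": 1, "unaligned": 1}


# ---------------------------------------------------------------------------
# core genes


def test_core_gene_scan(small_truth):
    g = small_truth.haplotype_A
    assembly = {"c0": g[:10_000]}
    full = g[1_000:2_000]          # fully present
    partial = g[9_500:10_500]      # half present
    rng = np.random.default_rng(3)
    absent = "".join(rng.choice(list("ACGT"), size=1_000))
    rep = H.core_gene_scan([("f", full), ("p", partial), ("x", absent)], assembly)
    assert rep["full_length"] == 1
    assert rep["partial"] == 1
    assert rep["absent"] == 1
    assert rep["per_gene"]["f"] == "full_length"
    assert rep["full_length_fraction"] == 0.5


def test_core_gene_scan_validation():
    with pytest.raises(ValueError):
        H.core_gene_scan([], {"c": "ACGT"})
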