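"""Tandem scanner, motif arrays, masking, and summary contracts."""

import numpy as np
import pytest

import haplasm as H
from haplasm._seq import revcomp
from haplasm.repeats import TELOMERE_MOTIF, find_tandem, motif_scan


def units(loci):
    return [(t.start, t.end, t.unit) for t in loci]


def test_perfect_dinucleotide_exact_span():
    loci = find_tandem("TTTAGAGAGAGAGAGCCCC", min_unit=2, max_unit=6)
    assert units(loci) == [(3, 15, "AG")]
    (t,) = loci
    assert t.copies == 6.0 and t.purity == 1.0 and t.unit_len == 2


def test_mononucleotide_run():
    loci = find_tandem("GGAAAAAAGG", max_unit=3)
    assert units(loci) == [(2, 8, "A")]


def test_degenerate_array_single_substitution():
    """An 8 bp AC array with one central substitution must be reported as a
    single locus over the full span with purity 7/8."""
    loci = find_tandem("ACACGCAC", min_unit=2, max_unit=4, min_purity=0.8)
    assert len(loci) == 1
    (t,) = loci
    assert (t.start, t.end) == (0, 8)
    assert t.unit == "AC"
    assert abs(t.purity - 7 / 8) < 1e-9


def test_purity_floor_excludes_noise():
    assert find_tandem("ACGTTGCAAC", min_unit=2, max_unit=4, min_purity=0.95) == []


def test_unit_reported_as_min_rotation():
    loci = find_tandem("TTGATGATGATGACC", min_unit=3, max_unit=5)
    (t,) = loci
    assert t.unit == "ATG"  # canonical rotation of TGA/GAT/ATG


def test_large_unit_via_seed_spacing():
    unit = "ACGTTGCAGGCTAATCGAT"  # 19 bp
    s = "TTT" + unit * 5 + "CCC"
    loci = [t for t in find_tandem(s, min_unit=13, max_unit=40, min_copies=3)
            if t.unit_len == 19]
    assert len(loci) == 1
    (t,) = loci
    assert t.start <= 3 and t.end >= 3 + 19 * 5
    assert t.purity > 0.95


def test_multimer_echo_rejected():
    # a perfect AT array must not also be reported at periods 4/6/8
    s = "G" * 5 + "AT" * 30 + "C" * 5
    loci = find_tandem(s, min_unit=2, max_unit=10, min_copies=3)
    assert {t.unit_len for t in loci} == {2}


def test_min_copies_gate():
    s = "TTT" + "ACGGT" * 3 + "CCC"
    assert find_tandem(s, min_unit=5, max_unit=5, min_copies=4.0) == []
    loci = find_tandem(s, min_unit=5, max_unit=5, min_copies=3.0)
    assert len(loci) == 1


def test_find_tandem_validation_and_empty():
    with pytest.raises(ValueError):
        find_tandem("ACGT", min_unit=0)
    assert find_tandem("", min_unit=1) == []


def test_filter_multimeric_nested_spans():
    a = H.TandemLocus("s", 10, 50, "AC", 2, 20.0, 1.0)
    inner = H.TandemLocus("s", 15, 35, "CA", 2, 10.0, 1.0)
    out = H.filter_multimeric([a, inner])
    assert out == [a]
    # idempotent
    assert H.filter_multimeric(out) == [a]


def test_filter_multimeric_interspersed_flag():
    a = H.TandemLocus("s", 0, 100, "AC", 2, 50.0, 1.0)
    b = H.TandemLocus("s", 500, 540, "AC", 2, 20.0, 1.0)
    out = H.filter_multimeric([a, b], interspersed_mask=[(0, 80)])
    flags = {(t.start, t.end): t.flagged_interspersed for t in out}
    assert flags[(0, 100)] is True  # 80% inside the mask
    assert flags[(500, 540)] is False
    # flagged loci are excluded from coverage
    assert H.tandem_coverage(out) == 40


def test_tandem_coverage_merges_overlaps():
    a = H.TandemLocus("s", 0, 30, "A", 1, 30.0, 1.0)
    b = H.TandemLocus("s", 20, 50, "C", 1, 30.0, 1.0)
    assert H.tandem_coverage([a, b]) == 50


# ---------------------------------------------------------------------------
# motif arrays


def test_motif_scan_basic():
    s = "A" * 10 + TELOMERE_MOTIF * 8 + "C" * 10
    r = motif_scan(s, TELOMERE_MOTIF)
    assert r.n_loci == 1
    assert r.loci == [(10, 10 + 7 * 8)]
    assert r.total_bp == 56


def test_motif_scan_reverse_strand():
    s = "A" * 10 + revcomp(TELOMERE_MOTIF * 5) + "C" * 10
    r = motif_scan(s, TELOMERE_MOTIF)
    assert r.n_loci == 1 and r.total_bp == 35


def test_motif_scan_rotation_start():
    motif = "TTTAGGG"
    rotated = motif[3:] + motif[:3]
    s = "C" * 8 + rotated * 4 + "A" * 8
    assert motif_scan(s, motif, allow_rotations=True).n_loci == 1
    assert motif_scan(s, motif, allow_rotations=False).n_loci == 1  # interior anchor
    single = "C" * 8 + motif + "A" * 8
    assert motif_scan(single, motif).n_loci == 0  # one copy is not an array


def test_motif_scan_divergence():
    copies = [TELOMERE_MOTIF] * 6
    copies[3] = "TTAAGGG"  # one substitution in one copy
    s = "C" * 5 + "".join(copies) + "A" * 5
    strict = motif_scan(s, TELOMERE_MOTIF, max_divergence=0.0)
    loose = motif_scan(s, TELOMERE_MOTIF, max_divergence=0.15)
    assert loose.total_bp >= strict.total_bp
    assert loose.n_loci == 1 and loose.total_bp == 42


def test_motif_scan_validation():
    with pytest.raises(ValueError):
        motif_scan("ACGT", "A")
    with pytest.raises(ValueError):
        motif_scan("ACGT", "ACG", max_divergence=0.5)


# ---------------------------------------------------------------------------
# library masking and summary


def test_mask_by_library(small_truth):
    g = small_truth.haplotype_A
    lib = [("elt", g[2_000:2_400])]
    intervals, frac = H.mask_by_library(g[:10_000], lib)
    assert len(intervals) == 1
    s, e = intervals[0]
    assert abs(s - 2_000) <= 5 and abs(e - 2_400) <= 5
    assert abs(frac - 0.04) < 0.005
    with pytest.raises(ValueError):
        H.mask_by_library(g[:1_000], [])


def test_summarize_densities_and_classes():
    loci = [
        H.TandemLocus("s", 0, 30, "A", 1, 30.0, 1.0),
        H.TandemLocus("s", 100, 140, "AC", 2, 20.0, 1.0),
        H.TandemLocus("s", 500, 800, "ACGTTGCAGGCT", 12, 25.0, 1.0),
    ]
    summ = H.summarize(loci, None, 0.1, 1_000_000)
    d = summ.to_dict()
    assert d["per_unit_size"]["1"]["n"] == 1
    assert d["per_unit_size"]["2"]["density_per_mbp"] == 1.0
    assert d["class_totals"]["microsatellite"]["n"] == 2
    assert d["class_totals"]["minisatellite"]["n"] == 1
    assert d["tandem_coverage_bp"] == 370
    # mononucleotide exclusion drops the unit-1 locus everywhere
    no_mono = H.summarize(loci, None, 0.1, 1_000_000, include_mononucleotide=False)
    assert "1" not in no_mono.to_dict()["per_unit_size"]
    assert no_mono.tandem_coverage_bp == 340
    with pytest.raises(ValueError):
        H.summarize(loci, None, 0.0, 0)


def test_planted_arrays_recovered_exactly():
    fams = [
        H.RepeatFamily("at", "tandem", unit="AT", copies=25, n_loci=4),
        H.RepeatFamily("aag", "tandem", unit="AAG", copies=15, n_loci=4),
    ]
    truth = H.gen_diploid_genome(60_000, repeat_spec=fams, seed=41)
    loci = H.filter_multimeric(
        find_tandem(truth.haplotype_A, min_unit=2, max_unit=20,
                    min_copies=10, min_purity=1.0))
    det = {(t.start, t.end) for t in loci}
    for s, e, _f, _k in truth.planted_repeats:
        assert (s, e) in det
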