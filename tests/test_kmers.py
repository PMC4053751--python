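"""K-mer database, error correction, and diploid-filter contracts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import haplasm as H
from haplasm._seq import canonical, revcomp
from haplasm.kmers import KmerDB, error_correct, solid_kmer_fraction


def naive_canonical_counts(seqs, k):
    counts = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" in w:
                continue
            c = canonical(w)
            counts[c] = counts.get(c, 0) + 1
    return counts


def test_count_kmers_frozen():
    db = H.count_kmers(["ACGTA"], k=3)
    # ACG and CGT share canonical form ACG; GTA (rc TAC) is its own canonical
    assert db.counts == {"ACG": 2, "GTA": 1}
    assert db.get("ACG") == 2 and db.get("CGT") == 2
    assert db.get("GTA") == 1 and db.get("TAC") == 1
    assert db.get("AAA") == 0


def test_count_kmers_validation():
    with pytest.raises(ValueError):
        H.count_kmers(["ACGT"], k=4)  # even
    with pytest.raises(ValueError):
        H.count_kmers(["ACGT"], k=103)


def test_count_kmers_skips_n():
    db = H.count_kmers(["ACNGT"], k=3)
    assert db.counts == {}
    db = H.count_kmers(["ACGNACG"], k=3)
    assert db.counts == {"ACG": 2}


@given(st.lists(st.text(alphabet="ACGTN", min_size=0, max_size=40), max_size=6),
       st.sampled_from([3, 5, 7]))
def test_count_kmers_matches_naive(seqs, k):
    db = H.count_kmers(seqs, k)
    assert db.counts == naive_canonical_counts(seqs, k)


def test_db_save_load_roundtrip(tmp_path):
    db = H.count_kmers(["ACGTACGTAA"], k=5, solid_threshold=3)
    p = tmp_path / "db.tsv"
    db.save(p)
    back = KmerDB.load(p)
    assert back.k == 5 and back.solid_threshold == 3
    assert back.counts == db.counts


def test_suggest_solid_threshold_bimodal():
    # error peak at 1, coverage peak at 30, valley in between
    counts = {}
    i = 0
    for c, n in [(1, 500), (2, 60), (3, 5), (4, 2), (29, 100), (30, 300), (31, 100)]:
        for _ in range(n):
            counts[f"k{i}"] = c
            i += 1
    db = KmerDB(21, counts)
    thr = H.suggest_solid_threshold(db)
    assert 4 <= thr <= 29  # above the valley, below the coverage peak


def test_suggest_solid_threshold_shallow_fallback():
    db = KmerDB(21, {"a": 1, "b": 2, "c": 3})
    assert H.suggest_solid_threshold(db) == 2
    assert H.suggest_solid_threshold(KmerDB(21, {})) == 2


# ---------------------------------------------------------------------------
# correction


@pytest.fixture(scope="module")
def clean_db(small_reads):
    db = H.count_kmers(small_reads, k=21)
    db.solid_threshold = 2
    return db


def test_correct_clean_read_is_solid(small_truth, clean_db):
    read = small_truth.haplotype_A[1_000:1_100]
    res = error_correct(read, clean_db)
    assert res.status == "solid" and res.n_corrections == 0
    assert res.sequence == read


def test_correct_single_substitution(small_truth, clean_db):
    read = small_truth.haplotype_A[1_000:1_100]
    for pos in (0, 13, 50, 99):
        bad = list(read)
        bad[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[pos]]
        res = error_correct("".join(bad), clean_db)
        assert res.status == "corrected", pos
        assert res.sequence == read, pos
        assert res.n_corrections == 1


def test_correct_too_short_and_uncorrectable(clean_db):
    assert error_correct("ACGT", clean_db).status == "too_short"
    junk = "AC" * 50  # not in the genome's spectrum
    res = error_correct(junk, clean_db, max_corrections=3)
    assert res.status == "uncorrectable"
    assert res.sequence == junk  # returned unchanged


def test_correct_readset_tally(small_truth, small_reads, clean_db):
    sub = H.subset_readset(small_reads, [r.id for r in small_reads.reads[:50]])
    out, tally, statuses = H.correct_readset(sub, clean_db)
    assert sum(tally.values()) == 50
    assert tally["solid"] == 50  # error-free input
    assert set(statuses) == {r.id for r in sub.reads}
    assert [r.id for r in out.reads] == [r.id for r in sub.reads]


# ---------------------------------------------------------------------------
# diploid filtering


def test_solid_kmer_fraction_window_arithmetic(small_truth, clean_db):
    """One mismatch at offset p in a read of length L kills the windows
    overlapping it: min(p, L-k+1... ) — frozen arithmetic on a known case."""
    g = small_truth.haplotype_A
    read = g[2_000:2_122]  # L=122, k=21 -> 102 windows
    assert solid_kmer_fraction(read, clean_db) == 1.0
    bad = list(read)
    bad[60] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[60]]
    # windows covering position 60: starts 40..60 -> 21 windows lost
    frac = solid_kmer_fraction("".join(bad), clean_db)
    assert abs(frac - (102 - 21) / 102) < 1e-9


def test_filter_keeps_identical_rejects_divergent(small_truth, clean_db):
    g = small_truth.haplotype_A
    reads = [H.Read(f"a{i}/1", g[i * 200 : i * 200 + 100], "I" * 100, f"a{i}/2")
             for i in range(20)]
    mates = [H.Read(f"a{i}/2", g[i * 200 + 150 : i * 200 + 250], "I" * 100, f"a{i}/1")
             for i in range(20)]
    rng = np.random.default_rng(0)
    divergent = []
    for i in range(20):
        s = list(g[i * 200 : i * 200 + 100])
        for pos in rng.choice(100, size=5, replace=False):  # 5% divergence
            s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
        divergent.append(H.Read(f"d{i}", "".join(s), "I" * 100))
    rs = H.ReadSet(reads + mates + divergent, "paired_end", 300, 25, 0.0, "diploid")
    rep = H.filter_diploid_reads(rs, clean_db, min_fraction=0.9)
    assert all(r.id in rep.kept for r in reads + mates)
    assert all(r.id in rep.rejected for r in divergent)
    assert all(rep.reasons[r.id] == "divergent" for r in divergent)


def test_filter_pairs_judged_jointly(small_truth, clean_db):
    g = small_truth.haplotype_A
    good = H.Read("p/1", g[100:200], "I" * 100, "p/2")
    bad = H.Read("p/2", "AC" * 50, "I" * 100, "p/1")
    rs = H.ReadSet([good, bad], "paired_end", 300, 25, 0.0, "diploid")
    rep = H.filter_diploid_reads(rs, clean_db)
    assert rep.kept == []
    assert rep.reasons["p/1"] == "mate_failed"
    assert rep.reasons["p/2"] == "divergent"


def test_filter_too_short(clean_db):
    rs = H.ReadSet([H.Read("s", "ACGT", "IIII")], "paired_end", 300, 25, 0.0, "x")
    rep = H.filter_diploid_reads(rs, clean_db)
    assert rep.rejected == ["s"] and rep.reasons["s"] == "too_short"


def test_filter_monotone_in_min_fraction(small_truth, clean_db, small_reads):
    sub = H.subset_readset(small_reads, [r.id for r in small_reads.reads[:200]])
    kept_sets = []
    for mf in (0.95, 0.9, 0.5, 0.0):
        kept_sets.append(set(H.filter_diploid_reads(sub, clean_db, mf).kept))
    for a, b in zip(kept_sets, kept_sets[1:]):
        assert a <= b  # lowering the threshold never shrinks the kept set
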