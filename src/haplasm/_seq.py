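"""Shared low-level sequence helpers: complements, GC, k-mer canonicalization, I/O.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases; N is excluded from both numerator
    and denominator. Returns 0.0 for sequences with no unambiguous base."""
    g = seq.count("G") + seq.count("g") + seq.count("C") + seq.count("c")
    n = len(seq) - seq.count("N") - seq.count("n")
    return g / n if n else 0.0


def iter_kmers(seq: str, k: int) -> Iterator[tuple[int, str]]:
    """Yield (offset, k-mer) for every window free of N."""
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w:
            yield i, w


def min_rotation(s: str) -> str:
    """Lexicographically least rotation (Booth-style; n is small here)."""
    best = s
    for i in range(1, len(s)):
        r = s[i:] + s[:i]
        if r < best:
            best = r
    return best


# ---------------------------------------------------------------------------
# Plain-text FASTA/FASTQ I/O.  Records are (id, sequence[, quality]) tuples;
# tuples rather than record objects keep million-read synthetic sets cheap.

def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    records = []
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                break
            seq = fh.readline().rstrip()
            fh.readline()
            qual = fh.readline().rstrip()
            records.append((header[1:].split()[0], seq.upper(), qual))
    return records


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
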