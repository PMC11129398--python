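"""Canonical k-mer extraction and per-color set construction.

A k-mer is *canonical* if it is lexicographically no larger than its reverse
complement; every k-mer set in the pipeline stores canonical forms only, so a
k-mer and its reverse complement are one object. Color sets are built either
from FASTA (all canonical k-mers occurring at least `a` times) or from a
plain-text list of k-mers, one per line.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import InvalidAlphabetError, ParseError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(seq: str) -> str:
    """Return the canonical form: min(seq, revcomp(seq)) lexicographically.

    Raises InvalidAlphabetError on characters outside {A, C, G, T}.
    """
    if not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET)
        raise InvalidAlphabetError(f"non-ACGT characters in k-mer: {bad}")
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@dataclass
class KmerSet:
    """A set of distinct canonical k-mers sharing one k."""

    k: int
    members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        for m in self.members:
            if len(m) != self.k:
                raise ValueError(f"k-mer {m!r} has length {len(m)}, expected {self.k}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)


def _canonical_windows(record: str, k: int) -> Iterator[str]:
    """Yield the canonical form of every clean k-length window of `record`.

    Lowercase is accepted (uppercased); any window touching a non-ACGT
    character (N, IUPAC codes, ...) is skipped.
    """
    seq = record.upper()
    n = len(seq)
    # positions of disallowed characters; a window [i, i+k) is clean iff it
    # contains none of them
    next_bad = n  # index of the next bad char at or after the cursor
    bad = [i for i, ch in enumerate(seq) if ch not in _ALPHABET]
    bad_iter = iter(bad + [n])
    next_bad = next(bad_iter)
    i = 0
    while i + k <= n:
        while next_bad < i:
            next_bad = next(bad_iter)
        if next_bad < i + k:
            i = next_bad + 1  # restart after the offending character
            continue
        yield canonicalize(seq[i : i + k])
        i += 1


def extract_kmers(records: Iterable[str], k: int, a: int = 1) -> KmerSet:
    """Canonical k-mers occurring at least `a` times across `records`.

    Each window contributes one count to its canonical form, so a k-mer and
    its reverse complement pool their occurrences (KMC-style canonical
    counting). Records shorter than k contribute nothing.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if a < 1:
        raise ValueError(f"abundance threshold must be >= 1, got {a}")
    if a == 1:
        members = {w for rec in records for w in _canonical_windows(rec, k)}
        return KmerSet(k, members)
    counts: Counter[str] = Counter()
    for rec in records:
        counts.update(_canonical_windows(rec, k))
    return KmerSet(k, {km for km, c in counts.items() if c >= a})


def read_kmer_list(lines: Iterable[str], k: int) -> KmerSet:
    """Build a KmerSet from one-k-mer-per-line text.

    Lines are canonicalized and deduplicated; blank lines are ignored.
    Raises ParseError naming the offending line on a length or alphabet
    violation.
    """
    members: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip().upper()
        if not line:
            continue
        if len(line) != k:
            raise ParseError(
                f"line {lineno}: k-mer {line!r} has length {len(line)}, expected {k}"
            )
        try:
            members.add(canonicalize(line))
        except InvalidAlphabetError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return KmerSet(k, members)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta_records(path: str | Path) -> list[str]:
    """Sequences of a (possibly gzipped) multi-record FASTA file."""
    with _open_text(path) as handle:
        return [str(rec.seq) for rec in SeqIO.parse(handle, "fasta")]


def load_color(path: str | Path, k: int, a: int = 1) -> KmerSet:
    """Load one color from FASTA (k-mers occurring >= a times) or from a
    plain-text k-mer list (first non-blank character decides the dialect)."""
    with _open_text(path) as handle:
        head = handle.read(1)
    if head == ">":
        return extract_kmers(read_fasta_records(path), k, a)
    with _open_text(path) as handle:
        return read_kmer_list(handle, k)


def union_kmers(colors: list[KmerSet]) -> KmerSet:
    """Union of the colors' canonical k-mer sets; rejects mixed k."""
    if not colors:
        raise ValueError("need at least one color")
    ks = {c.k for c in colors}
    if len(ks) > 1:
        raise ParseError(f"mixed k across colors: {sorted(ks)}")
    members: set[str] = set()
    for c in colors:
        members |= c.members
    return KmerSet(colors[0].k, members)
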