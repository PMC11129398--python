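"""Spectrum-preserving string set (simplitig) construction and k-mer ordering.

An SPSS of a k-mer set K is a set of strings in which every k-mer of K occurs
in exactly one window of exactly one string. Scanning its simplitigs in list
order, windows left to right, induces a total order (rank) on K; that rank is
what aligns the color matrix with the compressed sequence representation.

Construction is greedy: seeds are visited in lexicographic order and extended
maximally right, then left, always picking the lexicographically smallest
unused successor nucleotide. The result is deterministic for a fixed input,
though generally not the minimum-size SPSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

from .errors import ConsistencyError
from .kmer import KmerSet, canonicalize

_NUCS = "ACGT"

Mode = Literal["canonical", "forward_only"]


@dataclass
class SPSS:
    """Ordered simplitig list over a k-mer set."""

    k: int
    simplitigs: list[str]

    def __post_init__(self) -> None:
        for s in self.simplitigs:
            if len(s) < self.k:
                raise ValueError(f"simplitig shorter than k: {s!r}")

    @property
    def n_kmers(self) -> int:
        return sum(len(s) - self.k + 1 for s in self.simplitigs)

    def simplitig_sizes(self) -> list[int]:
        """Per-simplitig k-mer (window) counts."""
        return [len(s) - self.k + 1 for s in self.simplitigs]

    def windows(self) -> Iterator[str]:
        """All window k-mers as written (not canonicalized), in rank order."""
        k = self.k
        for s in self.simplitigs:
            for i in range(len(s) - k + 1):
                yield s[i : i + k]


@dataclass
class KmerOrder:
    """Bijection canonical k-mer -> rank in [0, |K|), plus simplitig sizes."""

    rank: dict[str, int]
    simplitig_sizes: list[int]


def build_spss(kmers: KmerSet, mode: Mode = "canonical") -> SPSS:
    """Greedy simplitig decomposition of a k-mer set.

    canonical mode walks the bidirected de Bruijn graph (a window matches a
    k-mer if its canonical form does); forward_only treats k-mers as literal
    strings with no reverse-complement identification.
    """
    if mode not in ("canonical", "forward_only"):
        raise ValueError(f"unknown mode {mode!r}")
    k = kmers.k
    if not kmers.members:
        return SPSS(k, [])

    key = canonicalize if mode == "canonical" else (lambda s: s)
    unused = set(kmers.members)
    simplitigs: list[str] = []

    for seed in sorted(kmers.members):
        if seed not in unused:
            continue
        unused.discard(seed)
        seq = seed
        # extend right
        while True:
            tail = seq[-(k - 1) :] if k > 1 else ""
            for nt in _NUCS:
                cand = key(tail + nt)
                if cand in unused:
                    unused.discard(cand)
                    seq += nt
                    break
            else:
                break
        # extend left
        while True:
            head = seq[: k - 1] if k > 1 else ""
            for nt in _NUCS:
                cand = key(nt + head)
                if cand in unused:
                    unused.discard(cand)
                    seq = nt + seq
                    break
            else:
                break
        simplitigs.append(seq)

    return SPSS(k, simplitigs)


def kmer_order(spss: SPSS, mode: Mode = "canonical") -> KmerOrder:
    """Rank map induced by the SPSS: simplitigs in list order, windows left
    to right. Raises ConsistencyError if a k-mer occurs in two windows."""
    key = canonicalize if mode == "canonical" else (lambda s: s)
    rank: dict[str, int] = {}
    r = 0
    for w in spss.windows():
        cw = key(w)
        if cw in rank:
            raise ConsistencyError(f"k-mer {cw} appears in two SPSS windows")
        rank[cw] = r
        r += 1
    return KmerOrder(rank, spss.simplitig_sizes())


def spss_kmer_set(spss: SPSS, mode: Mode = "canonical") -> KmerSet:
    """Re-extract the canonical k-mer set represented by an SPSS (used as the
    spectrum-preservation oracle and by the decompressor)."""
    key = canonicalize if mode == "canonical" else (lambda s: s)
    return KmerSet(spss.k, {key(w) for w in spss.windows()})


def write_fasta(spss: SPSS, path: str | Path) -> None:
    """One record per simplitig, headers ``simplitig_<i>``."""
    with open(path, "w") as fh:
        for i, s in enumerate(spss.simplitigs):
            fh.write(f">simplitig_{i}\n{s}\n")
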