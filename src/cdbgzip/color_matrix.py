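"""Color vectors, the SPSS-ordered color matrix, and the class census.

A k-mer's *color vector* is the C-bit indicator of which colors contain it;
its *color class* is the corresponding set of color indices. Vectors are held
as Python integers with color i at bit i, so color 0 is the least significant
bit; when a vector is written to a stream, bits go out in position order
0..C-1. Both conventions are fixed by the archive format (see FORMAT.md).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .errors import ConsistencyError
from .kmer import KmerSet
from .spss import KmerOrder


def vector_to_bits(vec: int, C: int) -> str:
    """Stream rendering of a color vector: positions 0..C-1 in order."""
    return "".join("1" if (vec >> i) & 1 else "0" for i in range(C))


def bits_to_vector(bits: str) -> int:
    vec = 0
    for i, ch in enumerate(bits):
        if ch == "1":
            vec |= 1 << i
    return vec


def class_of(vec: int) -> frozenset[int]:
    """Color-index set of a vector (for display and tests)."""
    return frozenset(i for i in range(vec.bit_length()) if (vec >> i) & 1)


@dataclass
class ColorMatrix:
    """One color vector per union k-mer, row index = SPSS rank."""

    C: int
    rows: list[int]

    def __post_init__(self) -> None:
        if self.C < 1:
            raise ValueError(f"C must be >= 1, got {self.C}")
        for r, vec in enumerate(self.rows):
            if vec == 0:
                raise ConsistencyError(f"row {r} has an all-zero color vector")
            if vec >> self.C:
                raise ConsistencyError(f"row {r} sets a color >= C={self.C}")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class ClassCensus:
    """Distinct color classes with their k-mer multiplicities.

    Classes are kept sorted ascending as C-bit integers, the order the
    serialized global table uses.
    """

    C: int
    classes: list[int]
    freq: dict[int, int]

    @property
    def M(self) -> int:
        return len(self.classes)

    @property
    def n_kmers(self) -> int:
        return sum(self.freq.values())


def build_color_matrix(order: KmerOrder, colors: list[KmerSet]) -> ColorMatrix:
    """Assemble the SPSS-ordered color matrix from the per-color sets.

    Raises ConsistencyError if a colored k-mer is missing from the order
    (the union was built wrongly) or a ranked k-mer has no color.
    """
    C = len(colors)
    n = len(order.rank)
    rows = [0] * n
    for i, color in enumerate(colors):
        bit = 1 << i
        for km in color.members:
            r = order.rank.get(km)
            if r is None:
                raise ConsistencyError(
                    f"k-mer {km} of color {i} is absent from the SPSS order"
                )
            rows[r] |= bit
    return ColorMatrix(C, rows)


def class_census(matrix: ColorMatrix) -> ClassCensus:
    """Distinct rows and their exact multiplicities."""
    counts = Counter(matrix.rows)
    classes = sorted(counts)
    return ClassCensus(matrix.C, classes, dict(counts))


def write_matrix_tsv(matrix: ColorMatrix, kmers_in_order: list[str], path: str | Path) -> None:
    """Debug/decompression output: ``kmer<TAB>color_vector_as_01string``."""
    if len(kmers_in_order) != len(matrix.rows):
        raise ValueError("k-mer list and matrix row count differ")
    with open(path, "w") as fh:
        for km, vec in zip(kmers_in_order, matrix.rows):
            fh.write(f"{km}\t{vector_to_bits(vec, matrix.C)}\n")


def write_matrix_binary(matrix: ColorMatrix, path: str | Path) -> None:
    """Packed row-major matrix: 8-byte header (C, row count as uint32 LE),
    then each row as ceil(C/8) bytes, bit i of the row at byte i//8, bit i%8
    (LSB-first within the byte, matching the integer convention)."""
    import struct

    row_bytes = (matrix.C + 7) // 8
    with open(path, "wb") as fh:
        fh.write(struct.pack("<II", matrix.C, len(matrix.rows)))
        for vec in matrix.rows:
            fh.write(vec.to_bytes(row_bytes, "little"))
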