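"""Global and local class tables.

The global table assigns each distinct color class a prefix-free Huffman code
(its *global ID*), built from the class census so frequent classes get short
codes. Construction is canonical and fully deterministic — heap ties break on
the smaller class integer, and codes are assigned in (length, class-integer)
order — so compressor and decompressor derive bit-identical codes from the
same frequencies.

On disk the table is three members: a color encoding Delta (first class
verbatim in C bits, every later class as the positions where it differs from
its predecessor, each position in ceil(log2 C) bits), a boundary bitvector b
marking where each class starts in Delta, and a text file of frequencies.

A *local* class table remaps the distinct classes of one simplitig onto small
fixed-width local IDs; it pays off when a class recurs in several runs of the
same simplitig.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

from .bitio import BitReader, ceil_log2
from .color_matrix import ClassCensus
from .errors import ConsistencyError, CorruptArchiveError


def index_field_width(C: int) -> int:
    """Width of a color-position field: ceil(log2 C), but never zero."""
    return max(1, ceil_log2(C))


def count_field_width(M: int, ell_cap_3bit: bool = False) -> int:
    """Width of the local-table ell field: ceil(log2 M) (min 1), or a fixed
    3 bits under the ell-cap optimization."""
    if ell_cap_3bit:
        return 3
    return max(1, ceil_log2(M))


@dataclass
class GlobalClassTable:
    """Canonical Huffman global IDs over the class census."""

    census: ClassCensus
    code: dict[int, str]  # class integer -> '0'/'1' code string

    @property
    def C(self) -> int:
        return self.census.C

    @property
    def M(self) -> int:
        return self.census.M

    def decode_tree(self) -> dict:
        """Binary trie {bit: child}; leaves are class integers."""
        root: dict = {}
        for cls, code in self.code.items():
            node = root
            for ch in code[:-1]:
                node = node.setdefault(ch, {})
                if not isinstance(node, dict):
                    raise ConsistencyError("Huffman code is not prefix-free")
            if code[-1] in node:
                raise ConsistencyError("Huffman code is not prefix-free")
            node[code[-1]] = cls
        return root


@dataclass
class SerializedGlobalTable:
    """On-disk triple (Delta, boundary, frequency lines)."""

    delta: str  # '0'/'1' string
    boundary: str  # same length as delta; M ones; first at position 0
    freq_lines: list[str]  # "class_integer<TAB>count", sorted ascending


@dataclass
class LocalClassTable:
    """Maps local IDs 0..ell-1 to global-ID codes, in first-occurrence order."""

    local_to_global: list[int]  # class integers

    @property
    def ell(self) -> int:
        return len(self.local_to_global)

    @property
    def id_width(self) -> int:
        """Fixed width of a local ID: ceil(log2 ell); ell=1 means 0 bits."""
        return ceil_log2(self.ell)


def _huffman_lengths(census: ClassCensus) -> dict[int, int]:
    """Optimal prefix-code lengths; deterministic tie-breaking by the
    smallest class integer contained in each subtree."""
    if census.M == 1:
        return {census.classes[0]: 1}
    # heap entries: (weight, min class integer in subtree, depth map)
    heap: list[tuple[int, int, dict[int, int]]] = [
        (census.freq[c], c, {c: 0}) for c in census.classes
    ]
    heapq.heapify(heap)
    while len(heap) > 1:
        w1, m1, d1 = heapq.heappop(heap)
        w2, m2, d2 = heapq.heappop(heap)
        merged = {c: d + 1 for c, d in d1.items()}
        merged.update({c: d + 1 for c, d in d2.items()})
        heapq.heappush(heap, (w1 + w2, min(m1, m2), merged))
    return heap[0][2]


def _canonical_codes(lengths: dict[int, int]) -> dict[int, str]:
    """Canonical code assignment: shorter lengths first, ties by class
    integer; codewords are consecutive integers at each length."""
    code: dict[int, str] = {}
    current = 0
    prev_len = 0
    for cls in sorted(lengths, key=lambda c: (lengths[c], c)):
        length = lengths[cls]
        current <<= length - prev_len
        code[cls] = format(current, f"0{length}b")
        current += 1
        prev_len = length
    return code


def build_global_table(census: ClassCensus) -> GlobalClassTable:
    """Canonical Huffman code over the census frequencies (M=1 -> code '0')."""
    if census.M < 1:
        raise ValueError("census has no classes")
    return GlobalClassTable(census, _canonical_codes(_huffman_lengths(census)))


def serialize_global_table(table: GlobalClassTable) -> SerializedGlobalTable:
    """Produce the (Delta, boundary, frequencies) triple.

    Classes go out sorted ascending as C-bit integers; the first verbatim
    (positions 0..C-1 in stream order), each later one as its differing
    positions vs. the predecessor, in increasing order, ceil(log2 C) bits
    each, MSB first.
    """
    C = table.C
    w = index_field_width(C)
    delta_parts: list[str] = []
    boundary_parts: list[str] = []
    prev = None
    for cls in table.census.classes:
        if prev is None:
            seg = "".join("1" if (cls >> i) & 1 else "0" for i in range(C))
        else:
            diff = cls ^ prev
            fields = []
            pos = 0
            while diff:
                if diff & 1:
                    fields.append(format(pos, f"0{w}b"))
                diff >>= 1
                pos += 1
            seg = "".join(fields)
        # classes are distinct and sorted, so every segment is non-empty
        delta_parts.append(seg)
        boundary_parts.append("1" + "0" * (len(seg) - 1))
        prev = cls
    delta_str = "".join(delta_parts)
    boundary = "".join(boundary_parts)
    freq_lines = [f"{cls}\t{table.census.freq[cls]}" for cls in table.census.classes]
    return SerializedGlobalTable(delta_str, boundary, freq_lines)


def deserialize_global_table(ser: SerializedGlobalTable, C: int) -> GlobalClassTable:
    """Inverse of serialize_global_table; rebuilds the identical canonical
    Huffman code from the frequency lines."""
    if len(ser.delta) != len(ser.boundary):
        raise CorruptArchiveError(
            f"delta length {len(ser.delta)} != boundary length {len(ser.boundary)}"
        )
    starts = [i for i, ch in enumerate(ser.boundary) if ch == "1"]
    if not starts or starts[0] != 0:
        raise CorruptArchiveError("boundary bitvector must mark position 0")
    starts.append(len(ser.delta))
    w = index_field_width(C)
    classes: list[int] = []
    prev = None
    for seg_start, seg_end in zip(starts, starts[1:]):
        seg = ser.delta[seg_start:seg_end]
        if prev is None:
            if len(seg) != C:
                raise CorruptArchiveError(
                    f"first class segment has {len(seg)} bits, expected C={C}"
                )
            cls = 0
            for i, ch in enumerate(seg):
                if ch == "1":
                    cls |= 1 << i
        else:
            if len(seg) % w:
                raise CorruptArchiveError("diff segment is not a whole number of fields")
            cls = prev
            for j in range(0, len(seg), w):
                pos = int(seg[j : j + w], 2)
                if pos >= C:
                    raise CorruptArchiveError(f"diff index {pos} >= C={C}")
                cls ^= 1 << pos
        classes.append(cls)
        prev = cls

    freq: dict[int, int] = {}
    for line in ser.freq_lines:
        cls_s, count_s = line.split("\t")
        freq[int(cls_s)] = int(count_s)
    if sorted(freq) != classes:
        raise CorruptArchiveError("frequency file classes disagree with Delta/boundary")
    from .color_matrix import ClassCensus as _Census

    return build_global_table(_Census(C, classes, freq))


def build_local_table(
    simplitig_classes: list[int], table: GlobalClassTable
) -> LocalClassTable:
    """Local IDs in first-occurrence order of the simplitig's class sequence."""
    seen: list[int] = []
    seen_set: set[int] = set()
    for cls in simplitig_classes:
        if cls not in seen_set:
            if cls not in table.code:
                raise ConsistencyError(f"class {cls} missing from the global table")
            seen.append(cls)
            seen_set.add(cls)
    return LocalClassTable(seen)


def serialize_local_table(
    lt: LocalClassTable, table: GlobalClassTable, ell_cap_3bit: bool = False
) -> str:
    """Count field holding ell-1 (ceil(log2 M) bits wide, or 3 with the cap),
    then the ell global-ID codes concatenated (self-delimiting)."""
    w = count_field_width(table.M, ell_cap_3bit)
    if lt.ell > (1 << w):
        raise ValueError(f"ell={lt.ell} overflows a {w}-bit count field")
    bits = format(lt.ell - 1, f"0{w}b")
    for cls in lt.local_to_global:
        bits += table.code[cls]
    return bits


def deserialize_local_table(
    reader: BitReader, table: GlobalClassTable, ell_cap_3bit: bool = False
) -> LocalClassTable:
    """Parse one local table off a bit stream."""
    w = count_field_width(table.M, ell_cap_3bit)
    ell = reader.read_uint(w) + 1
    tree = table.decode_tree()
    mapping: list[int] = []
    for _ in range(ell):
        node = tree
        while isinstance(node, dict):
            node = node.get(str(reader.read_bit()))
            if node is None:
                raise CorruptArchiveError("invalid Huffman code in local table")
        mapping.append(node)
    return LocalClassTable(mapping)
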