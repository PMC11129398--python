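"""Single-file archive container and the end-to-end compress / decompress
drivers.

An archive holds everything needed to recover the colored k-mer set exactly:
the 2-bit-packed SPSS with per-simplitig lengths, the 3-bit-per-simplitig
metadata stream, the m bitvector, the concatenated local tables, and the
three global-class-table members (Delta, boundary, frequencies). Every member
is passed through a generic lossless byte compressor (default LZMA) — disk
compression needs no rank/select queries over the bitvectors, so a succinct
structure would buy nothing here. Byte-exact layout is documented in
FORMAT.md at the repository root.
"""

from __future__ import annotations

import lzma
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .bitio import BitReader, BitWriter, bits_to_str
from .class_tables import (
    build_global_table,
    deserialize_global_table,
    deserialize_local_table,
    serialize_global_table,
    SerializedGlobalTable,
)
from .codec import (
    CodecConfig,
    choose_mode,
    decode_metadata,
    decode_simplitig,
)
from .color_matrix import (
    ColorMatrix,
    build_color_matrix,
    class_census,
    write_matrix_binary,
    write_matrix_tsv,
)
from .errors import CorruptArchiveError, ParseError
from .kmer import KmerSet, canonicalize, load_color, union_kmers
from .spss import SPSS, build_spss, kmer_order, write_fasta

MAGIC = b"CDZ1"
FORMAT_VERSION = 1

_NUC_TO_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS_TO_NUC = "ACGT"

COMPRESSORS = {"none": 0, "lzma": 1}
_COMPRESSOR_NAMES = {v: k for k, v in COMPRESSORS.items()}

FLAG_SINGLE_CLASS = 1
FLAG_ELL_CAP = 2

#: canonical member order in the container
MEMBER_ORDER = [
    "spss.len",
    "spss.seq",
    "meta.bits",
    "m.bits",
    "local_tables.bits",
    "classes.delta",
    "classes.boundary",
    "classes.freq",
]


def _compress_bytes(data: bytes, compressor: str) -> bytes:
    if compressor == "none":
        return data
    if compressor == "lzma":
        return lzma.compress(data, preset=6)
    raise ValueError(f"unknown compressor {compressor!r}")


def _decompress_bytes(data: bytes, compressor: str) -> bytes:
    if compressor == "none":
        return data
    if compressor == "lzma":
        try:
            return lzma.decompress(data)
        except lzma.LZMAError as exc:
            raise CorruptArchiveError(f"member decompression failed: {exc}") from exc
    raise CorruptArchiveError(f"unknown compressor id {compressor!r}")


def _encode_varint(value: int) -> bytes:
    out = bytearray()
    while True:
        byte = value & 0x7F
        value >>= 7
        if value:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return bytes(out)


def _decode_varints(data: bytes, count: int) -> list[int]:
    values = []
    pos = 0
    for _ in range(count):
        shift = 0
        value = 0
        while True:
            if pos >= len(data):
                raise CorruptArchiveError("truncated varint in simplitig lengths")
            byte = data[pos]
            pos += 1
            value |= (byte & 0x7F) << shift
            if not byte & 0x80:
                break
            shift += 7
        values.append(value)
    if pos != len(data):
        raise CorruptArchiveError("trailing bytes after simplitig lengths")
    return values


@dataclass
class Member:
    raw: bytes
    bit_len: int  # meaningful payload bits (8*len(raw) for byte members)


@dataclass
class Archive:
    """In-memory archive: header fields plus raw (uncompressed) members."""

    k: int
    C: int
    M: int
    run_divisor: int
    n_simplitigs: int
    n_kmers: int
    flags: int
    compressor: str
    members: dict[str, Member] = field(default_factory=dict)
    compressed_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def single_class_flag(self) -> bool:
        return bool(self.flags & FLAG_SINGLE_CLASS)

    @property
    def ell_cap_3bit(self) -> bool:
        return bool(self.flags & FLAG_ELL_CAP)

    def to_bytes(self) -> bytes:
        payloads = {}
        for name in MEMBER_ORDER:
            payloads[name] = _compress_bytes(self.members[name].raw, self.compressor)
            self.compressed_sizes[name] = len(payloads[name])
        out = bytearray()
        out += MAGIC
        out += struct.pack(
            "<HIIQIQQBB",
            FORMAT_VERSION,
            self.k,
            self.C,
            self.M,
            self.run_divisor,
            self.n_simplitigs,
            self.n_kmers,
            self.flags,
            COMPRESSORS[self.compressor],
        )
        out += struct.pack("<H", len(MEMBER_ORDER))
        for name in MEMBER_ORDER:
            member = self.members[name]
            name_b = name.encode()
            out += struct.pack("<H", len(name_b))
            out += name_b
            out += struct.pack(
                "<QQQI",
                len(member.raw),
                member.bit_len,
                len(payloads[name]),
                zlib.crc32(member.raw),
            )
        for name in MEMBER_ORDER:
            out += payloads[name]
        return bytes(out)

    @classmethod
    def from_bytes(cls, blob: bytes) -> "Archive":
        if blob[:4] != MAGIC:
            raise CorruptArchiveError("bad magic; not a cdbgzip archive")
        header_fmt = "<HIIQIQQBB"
        header_size = struct.calcsize(header_fmt)
        (
            version,
            k,
            C,
            M,
            run_divisor,
            n_simplitigs,
            n_kmers,
            flags,
            comp_id,
        ) = struct.unpack_from(header_fmt, blob, 4)
        if version != FORMAT_VERSION:
            raise CorruptArchiveError(f"unsupported format version {version}")
        if comp_id not in _COMPRESSOR_NAMES:
            raise CorruptArchiveError(f"unknown compressor id {comp_id}")
        compressor = _COMPRESSOR_NAMES[comp_id]
        pos = 4 + header_size
        (n_members,) = struct.unpack_from("<H", blob, pos)
        pos += 2
        entries = []
        for _ in range(n_members):
            (name_len,) = struct.unpack_from("<H", blob, pos)
            pos += 2
            name = blob[pos : pos + name_len].decode()
            pos += name_len
            raw_len, bit_len, comp_len, crc = struct.unpack_from("<QQQI", blob, pos)
            pos += struct.calcsize("<QQQI")
            entries.append((name, raw_len, bit_len, comp_len, crc))
        members: dict[str, Member] = {}
        compressed_sizes: dict[str, int] = {}
        for name, raw_len, bit_len, comp_len, crc in entries:
            payload = blob[pos : pos + comp_len]
            if len(payload) != comp_len:
                raise CorruptArchiveError(f"member {name}: truncated payload")
            pos += comp_len
            raw = _decompress_bytes(payload, compressor)
            if len(raw) != raw_len:
                raise CorruptArchiveError(
                    f"member {name}: length {len(raw)} != declared {raw_len}"
                )
            if zlib.crc32(raw) != crc:
                raise CorruptArchiveError(f"member {name}: checksum mismatch")
            members[name] = Member(raw, bit_len)
            compressed_sizes[name] = comp_len
        for name in MEMBER_ORDER:
            if name not in members:
                raise CorruptArchiveError(f"missing archive member {name}")
        return cls(
            k=k,
            C=C,
            M=M,
            run_divisor=run_divisor,
            n_simplitigs=n_simplitigs,
            n_kmers=n_kmers,
            flags=flags,
            compressor=compressor,
            members=members,
            compressed_sizes=compressed_sizes,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_bytes(self.to_bytes())

    @classmethod
    def read(cls, path: str | Path) -> "Archive":
        return cls.from_bytes(Path(path).read_bytes())


def _pack_spss(spss: SPSS) -> tuple[Member, Member]:
    lengths = b"".join(_encode_varint(len(s)) for s in spss.simplitigs)
    writer = BitWriter()
    for s in spss.simplitigs:
        for ch in s:
            writer.write_uint(_NUC_TO_BITS[ch], 2)
    data, bitlen = writer.getvalue()
    return Member(lengths, 8 * len(lengths)), Member(data, bitlen)


def _unpack_spss(len_member: Member, seq_member: Member, k: int, n_simplitigs: int) -> SPSS:
    lengths = _decode_varints(len_member.raw, n_simplitigs)
    reader = BitReader(seq_member.raw, seq_member.bit_len)
    simplitigs = []
    for length in lengths:
        simplitigs.append(
            "".join(_BITS_TO_NUC[reader.read_uint(2)] for _ in range(length))
        )
    if not reader.exhausted():
        raise CorruptArchiveError("trailing bits after SPSS sequence data")
    return SPSS(k, simplitigs)


def _pack_bit_string(bits: str) -> Member:
    writer = BitWriter()
    writer.write_bits(bits)
    data, bitlen = writer.getvalue()
    return Member(data, bitlen)


def compress_color_sets(
    colors: list[KmerSet],
    config: CodecConfig = CodecConfig(),
    compressor: str = "lzma",
) -> Archive:
    """Compress a colored k-mer set (list of per-color canonical KmerSets).

    Pipeline: union -> SPSS -> k-mer ranks -> color matrix -> class census ->
    global Huffman table -> per-simplitig mode search and encoding.
    """
    if not colors:
        raise ParseError("need at least one color")
    for i, color in enumerate(colors):
        if not color.members:
            warnings.warn(f"color {i} has no k-mers after thresholding")
    union = union_kmers(colors)
    if not union.members:
        raise ParseError("the union k-mer set is empty; nothing to compress")
    spss = build_spss(union, mode="canonical")
    order = kmer_order(spss)
    matrix = build_color_matrix(order, colors)
    census = class_census(matrix)
    gt = build_global_table(census)

    meta_bits: list[str] = []
    m_bits: list[str] = []
    local_bits: list[str] = []
    row_cursor = 0
    for size in order.simplitig_sizes:
        classes = matrix.rows[row_cursor : row_cursor + size]
        row_cursor += size
        enc = choose_mode(classes, gt, config)
        meta_bits.append(format(enc.meta, "03b"))
        m_bits.append(enc.m_bits)
        local_bits.append(enc.local_bits)

    ser = serialize_global_table(gt)
    len_member, seq_member = _pack_spss(spss)
    flags = (FLAG_SINGLE_CLASS if config.single_class_flag else 0) | (
        FLAG_ELL_CAP if config.ell_cap_3bit else 0
    )
    freq_raw = ("\n".join(ser.freq_lines) + "\n").encode()
    archive = Archive(
        k=union.k,
        C=len(colors),
        M=census.M,
        run_divisor=config.run_divisor,
        n_simplitigs=len(spss.simplitigs),
        n_kmers=len(union),
        flags=flags,
        compressor=compressor,
        members={
            "spss.len": len_member,
            "spss.seq": seq_member,
            "meta.bits": _pack_bit_string("".join(meta_bits)),
            "m.bits": _pack_bit_string("".join(m_bits)),
            "local_tables.bits": _pack_bit_string("".join(local_bits)),
            "classes.delta": _pack_bit_string(ser.delta),
            "classes.boundary": _pack_bit_string(ser.boundary),
            "classes.freq": Member(freq_raw, 8 * len(freq_raw)),
        },
    )
    return archive


def compress(
    input_paths: list[str | Path],
    k: int,
    a: int = 1,
    out_path: str | Path | None = None,
    config: CodecConfig = CodecConfig(),
    compressor: str = "lzma",
) -> Archive:
    """File-level driver: one input path per color (FASTA or k-mer list)."""
    colors = [load_color(p, k, a) for p in input_paths]
    archive = compress_color_sets(colors, config, compressor)
    if out_path is not None:
        archive.write(out_path)
    return archive


@dataclass
class Decompressed:
    """Lossless reconstruction of the colored k-mer set."""

    spss: SPSS
    matrix: ColorMatrix
    kmers: list[str]  # canonical k-mers in SPSS rank order

    def iter_colored_kmers(self) -> Iterator[tuple[str, int]]:
        """Stream (canonical k-mer, color-vector integer) in rank order."""
        return zip(self.kmers, self.matrix.rows)

    def color_sets(self) -> list[KmerSet]:
        """Reconstructed per-color canonical k-mer sets."""
        sets: list[set[str]] = [set() for _ in range(self.matrix.C)]
        for km, vec in self.iter_colored_kmers():
            i = 0
            while vec:
                if vec & 1:
                    sets[i].add(km)
                vec >>= 1
                i += 1
        return [KmerSet(self.spss.k, s) for s in sets]

    def write_outputs(
        self, outdir: str | Path, tsv: bool = False
    ) -> tuple[Path, Path]:
        """Write the SPSS FASTA and the color matrix (binary, or TSV keyed by
        k-mer when tsv=True); returns the two paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "spss.fa"
        write_fasta(self.spss, fasta)
        if tsv:
            matrix_path = outdir / "color_matrix.tsv"
            write_matrix_tsv(self.matrix, self.kmers, matrix_path)
        else:
            matrix_path = outdir / "color_matrix.bin"
            write_matrix_binary(self.matrix, matrix_path)
        return fasta, matrix_path


def decompress(archive: Archive | str | Path | bytes) -> Decompressed:
    """Decode an archive back to (SPSS, SPSS-ordered color matrix)."""
    if isinstance(archive, (str, Path)):
        archive = Archive.read(archive)
    elif isinstance(archive, bytes):
        archive = Archive.from_bytes(archive)

    spss = _unpack_spss(
        archive.members["spss.len"],
        archive.members["spss.seq"],
        archive.k,
        archive.n_simplitigs,
    )
    sizes = spss.simplitig_sizes()
    if sum(sizes) != archive.n_kmers:
        raise CorruptArchiveError(
            f"header k-mer count {archive.n_kmers} != SPSS windows {sum(sizes)}"
        )

    delta_m = archive.members["classes.delta"]
    bound_m = archive.members["classes.boundary"]
    ser = SerializedGlobalTable(
        bits_to_str(delta_m.raw, delta_m.bit_len),
        bits_to_str(bound_m.raw, bound_m.bit_len),
        archive.members["classes.freq"].raw.decode().splitlines(),
    )
    gt = deserialize_global_table(ser, archive.C)
    if gt.M != archive.M:
        raise CorruptArchiveError(f"header M={archive.M} but table has {gt.M} classes")
    tree = gt.decode_tree()

    meta_m = archive.members["meta.bits"]
    meta_reader = BitReader(meta_m.raw, meta_m.bit_len)
    m_m = archive.members["m.bits"]
    m_reader = BitReader(m_m.raw, m_m.bit_len)
    local_m = archive.members["local_tables.bits"]
    local_reader = BitReader(local_m.raw, local_m.bit_len)

    rows: list[int] = []
    for size in sizes:
        mode = decode_metadata(meta_reader.read_uint(3))
        if mode is None:  # single-class simplitig: one bare global ID
            node = tree
            while isinstance(node, dict):
                node = node.get(str(m_reader.read_bit()))
                if node is None:
                    raise CorruptArchiveError("invalid Huffman code in m")
            rows.extend([node] * size)
            continue
        lt = None
        if mode.use_local_id:
            lt = deserialize_local_table(local_reader, gt, archive.ell_cap_3bit)
        rows.extend(
            decode_simplitig(
                m_reader, size, mode, gt, lt, archive.run_divisor, archive.C
            )
        )
    for reader, name in (
        (meta_reader, "meta.bits"),
        (m_reader, "m.bits"),
        (local_reader, "local_tables.bits"),
    ):
        if not reader.exhausted():
            raise CorruptArchiveError(f"{name}: {reader.remaining()} unconsumed bits")

    matrix = ColorMatrix(archive.C, rows)
    kmers = [canonicalize(w) for w in spss.windows()]
    return Decompressed(spss, matrix, kmers)


def stats(archive: Archive | str | Path) -> dict:
    """Size report: per-member compressed bytes, percentage breakdown, bits
    per k-mer, and the single-color k-mer fraction (from the frequency
    member, without decoding m)."""
    if isinstance(archive, (str, Path)):
        archive = Archive.read(archive)
    if not archive.compressed_sizes:
        archive.to_bytes()  # populate compressed sizes
    sizes = dict(archive.compressed_sizes)
    total = sum(sizes.values())
    freq_lines = archive.members["classes.freq"].raw.decode().splitlines()
    single = 0
    for line in freq_lines:
        cls_s, count_s = line.split("\t")
        if int(cls_s).bit_count() == 1:
            single += int(count_s)
    return {
        "k": archive.k,
        "C": archive.C,
        "M": archive.M,
        "n_kmers": archive.n_kmers,
        "n_simplitigs": archive.n_simplitigs,
        "member_bytes": sizes,
        "member_percent": {
            name: (100.0 * size / total if total else 0.0)
            for name, size in sizes.items()
        },
        "total_member_bytes": total,
        "bits_per_kmer": 8.0 * total / archive.n_kmers if archive.n_kmers else 0.0,
        "single_color_fraction": 100.0 * single / archive.n_kmers
        if archive.n_kmers
        else 0.0,
    }
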