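"""Per-simplitig encoding of the class stream into the m bitvector.

Scanning a simplitig left to right, each k-mer is encoded with one of four
options:

* **skip** — interior k-mer whose class equals both neighbours': nothing is
  emitted;
* **small class difference** — the class differs from the predecessor's at
  h <= maxDif bit positions: type prefix ``10``, an h flag when maxDif=2,
  then the differing positions;
* **end of run** — same class as the predecessor and the run stops here:
  type prefix ``11`` (just ``1`` when maxDif=0, where only two types exist),
  then the run length as a unary quotient / binary remainder with respect to
  ``runDivisor``;
* **store the class ID** — everything else: type prefix ``0``, then the
  global Huffman ID (or a fixed-width local ID when UseLocalID is set).

Two per-simplitig parameters — maxDif in {0,1,2} and UseLocalID — give six
encoding modes; all six are tried and the smallest output kept, recorded in
3 bits of metadata per simplitig. A spare metadata value optionally marks a
single-class simplitig whose m holds just one bare global ID.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .bitio import BitReader, ceil_log2
from .class_tables import (
    GlobalClassTable,
    LocalClassTable,
    build_local_table,
    index_field_width,
    serialize_local_table,
)
from .errors import ConsistencyError, CorruptArchiveError

DEFAULT_RUN_DIVISOR = 16

#: metadata enumeration of (maxDif, useLocalID); value 6 = single-class flag
META_ORDER: list[tuple[int, bool]] = [
    (0, False),
    (1, False),
    (2, False),
    (0, True),
    (1, True),
    (2, True),
]
META_SINGLE_CLASS = 6


class Token(Enum):
    SKIP = "skip"
    DIFF = "diff"
    END_OF_RUN = "end_of_run"
    CLASS_ID = "class_id"


@dataclass(frozen=True)
class EncodingMode:
    max_dif: int  # 0, 1 or 2
    use_local_id: bool

    def __post_init__(self) -> None:
        if self.max_dif not in (0, 1, 2):
            raise ValueError(f"maxDif must be 0, 1 or 2, got {self.max_dif}")


@dataclass(frozen=True)
class CodecConfig:
    """Optional optimizations, off by default."""

    run_divisor: int = DEFAULT_RUN_DIVISOR
    single_class_flag: bool = False
    ell_cap_3bit: bool = False

    def __post_init__(self) -> None:
        rd = self.run_divisor
        if rd < 2 or rd & (rd - 1):
            raise ValueError(f"runDivisor must be a power of two >= 2, got {rd}")


def encode_run_length(run_len: int, run_divisor: int) -> str:
    """q ones, a terminating zero, then the remainder in ceil(log2 runDivisor)
    bits, MSB first (q = runLen // runDivisor, r = runLen % runDivisor)."""
    if run_len < 1:
        raise ValueError(f"runLen must be >= 1, got {run_len}")
    q, r = divmod(run_len, run_divisor)
    return "1" * q + "0" + format(r, f"0{ceil_log2(run_divisor)}b")


def decode_run_length(reader: BitReader, run_divisor: int) -> int:
    """Inverse of encode_run_length; rejects runLen=0 as corrupt."""
    q = 0
    while reader.read_bit():
        q += 1
    r = reader.read_uint(ceil_log2(run_divisor))
    run_len = q * run_divisor + r
    if run_len < 1:
        raise CorruptArchiveError("decoded run length 0 (runs are >= 1)")
    return run_len


def classify_kmer(i: int, classes: list[int], max_dif: int) -> Token:
    """Which of the four options encodes the k-mer at position i.

    The first k-mer of a simplitig is always CLASS_ID (differences are
    defined only against a predecessor within the same simplitig).
    """
    n = len(classes)
    cur = classes[i]
    if i == 0:
        return Token.CLASS_ID
    prev = classes[i - 1]
    last = i == n - 1
    if cur == prev:
        if not last and classes[i + 1] == cur:
            return Token.SKIP
        return Token.END_OF_RUN
    h = (cur ^ prev).bit_count()
    if 0 < h <= max_dif:
        return Token.DIFF
    return Token.CLASS_ID


def _diff_positions(a: int, b: int) -> list[int]:
    diff = a ^ b
    out = []
    pos = 0
    while diff:
        if diff & 1:
            out.append(pos)
        diff >>= 1
        pos += 1
    return out


def encode_simplitig(
    classes: list[int],
    mode: EncodingMode,
    gt: GlobalClassTable,
    lt: LocalClassTable | None,
    run_divisor: int,
    C: int,
) -> str:
    """Encode one simplitig's class sequence under a fixed mode; returns the
    m-vector bits as a '0'/'1' string."""
    if mode.use_local_id != (lt is not None):
        raise ValueError("local table must be present iff UseLocalID is set")
    if not classes:
        raise ValueError("empty class sequence")
    idx_w = index_field_width(C)
    local_index = (
        {cls: j for j, cls in enumerate(lt.local_to_global)} if lt is not None else None
    )
    parts: list[str] = []
    run_start = 0
    for i, cur in enumerate(classes):
        token = classify_kmer(i, classes, mode.max_dif)
        if token is Token.SKIP:
            continue
        if token is Token.END_OF_RUN:
            run_len = i - run_start  # preceding same-class k-mers, excluding x
            parts.append("11" if mode.max_dif > 0 else "1")
            parts.append(encode_run_length(run_len, run_divisor))
            continue
        run_start = i
        if token is Token.DIFF:
            positions = _diff_positions(cur, classes[i - 1])
            if len(positions) > mode.max_dif:
                raise ConsistencyError("DIFF selected with h > maxDif")
            parts.append("10")
            if mode.max_dif == 2:
                parts.append("1" if len(positions) == 2 else "0")
            for pos in positions:
                parts.append(format(pos, f"0{idx_w}b"))
            continue
        # CLASS_ID
        parts.append("0")
        if lt is not None:
            lid = local_index[cur]
            if lt.id_width:
                parts.append(format(lid, f"0{lt.id_width}b"))
        else:
            parts.append(gt.code[cur])
    return "".join(parts)


def decode_simplitig(
    reader: BitReader,
    n_kmers: int,
    mode: EncodingMode,
    gt: GlobalClassTable,
    lt: LocalClassTable | None,
    run_divisor: int,
    C: int,
) -> list[int]:
    """Exact inverse of encode_simplitig; consumes precisely the bits the
    encoder produced. A run token of length L extends the previous class over
    the next L positions (the run's first k-mer was encoded explicitly)."""
    if mode.use_local_id != (lt is not None):
        raise ValueError("local table must be present iff UseLocalID is set")
    idx_w = index_field_width(C)
    tree = gt.decode_tree()
    out: list[int] = []
    while len(out) < n_kmers:
        bit = reader.read_bit()
        if bit == 0:  # CLASS_ID
            if lt is not None:
                lid = reader.read_uint(lt.id_width)
                if lid >= lt.ell:
                    raise CorruptArchiveError(f"local ID {lid} >= ell={lt.ell}")
                out.append(lt.local_to_global[lid])
            else:
                node = tree
                while isinstance(node, dict):
                    node = node.get(str(reader.read_bit()))
                    if node is None:
                        raise CorruptArchiveError("invalid Huffman code in m")
                out.append(node)
            continue
        if mode.max_dif == 0:
            token = Token.END_OF_RUN
        else:
            token = Token.END_OF_RUN if reader.read_bit() else Token.DIFF
        if not out:
            raise CorruptArchiveError("run/diff token with no preceding k-mer")
        if token is Token.DIFF:
            h = 1
            if mode.max_dif == 2:
                h = 2 if reader.read_bit() else 1
            cls = out[-1]
            prev_pos = -1
            for _ in range(h):
                pos = reader.read_uint(idx_w)
                if pos >= C:
                    raise CorruptArchiveError(f"diff index {pos} >= C={C}")
                if pos <= prev_pos:
                    raise CorruptArchiveError("diff indices not strictly increasing")
                cls ^= 1 << pos
                prev_pos = pos
            out.append(cls)
        else:
            run_len = decode_run_length(reader, run_divisor)
            if len(out) + run_len > n_kmers:
                raise CorruptArchiveError(
                    f"run of {run_len} overruns the simplitig ({n_kmers} k-mers)"
                )
            out.extend([out[-1]] * run_len)
    return out


def encode_metadata(mode: EncodingMode | None, single_class: bool = False) -> str:
    """3-bit metadata: values 0-5 enumerate (maxDif, useLocalID); value 6
    flags a single-class simplitig (m holds one bare global ID)."""
    if single_class:
        return format(META_SINGLE_CLASS, "03b")
    value = META_ORDER.index((mode.max_dif, mode.use_local_id))
    return format(value, "03b")


def decode_metadata(value: int) -> EncodingMode | None:
    """Inverse of encode_metadata; None means single-class. Value 7 is
    reserved and rejected."""
    if 0 <= value < len(META_ORDER):
        return EncodingMode(*META_ORDER[value])
    if value == META_SINGLE_CLASS:
        return None
    raise CorruptArchiveError(f"reserved metadata value {value}")


@dataclass
class SimplitigEncoding:
    """choose_mode result: metadata value, m bits, optional local table and
    its serialized bits."""

    meta: int
    m_bits: str
    local_table: LocalClassTable | None
    local_bits: str

    @property
    def cost(self) -> int:
        return len(self.m_bits) + len(self.local_bits)


def choose_mode(
    classes: list[int],
    gt: GlobalClassTable,
    config: CodecConfig = CodecConfig(),
) -> SimplitigEncoding:
    """Try every encoding mode and keep the smallest.

    All six (maxDif, UseLocalID) combinations are evaluated; the cost of a
    local-ID mode includes its serialized local table. Ties go to the
    earliest mode in metadata order. With the single-class flag enabled, a
    single-class simplitig is stored as its bare global ID under metadata
    value 6 (always at least as small as any mode).
    """
    if not classes:
        raise ValueError("empty class sequence")
    rd = config.run_divisor
    if config.single_class_flag and len(set(classes)) == 1:
        return SimplitigEncoding(META_SINGLE_CLASS, gt.code[classes[0]], None, "")

    best: SimplitigEncoding | None = None
    for meta, (max_dif, use_local) in enumerate(META_ORDER):
        mode = EncodingMode(max_dif, use_local)
        if use_local:
            lt = build_local_table(classes, gt)
            try:
                local_bits = serialize_local_table(lt, gt, config.ell_cap_3bit)
            except ValueError:  # ell overflows the capped count field
                continue
        else:
            lt, local_bits = None, ""
        m_bits = encode_simplitig(classes, mode, gt, lt, rd, gt.C)
        cand = SimplitigEncoding(meta, m_bits, lt, local_bits)
        if best is None or cand.cost < best.cost:
            best = cand
    assert best is not None
    return best
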