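"""Bit-level stream primitives.

All multi-bit fixed-width fields are written most-significant bit first
(big-endian within the field); bits are packed MSB-first within each byte.
Streams carry an explicit bit length so trailing pad bits in the final byte
are never misread as data.
"""

from __future__ import annotations

from .errors import CorruptArchiveError


def ceil_log2(n: int) -> int:
    """Smallest w with 2**w >= n (0 for n=1)."""
    if n < 1:
        raise ValueError(f"ceil_log2 requires n >= 1, got {n}")
    return (n - 1).bit_length()


class BitWriter:
    """Append-only bit sink backed by a bytearray."""

    def __init__(self) -> None:
        self._buf = bytearray()
        self._bitlen = 0

    def __len__(self) -> int:
        return self._bitlen

    def write_bit(self, bit: int) -> None:
        pos = self._bitlen & 7
        if pos == 0:
            self._buf.append(0)
        if bit:
            self._buf[-1] |= 0x80 >> pos
        self._bitlen += 1

    def write_bits(self, bits: str) -> None:
        """Append a '0'/'1' string, leftmost bit first."""
        for ch in bits:
            if ch == "1":
                self.write_bit(1)
            elif ch == "0":
                self.write_bit(0)
            else:
                raise ValueError(f"not a bit: {ch!r}")

    def write_uint(self, value: int, width: int) -> None:
        """Append `value` in exactly `width` bits, MSB first."""
        if value < 0 or (width < value.bit_length()):
            raise ValueError(f"{value} does not fit in {width} bits")
        for shift in range(width - 1, -1, -1):
            self.write_bit((value >> shift) & 1)

    def getvalue(self) -> tuple[bytes, int]:
        """Return (packed bytes, exact bit length)."""
        return bytes(self._buf), self._bitlen


class BitReader:
    """Cursor over a packed bit stream with an explicit bit length."""

    def __init__(self, data: bytes, bitlen: int | None = None) -> None:
        self._data = data
        self._bitlen = 8 * len(data) if bitlen is None else bitlen
        if self._bitlen > 8 * len(data):
            raise CorruptArchiveError(
                f"declared bit length {self._bitlen} exceeds buffer of "
                f"{8 * len(data)} bits"
            )
        self._pos = 0

    @property
    def pos(self) -> int:
        return self._pos

    @property
    def bitlen(self) -> int:
        return self._bitlen

    def remaining(self) -> int:
        return self._bitlen - self._pos

    def exhausted(self) -> bool:
        return self._pos >= self._bitlen

    def read_bit(self) -> int:
        if self._pos >= self._bitlen:
            raise CorruptArchiveError("bit stream exhausted mid-field")
        byte = self._data[self._pos >> 3]
        bit = (byte >> (7 - (self._pos & 7))) & 1
        self._pos += 1
        return bit

    def read_uint(self, width: int) -> int:
        value = 0
        for _ in range(width):
            value = (value << 1) | self.read_bit()
        return value


def bits_to_str(data: bytes, bitlen: int) -> str:
    """Render a packed stream as a '0'/'1' string (testing/debug aid)."""
    reader = BitReader(data, bitlen)
    return "".join(str(reader.read_bit()) for _ in range(bitlen))
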