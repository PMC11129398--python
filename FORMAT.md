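# cdbgzip archive format (version 1)

A cdbgzip archive is a single binary file holding everything needed to
reconstruct a colored k-mer set exactly. All container-layer integers are
little-endian. Bit streams are packed most-significant-bit first within each
byte, padded with zero bits to a byte boundary, and carry their exact bit
length in the member table so pad bits are never interpreted.

## Layout

```
magic           4 bytes   "CDZ1"
header          struct <HIIQIQQBB>:
    version         u16   format version (1)
    k               u32   k-mer length
    C               u32   number of colors
    M               u64   number of distinct color classes
    runDivisor      u32   power-of-two divisor for run-length coding
    n_simplitigs    u64
    n_kmers         u64   = sum over simplitigs of (length - k + 1)
    flags           u8    bit 0: single-class metadata value in use
                          bit 1: 3-bit local-table count fields (ell cap)
    compressor      u8    0 = none, 1 = LZMA (xz raw stream, preset 6)
member_count    u16       always 8
member table    per member, in the canonical order below:
    name_len        u16
    name            UTF-8 bytes
    raw_len         u64   uncompressed byte length
    bit_len         u64   meaningful payload bits (8*raw_len for byte members)
    comp_len        u64   compressed byte length
    crc32           u32   CRC-32 of the uncompressed bytes
payloads        the 8 compressed members, concatenated in table order
```

Every member is independently passed through the final-stage compressor
named in the header.

## Members (canonical order)

1. **spss.len** — per-simplitig base lengths as unsigned LEB128 varints,
   `n_simplitigs` of them.
2. **spss.seq** — the simplitig sequences concatenated, 2 bits per base
   (A=00, C=01, G=10, T=11).
3. **meta.bits** — exactly 3 bits per simplitig. Values 0–5 enumerate the
   encoding mode in the order (maxDif=0, local=False), (1, False), (2, False),
   (0, True), (1, True), (2, True); value 6 (only if flag bit 0) marks a
   single-class simplitig whose m entry is one bare global class ID; value 7
   is reserved and rejected.
4. **m.bits** — the per-simplitig class encodings concatenated in simplitig
   order with no separators; the decoder segments the stream using the
   per-simplitig k-mer counts derived from spss.len.
5. **local_tables.bits** — serialized local class tables, concatenated in
   simplitig order, present only for simplitigs whose metadata sets
   UseLocalID. Each table is a count field holding `ell - 1`
   (`ceil(log2 M)` bits wide, minimum 1; exactly 3 bits when flag bit 1 is
   set) followed by `ell` global Huffman codes (self-delimiting).
6. **classes.delta** — the Delta color encoding: classes sorted ascending as
   C-bit integers (color 0 = least significant bit), the first written
   verbatim as C bits in position order 0..C-1, each subsequent class as its
   differing positions vs. the predecessor, ascending, each position in
   `ceil(log2 C)` bits (minimum 1), MSB first.
7. **classes.boundary** — same bit length as classes.delta, a 1 wherever a
   class's segment starts (so M ones, the first at position 0).
8. **classes.freq** — UTF-8 text, one `class_integer<TAB>count` line per
   class, sorted ascending, trailing newline.

## Color-vector conventions

A color vector is read as a C-bit integer with color i at bit i (color 0 is
the least significant bit). When a vector is emitted to a bit stream it goes
out in position order 0..C-1. These two conventions fix the sort order of the
global class table and the meaning of difference indices.

## m-vector encodings

Within a simplitig, scanned left to right, each k-mer is one of:

* **skip** — interior k-mer, class equal to both neighbours: no bits.
* **small class difference** — prefix `10`; if maxDif=2 one flag bit (1 means
  h=2); then h position fields of `ceil(log2 C)` bits (ascending).
* **end of run** — prefix `11` (`1` when maxDif=0); then runLen (the number
  of immediately preceding consecutive same-class k-mers, excluding this one)
  as `runLen // runDivisor` ones, a zero, and `runLen % runDivisor` in
  `log2(runDivisor)` bits. The decoder, having already decoded the run's
  first k-mer, extends its class over the next runLen positions.
* **store the class ID** — prefix `0`; then the global Huffman ID, or, when
  UseLocalID is set, a fixed-width local ID of `ceil(log2 ell)` bits
  (0 bits when ell = 1).

The first k-mer of a simplitig is always a stored class ID (or absorbed by
the single-class metadata value); differences never cross simplitig
boundaries.

## Global Huffman code reconstruction

Both sides derive the code from the class frequencies alone: Huffman merging
with heap ties broken toward the subtree containing the smallest class
integer, then canonical code assignment (shorter lengths first, ties by class
integer, consecutive codewords). M=1 is assigned the single 1-bit code `0`.
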