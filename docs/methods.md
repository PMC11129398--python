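# Methods

## Model and scope

cdbgzip compresses a colored de Bruijn graph given as C per-color k-mer sets.
The losslessness contract is over the **colored k-mer set**: decompression
reproduces the union of canonical k-mers and each k-mer's C-bit color vector
exactly. It is deliberately *not* over the original FASTA reads — abundance
thresholding (keep k-mers seen ≥ a times) is a lossy, intentional
preprocessing step, as is canonicalization (a k-mer and its reverse
complement are identified). The archive supports no queries; rank/select
structures would buy nothing on disk, so all bitvectors go through a generic
byte compressor instead (LZMA by default, selectable; "none" is available
and bijective, which the tests exploit).

## k-mer extraction

Canonical form = lexicographic min of a window and its reverse complement.
Lowercase input is uppercased; any window containing a non-ACGT character is
skipped. The abundance threshold counts one occurrence per window position,
credited to the window's canonical form, so both strands pool. These rules
are stated here because k-mer counters differ in their degenerate-base
handling; ours is fixed and tested rather than inherited from any external
counter.

## SPSS construction

Simplitigs are built greedily: canonical k-mers are visited in lexicographic
order; each unvisited k-mer seeds a simplitig that is extended maximally to
the right and then to the left, always taking the lexicographically smallest
nucleotide whose (canonical) k-mer is still unused. In canonical mode the
walk follows the bidirected graph, so a simplitig window may be the reverse
complement of the stored canonical k-mer. Lexicographic tie-breaking makes
the decomposition deterministic — two runs on the same input produce
byte-identical archives — at the cost of not minimizing simplitig count; a
minimum-size SPSS or color-aware extension would only change constants, not
correctness, and is out of scope. A forward_only mode (no reverse-complement
identification) exists for exercising the string-level definition in tests;
the pipeline always uses canonical mode.

## Bit-level conventions

Choices the format had to fix (all documented byte-exactly in FORMAT.md):

* Color i sits at bit i of the vector-as-integer (color 0 = LSB); stream
  emission order is position 0 first. This fixes the global table's sort
  order and the meaning of difference indices.
* All ⌈log2 x⌉ field widths use the integer ceiling; widths that could be 0
  (C=1 index fields, M=1 count fields) are clamped to 1 bit, except local
  IDs, where ℓ=1 genuinely means 0-bit IDs (the table itself names the
  class).
* The local-table count field stores ℓ−1, since ℓ=0 cannot occur.
* Huffman construction is canonical with heap ties broken toward the
  smallest class integer, so compressor and decompressor rebuild identical
  codes from the frequency file alone. M=1 gets the 1-bit code "0".
* runLen at an end-of-run token counts the consecutive same-class k-mers
  preceding the token's k-mer, excluding it. The run's first k-mer is always
  explicitly encoded, so the decoder extends the previous class over the
  next runLen positions; this is the only convention under which skipped
  k-mers emit nothing and the stream stays prefix-decodable, and it
  reproduces the runLen=21 → `100101` reference pattern.
* The first k-mer of every simplitig is a stored class ID; class differences
  never cross simplitig boundaries.
* The per-simplitig m segments are concatenated without separators; the
  decoder segments them using window counts derived from the stored
  simplitig lengths.

## Tunable parameters

* `k` — k-mer length, a global constant of one archive; mixed-k inputs are
  rejected.
* `a` (default 1) — abundance threshold for FASTA inputs; ≥ 2 is the usual
  choice for read data, 1 for assemblies.
* `runDivisor` (default 16) — power-of-two split of run lengths into unary
  quotient and binary remainder. Smaller values inflate long runs (bigger
  quotients), larger values inflate short runs (wider remainders); 16
  balances the two for typical run-length distributions and is the default.
* `maxDif` and `UseLocalID` are *not* user parameters: all six combinations
  are evaluated per simplitig and the smallest encoding kept (ties to the
  earliest in metadata order, making the choice deterministic). The chosen
  encoding is provably ≤ every fixed mode, which the tests assert.
* Optional, off by default (their measured benefit is small and
  data-dependent): `single_class_flag` stores a single-class simplitig as
  one bare global ID under the spare metadata value 6; `ell_cap_3bit`
  shrinks local-table count fields to 3 bits and falls back to global IDs
  whenever a simplitig has more than 8 distinct classes.

## Mode search cost

The per-simplitig minimization compares `|m bits| + |serialized local
table|`. The 3 metadata bits are constant across candidates and excluded.
The final byte-compressor stage is not simulated during the search: ranking
by pre-compression bit counts keeps the search O(6 × simplitig length) and
in practice agrees with post-compression ranking except in pathological
ties.

## Synthetic data generator

`simulate.simulate_cdbg` draws one ancestral i.i.d. random sequence and
mutates it independently per color by per-base substitutions, optionally
sampling fixed-length reads with per-base errors so abundance thresholds are
meaningful. The substitution rate tunes the single-color fraction
monotonically (rate 0 → every k-mer in all C colors; high rates → ~100%
single-color), letting tests sweep the sharing spectrum that governs
compressibility. A target single-color fraction can be requested and is met
by bisection on the rate. Everything is seeded; a fixed config reproduces
byte-identical outputs.

What the generator does **not** emulate: indels and rearrangements (the
codec sees only sets, so substitutions already produce every class pattern
that matters), repeat structure, population-genetic correlation between
colors, coverage biases, and real base-error profiles. Passing tests
therefore demonstrate losslessness and codec behavior across sharing
regimes, not the absolute compression ratios achievable on real genomes.

Test and acceptance problem sizes are deliberately desk-scale (genomes of
10²–10⁵ bases, C ≤ 64): the codec's correctness properties are
size-independent, and the randomized suites cover the full metadata/mode
space at these sizes.

## Degenerate inputs and failure modes

An empty union is rejected at compression time; an individual empty color is
retained with a warning (its bit is simply never set, and it reconstructs as
an empty set). Decoding validates everything it can: member checksums and
lengths, metadata value 7, run lengths of 0, runs overrunning their
simplitig, non-increasing difference indices, difference indices ≥ C,
Huffman codes falling off the tree, and unconsumed trailing bits all raise a
corrupt-archive error rather than returning wrong data.

## Known limitations

* Whole-pipeline memory is O(|Ē|); there is no external-memory or
  multithreaded path.
* The greedy SPSS is not minimum-size, and simplitig boundaries are chosen
  without looking at colors, so runs are sometimes split that a color-aware
  decomposition would keep intact.
* Absolute bits/k-mer depends on the backend byte compressor and the SPSS
  serialization; comparisons against other tools should hold the backend
  fixed (the integrated-vs-independent test does exactly that).
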