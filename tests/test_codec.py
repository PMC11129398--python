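import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdbgzip.bitio import BitReader, BitWriter, ceil_log2
from cdbgzip.class_tables import build_global_table, build_local_table
from cdbgzip.codec import (
    CodecConfig,
    EncodingMode,
    META_ORDER,
    META_SINGLE_CLASS,
    Token,
    choose_mode,
    classify_kmer,
    decode_metadata,
    decode_run_length,
    decode_simplitig,
    encode_metadata,
    encode_run_length,
    encode_simplitig,
)
from cdbgzip.color_matrix import ClassCensus
from cdbgzip.errors import CorruptArchiveError


def table_for(C, freq):
    return build_global_table(ClassCensus(C, sorted(freq), dict(freq)))


def reader_for(bits: str) -> BitReader:
    w = BitWriter()
    w.write_bits(bits)
    return BitReader(*w.getvalue())


@pytest.mark.parametrize(
    "run_len,divisor,expected",
    [
        (21, 16, "100101"),  # q=1, r=5
        (1, 16, "00001"),  # q=0, r=1
        (16, 16, "100000"),  # q=1, r=0
        (3, 4, "011"),
        (8, 2, "111100"),  # q=4, r=0 in the 1-bit remainder field
    ],
)
def test_encode_run_length_examples(run_len, divisor, expected):
    assert encode_run_length(run_len, divisor) == expected


def test_decode_run_length_inverts_printed_example():
    assert decode_run_length(reader_for("100101"), 16) == 21


def test_decode_run_length_rejects_zero():
    with pytest.raises(CorruptArchiveError):
        decode_run_length(reader_for("00000"), 16)


@pytest.mark.parametrize("divisor", [2, 4, 16, 64])
def test_run_length_roundtrip(divisor):
    for run_len in range(1, 1001):
        reader = reader_for(encode_run_length(run_len, divisor))
        assert decode_run_length(reader, divisor) == run_len
        assert reader.exhausted()


def test_classify_kmer_rules():
    X, Y = 1, 3
    assert [classify_kmer(i, [X, X, X], 0) for i in range(3)] == [
        Token.CLASS_ID,
        Token.SKIP,
        Token.END_OF_RUN,
    ]
    assert classify_kmer(0, [X], 0) is Token.CLASS_ID
    # Hamming(X, Y) = 1: DIFF iff maxDif >= 1
    assert classify_kmer(1, [X, Y], 1) is Token.DIFF
    assert classify_kmer(1, [X, Y], 0) is Token.CLASS_ID
    # run interrupted in the middle
    assert [classify_kmer(i, [X, X, Y, Y], 1) for i in range(4)] == [
        Token.CLASS_ID,
        Token.END_OF_RUN,
        Token.DIFF,
        Token.END_OF_RUN,
    ]


def test_encode_identical_run_23_kmers():
    # CLASS_ID at position 0, 21 skips, END_OF_RUN with runLen=22 at the end;
    # maxDif=0 uses a 1-bit run prefix
    gt = table_for(3, {1: 23})
    assert gt.code[1] == "0"
    bits = encode_simplitig([1] * 23, EncodingMode(0, False), gt, None, 16, 3)
    assert bits == "0" + "0" + "1" + "100110"


def test_encode_single_kmer():
    gt = table_for(3, {1: 1, 2: 1, 4: 2})
    code = gt.code[4]
    bits = encode_simplitig([4], EncodingMode(0, False), gt, None, 16, 3)
    assert bits == "0" + code


def test_encode_diff_lists_positions():
    # X={0}, Y={0,2}: Hamming 1 at color 2, C=6 -> 3-bit index field "010"
    gt = table_for(6, {1: 5, 5: 3})
    bits = encode_simplitig([1, 5], EncodingMode(1, False), gt, None, 16, 6)
    assert bits == "0" + gt.code[1] + "10" + "010"


def test_encode_diff_h_flag_only_when_maxdif_2():
    gt = table_for(6, {1: 5, 5: 3, 6: 1})
    # h=2 between 1 (={0}) and 6 (={1,2}): positions 0,1,2 change -> h=3? no:
    # 1 ^ 6 = 7, h=3, so use 1 -> 5 (h=1) and 5 -> 6 (h=2: positions 0 and 1)
    bits = encode_simplitig([5, 6], EncodingMode(2, False), gt, None, 16, 6)
    assert bits == "0" + gt.code[5] + "10" + "1" + "000" + "001"


def test_run_cost_formula():
    # n identical classes cost 2 + |code| + q + 1 + log2(runDivisor) bits,
    # with q = (n-1) // runDivisor (maxDif=0: 1-bit prefixes on both tokens)
    gt = table_for(4, {3: 100, 1: 1})
    code = gt.code[3]
    for n in (2, 16, 17, 50, 200):
        bits = encode_simplitig([3] * n, EncodingMode(0, False), gt, None, 16, 4)
        q = (n - 1) // 16
        assert len(bits) == 2 + len(code) + q + 1 + 4


@pytest.mark.parametrize("meta,expected", list(enumerate(META_ORDER)))
def test_metadata_enumeration(meta, expected):
    mode = EncodingMode(*expected)
    assert encode_metadata(mode) == format(meta, "03b")
    assert decode_metadata(meta) == mode


def test_metadata_single_class_and_reserved():
    assert encode_metadata(None, single_class=True) == "110"
    assert decode_metadata(META_SINGLE_CLASS) is None
    with pytest.raises(CorruptArchiveError):
        decode_metadata(7)


def _random_instance(rng):
    C = rng.randint(1, 16)
    M = rng.randint(1, min(2**C - 1, 10))
    classes = rng.sample(range(1, 2**C), M)
    freq = {c: rng.randint(1, 40) for c in classes}
    gt = table_for(C, freq)
    n = rng.randint(1, 60)
    if rng.random() < 0.5:
        # runs of random length to exercise skip / end-of-run
        seq = []
        while len(seq) < n:
            seq.extend([rng.choice(classes)] * rng.randint(1, 12))
        seq = seq[:n]
    else:
        seq = [rng.choice(classes) for _ in range(n)]
    return C, gt, seq


@pytest.mark.parametrize("seed", range(40))
def test_roundtrip_all_modes(seed):
    rng = random.Random(seed)
    C, gt, seq = _random_instance(rng)
    for max_dif in (0, 1, 2):
        for use_local in (False, True):
            mode = EncodingMode(max_dif, use_local)
            lt = build_local_table(seq, gt) if use_local else None
            bits = encode_simplitig(seq, mode, gt, lt, 16, C)
            reader = reader_for(bits)
            out = decode_simplitig(reader, len(seq), mode, gt, lt, 16, C)
            assert out == seq
            assert reader.exhausted()  # stream consumed exactly


@given(st.integers(0, 10_000))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_roundtrip_property(seed):
    rng = random.Random(seed)
    C, gt, seq = _random_instance(rng)
    enc = choose_mode(seq, gt)
    mode = decode_metadata(enc.meta)
    reader = reader_for(enc.m_bits)
    assert decode_simplitig(reader, len(seq), mode, gt, enc.local_table, 16, C) == seq
    assert reader.exhausted()


@pytest.mark.parametrize("seed", range(25))
def test_choose_mode_dominates_every_fixed_mode(seed):
    rng = random.Random(1000 + seed)
    C, gt, seq = _random_instance(rng)
    enc = choose_mode(seq, gt)
    from cdbgzip.class_tables import serialize_local_table

    for max_dif, use_local in META_ORDER:
        mode = EncodingMode(max_dif, use_local)
        lt = build_local_table(seq, gt) if use_local else None
        bits = encode_simplitig(seq, mode, gt, lt, 16, C)
        cost = len(bits) + (len(serialize_local_table(lt, gt)) if lt else 0)
        assert enc.cost <= cost


def test_single_class_flag_uses_bare_global_id():
    gt = table_for(3, {1: 9, 2: 1})
    enc = choose_mode([1] * 9, gt, CodecConfig(single_class_flag=True))
    assert enc.meta == META_SINGLE_CLASS
    assert enc.m_bits == gt.code[1]
    assert enc.local_bits == ""
    # and never worse than the best of the six plain modes
    plain = choose_mode([1] * 9, gt, CodecConfig())
    assert len(enc.m_bits) <= plain.cost


def test_prefix_freeness_of_simplitig_encodings():
    # no encoded class sequence is a proper prefix of a different sequence's
    # encoding under the same mode and tables (exhaustive, small alphabet)
    import itertools

    gt = table_for(2, {1: 4, 2: 3, 3: 2})
    mode = EncodingMode(1, False)
    for n in (1, 2, 3):
        seen = {}
        for seq in itertools.product([1, 2, 3], repeat=n):
            bits = encode_simplitig(list(seq), mode, gt, None, 4, 2)
            assert bits not in seen
            seen[bits] = seq
        for a, b in itertools.combinations(sorted(seen), 2):
            assert not b.startswith(a) or seen[a] == seen[b]
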