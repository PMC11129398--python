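import itertools
import random

import pytest

from cdbgzip.bitio import BitReader, BitWriter, ceil_log2
from cdbgzip.class_tables import (
    build_global_table,
    build_local_table,
    deserialize_global_table,
    deserialize_local_table,
    serialize_global_table,
    serialize_local_table,
)
from cdbgzip.color_matrix import ClassCensus
from cdbgzip.errors import CorruptArchiveError


def make_census(C, freq):
    return ClassCensus(C, sorted(freq), dict(freq))


def optimal_prefix_cost(freqs):
    """Independent oracle: minimum of sum(f*l) over all length assignments
    satisfying the Kraft inequality (every such assignment is realizable as a
    prefix code). Exhaustive for small M."""
    M = len(freqs)
    if M == 1:
        return freqs[0]  # one symbol still needs one bit
    best = None
    for lengths in itertools.product(range(1, M + 1), repeat=M):
        if sum(2 ** -l for l in lengths) <= 1:
            cost = sum(f * l for f, l in zip(freqs, lengths))
            best = cost if best is None else min(best, cost)
    return best


def huffman_cost(table):
    return sum(table.census.freq[c] * len(table.code[c]) for c in table.census.classes)


def test_worked_example_code_lengths():
    # frequencies 3, 2, 2 -> lengths 1, 2, 2 with the length 1 on the
    # most frequent class
    census = make_census(3, {7: 3, 6: 2, 2: 2})
    table = build_global_table(census)
    assert len(table.code[7]) == 1
    assert len(table.code[6]) == 2
    assert len(table.code[2]) == 2


def test_single_class_gets_one_bit_code():
    table = build_global_table(make_census(3, {1: 10}))
    assert table.code == {1: "0"}


def test_uniform_four_classes_all_two_bits():
    table = build_global_table(make_census(4, {1: 5, 2: 5, 4: 5, 8: 5}))
    assert all(len(c) == 2 for c in table.code.values())


@pytest.mark.parametrize("seed", range(8))
def test_huffman_matches_exhaustive_optimum(seed):
    rng = random.Random(seed)
    M = rng.randint(1, 6)
    classes = rng.sample(range(1, 64), M)
    freq = {c: rng.randint(1, 30) for c in classes}
    table = build_global_table(make_census(6, freq))
    assert huffman_cost(table) == optimal_prefix_cost(
        [freq[c] for c in sorted(freq)]
    )


def test_codes_are_prefix_free_and_deterministic():
    freq = {c: (c * 7919) % 13 + 1 for c in [1, 2, 3, 5, 9, 17, 33]}
    t1 = build_global_table(make_census(6, freq))
    t2 = build_global_table(make_census(6, freq))
    assert t1.code == t2.code
    codes = sorted(t1.code.values())
    for a, b in itertools.combinations(codes, 2):
        assert not b.startswith(a) and not a.startswith(b)


def test_worked_example_serialization_bits():
    # classes as integers: {1}->2, {1,2}->6, {0,1,2}->7; sorted (2, 6, 7);
    # Delta = first vector "010" + index field "10" (pos 2) + "00" (pos 0)
    census = make_census(3, {7: 3, 6: 2, 2: 2})
    ser = serialize_global_table(build_global_table(census))
    assert ser.delta == "0101000"
    assert ser.boundary == "1001010"
    assert ser.freq_lines == ["2\t2", "6\t2", "7\t3"]


def test_single_class_serialization():
    census = make_census(3, {1: 4})  # class {0}
    ser = serialize_global_table(build_global_table(census))
    assert ser.delta == "100"
    assert ser.boundary == "100"


def test_worked_example_deserialization():
    census = make_census(3, {7: 3, 6: 2, 2: 2})
    table = build_global_table(census)
    back = deserialize_global_table(serialize_global_table(table), 3)
    assert back.census.classes == [2, 6, 7]
    assert back.census.freq == {2: 2, 6: 2, 7: 3}
    assert back.code == table.code


@pytest.mark.parametrize("seed", range(10))
def test_serialization_roundtrip_random(seed):
    rng = random.Random(seed)
    C = rng.randint(1, 16)
    M = rng.randint(1, min(2**C - 1, 20))
    classes = rng.sample(range(1, 2**C), M)
    freq = {c: rng.randint(1, 50) for c in classes}
    table = build_global_table(make_census(C, freq))
    ser = serialize_global_table(table)
    # closed form: |Delta| = C + ceil(log2 C) * sum of Hamming distances
    srt = sorted(classes)
    hsum = sum((a ^ b).bit_count() for a, b in zip(srt, srt[1:]))
    assert len(ser.delta) == C + max(1, ceil_log2(C)) * hsum
    assert ser.boundary.count("1") == M and ser.boundary[0] == "1"
    back = deserialize_global_table(ser, C)
    assert back.census.classes == srt
    assert back.census.freq == freq
    assert back.code == table.code


def test_deserialize_rejects_length_mismatch():
    census = make_census(3, {7: 3, 6: 2, 2: 2})
    ser = serialize_global_table(build_global_table(census))
    ser.boundary = ser.boundary[:-1]
    with pytest.raises(CorruptArchiveError):
        deserialize_global_table(ser, 3)


def test_local_table_first_occurrence_order():
    table = build_global_table(make_census(4, {3: 5, 8: 3, 4: 2}))
    lt = build_local_table([3, 8, 3], table)
    assert lt.local_to_global == [3, 8]
    assert lt.ell == 2
    assert lt.id_width == 1
    assert build_local_table([3, 3, 3], table).ell == 1
    assert build_local_table([3, 3, 3], table).id_width == 0  # 0-bit IDs
    assert build_local_table([3, 8, 4], table).id_width == 2  # ell=3 -> 2 bits


def test_local_table_serialization_layout():
    # M=4, ell=2, codes "0" and "10": 2-bit count field storing ell-1=1,
    # then the two global codes
    freq = {1: 10, 2: 3, 4: 2, 8: 1}
    table = build_global_table(make_census(4, freq))
    assert table.code[1] == "0"
    lt = build_local_table([1, 2], table)
    bits = serialize_local_table(lt, table)
    assert bits == "01" + table.code[1] + table.code[2]
    assert bits.startswith("01" + "0")


@pytest.mark.parametrize("seed", range(6))
def test_local_table_roundtrip(seed):
    rng = random.Random(seed)
    C = rng.randint(2, 10)
    classes = rng.sample(range(1, 2**C), rng.randint(1, 8))
    freq = {c: rng.randint(1, 20) for c in classes}
    table = build_global_table(make_census(C, freq))
    seq = [rng.choice(classes) for _ in range(15)]
    lt = build_local_table(seq, table)
    bits = serialize_local_table(lt, table)
    writer = BitWriter()
    writer.write_bits(bits)
    reader = BitReader(*writer.getvalue())
    back = deserialize_local_table(reader, table)
    assert back.local_to_global == lt.local_to_global
    assert reader.exhausted()


def test_ell_cap_overflow_raises():
    classes = list(range(1, 11))
    freq = {c: 1 for c in classes}
    table = build_global_table(make_census(4, freq))
    lt = build_local_table(classes, table)  # ell = 10 > 8
    with pytest.raises(ValueError):
        serialize_local_table(lt, table, ell_cap_3bit=True)
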