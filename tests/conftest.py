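import pytest

from cdbgzip.kmer import KmerSet

# The fully worked 3-color, k=5 instance used throughout: three k-mer sets
# whose union has 7 k-mers and exactly three distinct color classes
# ({0,1,2} x3, {1,2} x2, {1} x2).
E0 = {"TCAAA", "CAAAA", "AAAAT"}
E1 = {"TCAAA", "CAAAA", "AAAAT", "AAATT", "CAAAG", "AAATC", "AATCG"}
E2 = {"TCAAA", "CAAAA", "AAAAT", "AAATT", "CAAAG"}


@pytest.fixture
def worked_example_colors() -> list[KmerSet]:
    return [KmerSet(5, set(E0)), KmerSet(5, set(E1)), KmerSet(5, set(E2))]


@pytest.fixture
def worked_example_truth() -> dict[str, int]:
    """Canonical k-mer -> color-vector integer (bit i = color i)."""
    truth: dict[str, int] = {}
    for i, E in enumerate([E0, E1, E2]):
        for km in E:
            truth[km] = truth.get(km, 0) | (1 << i)
    return truth
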