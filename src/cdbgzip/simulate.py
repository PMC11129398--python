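"""Synthetic colored de Bruijn graphs with controllable sharing structure.

The generator draws one ancestral random sequence and derives each color's
sequence by independent per-base substitutions, so the substitution rate
directly tunes how much of the union k-mer set is shared between colors: rate
0 gives every k-mer all C colors, higher rates push the single-color fraction
toward 100%. An optional read model samples uniform substrings with per-base
errors, which makes abundance thresholds (a >= 2) meaningful.

Every draw comes from a seeded generator, so a fixed config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from .kmer import KmerSet, extract_kmers
from .spss import build_spss

_NUCS = "ACGT"


@dataclass
class SimulationConfig:
    C: int = 3
    genome_len: int = 1000
    k: int = 21
    mutation_rate: float = 0.01
    coverage_model: Literal["none", "reads"] = "none"
    coverage: float = 10.0  # mean depth under the read model
    read_len: int = 100
    error_rate: float = 0.002  # per-base sequencing error under the read model
    abundance: int = 1  # threshold a applied when extracting each color's set
    target_single_color_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 1:
            raise ValueError("C must be >= 1")
        if self.genome_len < self.k:
            raise ValueError("genome_len must be >= k")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass
class SimulatedCdbg:
    """Per-color FASTA records plus the truth colored k-mer set."""

    config: SimulationConfig
    records: list[list[str]]  # records[i] = FASTA sequences of color i
    colors: list[KmerSet]  # truth per-color canonical k-mer sets

    def truth_vectors(self) -> dict[str, int]:
        """Truth map canonical k-mer -> color-vector integer (bit i = color i)."""
        vectors: dict[str, int] = {}
        for i, color in enumerate(self.colors):
            bit = 1 << i
            for km in color.members:
                vectors[km] = vectors.get(km, 0) | bit
        return vectors

    def single_color_fraction(self) -> float:
        """Percentage of union k-mers present in exactly one color."""
        vectors = self.truth_vectors()
        if not vectors:
            return 0.0
        single = sum(1 for v in vectors.values() if v.bit_count() == 1)
        return 100.0 * single / len(vectors)

    def write_fastas(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, recs in enumerate(self.records):
            path = outdir / f"color_{i}.fa"
            with open(path, "w") as fh:
                for j, seq in enumerate(recs):
                    fh.write(f">color{i}_seq{j}\n{seq}\n")
            paths.append(path)
        return paths

    def write_truth_tsv(self, path: str | Path) -> None:
        vectors = self.truth_vectors()
        C = self.config.C
        with open(path, "w") as fh:
            for km in sorted(vectors):
                bits = "".join(
                    "1" if (vectors[km] >> i) & 1 else "0" for i in range(C)
                )
                fh.write(f"{km}\t{bits}\n")


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_NUCS) for _ in range(length))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([n for n in _NUCS if n != base])
    return "".join(out)


def _sample_reads(
    rng: random.Random, genome: str, coverage: float, read_len: int, error_rate: float
) -> list[str]:
    read_len = min(read_len, len(genome))
    n_reads = max(1, round(coverage * len(genome) / read_len))
    reads = []
    for _ in range(n_reads):
        start = rng.randrange(0, len(genome) - read_len + 1)
        reads.append(_mutate(rng, genome[start : start + read_len], error_rate))
    return reads


def _simulate_at_rate(cfg: SimulationConfig, rate: float) -> SimulatedCdbg:
    rng = random.Random(cfg.seed)
    ancestor = _random_seq(rng, cfg.genome_len)
    records: list[list[str]] = []
    colors: list[KmerSet] = []
    for _ in range(cfg.C):
        genome = _mutate(rng, ancestor, rate)
        if cfg.coverage_model == "reads":
            recs = _sample_reads(rng, genome, cfg.coverage, cfg.read_len, cfg.error_rate)
        else:
            recs = [genome]
        records.append(recs)
        colors.append(extract_kmers(recs, cfg.k, cfg.abundance))
    return SimulatedCdbg(cfg, records, colors)


def simulate_cdbg(cfg: SimulationConfig) -> SimulatedCdbg:
    """Draw a synthetic cdBG under the config.

    When target_single_color_fraction is set, the substitution rate is found
    by bisection on the realized fraction (the relationship is monotone in
    expectation); otherwise cfg.mutation_rate is used directly.
    """
    if cfg.target_single_color_fraction is None:
        return _simulate_at_rate(cfg, cfg.mutation_rate)
    target = cfg.target_single_color_fraction
    lo, hi = 0.0, 0.5
    best = _simulate_at_rate(cfg, lo)
    for _ in range(12):
        mid = (lo + hi) / 2
        sim = _simulate_at_rate(cfg, mid)
        frac = sim.single_color_fraction()
        if abs(frac - target) < abs(best.single_color_fraction() - target):
            best = sim
        if frac < target:
            lo = mid
        else:
            hi = mid
    return best


@dataclass
class DatasetStats:
    C: int
    M: int
    n_kmers: int
    single_color_percent: float
    n_simplitigs: int


def dataset_stats(colors: list[KmerSet]) -> DatasetStats:
    """Summary statistics of a colored k-mer set: number of colors, distinct
    color classes, union size, single-color percentage, simplitig count."""
    if not colors:
        raise ValueError("need at least one color")
    vectors: dict[str, int] = {}
    for i, color in enumerate(colors):
        bit = 1 << i
        for km in color.members:
            vectors[km] = vectors.get(km, 0) | bit
    n = len(vectors)
    classes = set(vectors.values())
    single = sum(1 for v in vectors.values() if v.bit_count() == 1)
    union = KmerSet(colors[0].k, set(vectors))
    spss = build_spss(union) if n else None
    return DatasetStats(
        C=len(colors),
        M=len(classes),
        n_kmers=n,
        single_color_percent=100.0 * single / n if n else 0.0,
        n_simplitigs=len(spss.simplitigs) if spss else 0,
    )
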