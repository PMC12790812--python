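"""Synthetic mock communities with known ground truth.

Generates genomes that carry a configurable number of rRNA-operon-like
amplicon loci (a concrete forward-primer realization, a random core, and
the reverse complement of a concrete reverse-primer realization) separated
by random intergenic spacers.  Degenerate primer positions are
instantiated to a random concrete base from the degeneracy set per operon,
so downstream extraction must genuinely handle IUPAC matching.  Copies
2..k of an operon are the first copy mutated by substitutions at a
configurable per-base rate, emulating intra-genome operon divergence.

Everything is seeded: a fixed seed gives byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from hifisim.io_formats import (
    CONCRETE_BASES,
    IUPAC_CODES,
    BarcodePair,
    SeqRecord,
    reverse_complement,
)


@dataclasses.dataclass(frozen=True)
class TruthRow:
    """One embedded amplicon: where it is and what it should extract as."""

    genome_id: str
    start: int
    end: int
    strand: str
    asv_seq: str  # primer-inclusive, forward orientation


@dataclasses.dataclass
class MockCommunitySpec:
    """Parameters of a synthetic community.

    ``operons_per_genome[i]`` is genome *i*'s operon copy number;
    ``intra_genome_divergence`` is the per-base substitution probability
    between operon copies within a genome (0 => identical copies, a single
    ASV per genome).
    """

    n_genomes: int = 3
    operons_per_genome: list[int] = dataclasses.field(default_factory=lambda: [3, 2, 1])
    asv_core_length: int = 300
    intra_genome_divergence: float = 0.02
    intergenic_length: int = 200
    seed: int = 0
    reverse_strand_operons: bool = False

    def __post_init__(self) -> None:
        if len(self.operons_per_genome) != self.n_genomes:
            raise ValueError("operons_per_genome must have n_genomes entries")
        if any(c < 1 for c in self.operons_per_genome):
            raise ValueError("operon copy numbers must be >= 1")
        if not 0.0 <= self.intra_genome_divergence <= 0.2:
            raise ValueError("intra_genome_divergence must be in [0, 0.2]")
        if self.asv_core_length <= 0 or self.intergenic_length <= 0:
            raise ValueError("lengths must be > 0")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(CONCRETE_BASES))[rng.integers(0, 4, length)])


def realize_primer(primer: str, rng: np.random.Generator) -> str:
    """Replace each degenerate position with a random base from its set."""
    out = []
    for ch in primer:
        choices = sorted(IUPAC_CODES[ch])
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def _mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.flatnonzero(hit)
    base_codes = np.frombuffer(CONCRETE_BASES.encode("ascii"), dtype=np.uint8)
    code_of = {c: i for i, c in enumerate(base_codes)}
    for i in idx:
        cur = code_of[arr[i]]
        arr[i] = base_codes[(cur + rng.integers(1, 4)) % 4]
    return arr.tobytes().decode("ascii")


def generate_mock_genome(
    spec: MockCommunitySpec,
    genome_index: int,
    fwd_primer: str,
    rev_primer: str,
) -> tuple[SeqRecord, list[TruthRow]]:
    """Build one genome and the truth table of its embedded amplicons.

    The core of each operon must be long enough to remain unique; the
    combined primer length plus a small margin is required.
    """
    if spec.asv_core_length < len(fwd_primer) + len(rev_primer) + 10:
        raise ValueError("asv_core_length too short for the primer pair")
    if not 0 <= genome_index < spec.n_genomes:
        raise ValueError(f"genome_index {genome_index} out of range")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(spec.seed, 7, genome_index))
    )
    genome_id = f"genome{genome_index + 1}"
    n_copies = spec.operons_per_genome[genome_index]

    # first copy: concrete primer realizations + random core
    fwd_real = realize_primer(fwd_primer, rng)
    rev_real = realize_primer(rev_primer, rng)
    core = _random_dna(rng, spec.asv_core_length)
    first = fwd_real + core + reverse_complement(rev_real)

    operons = [first]
    for _ in range(n_copies - 1):
        # mutate only the core so the primer sites stay in-degeneracy
        mutated_core = _mutate_substitutions(core, spec.intra_genome_divergence, rng)
        operons.append(fwd_real + mutated_core + reverse_complement(rev_real))

    parts: list[str] = []
    truth: list[TruthRow] = []
    pos = 0
    for op in operons:
        spacer = _random_dna(rng, spec.intergenic_length)
        parts.append(spacer)
        pos += len(spacer)
        strand = "+"
        placed = op
        if spec.reverse_strand_operons and rng.random() < 0.5:
            strand = "-"
            placed = reverse_complement(op)
        parts.append(placed)
        truth.append(
            TruthRow(
                genome_id=genome_id,
                start=pos,
                end=pos + len(op),
                strand=strand,
                asv_seq=op,
            )
        )
        pos += len(op)
    parts.append(_random_dna(rng, spec.intergenic_length))
    seq = "".join(parts)
    return SeqRecord(id=genome_id, seq=seq, description="synthetic mock genome"), truth


def generate_community(
    spec: MockCommunitySpec, fwd_primer: str, rev_primer: str
) -> tuple[list[SeqRecord], list[TruthRow]]:
    """All genomes of the community plus the combined truth table."""
    genomes: list[SeqRecord] = []
    truth: list[TruthRow] = []
    for g in range(spec.n_genomes):
        rec, rows = generate_mock_genome(spec, g, fwd_primer, rev_primer)
        genomes.append(rec)
        truth.extend(rows)
    return genomes, truth


def generate_barcodes(n_samples: int, length: int = 16, seed: int = 0) -> list[BarcodePair]:
    """Distinct random dual barcodes, one pair per sample."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 11)))
    seen: set[tuple[str, str]] = set()
    pairs: list[BarcodePair] = []
    while len(pairs) < n_samples:
        fwd = _random_dna(rng, length)
        rev = _random_dna(rng, length)
        if (fwd, rev) in seen:
            continue
        seen.add((fwd, rev))
        pairs.append(BarcodePair(f"S{len(pairs) + 1}", fwd, rev))
    return pairs


def generate_empirical_np_table(
    mu: float,
    sigma: float,
    n_draws: int,
    seed: int = 0,
    np_min: int = 1,
    np_max: int = 255,
) -> list[tuple[int, int]]:
    """Synthetic pass-number histogram, stand-in for a real-run extraction.

    Draws ``n_draws`` lognormal(mu, sigma) pass numbers, rounds to the
    nearest integer, and rejection-truncates into [np_min, np_max].
    Returns sorted ``(np, count)`` rows whose counts sum to n_draws.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 13)))
    vals = np.zeros(n_draws, dtype=np.int64)
    pending = np.arange(n_draws)
    while pending.size:
        draw = np.rint(rng.lognormal(mu, sigma, pending.size)).astype(np.int64)
        ok = (draw >= np_min) & (draw <= np_max)
        vals[pending[ok]] = draw[ok]
        pending = pending[~ok]
    nps, counts = np.unique(vals, return_counts=True)
    return [(int(v), int(c)) for v, c in zip(nps, counts)]


def write_np_table(rows: list[tuple[int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("np\tcount\n")
        for np_val, count in rows:
            fh.write(f"{np_val}\t{count}\n")


def write_truth_table(rows: list[TruthRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tstart\tend\tstrand\tasv_seq\n")
        for r in rows:
            fh.write(f"{r.genome_id}\t{r.start}\t{r.end}\t{r.strand}\t{r.asv_seq}\n")
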