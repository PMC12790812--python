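"""Sequence I/O primitives: FASTA/FASTQ, barcode tables, run configuration.

All sequences are DNA over the IUPAC nucleotide alphabet, upper-cased on
read.  FASTQ output follows PacBio CCS naming conventions
(``<movie>/<zmw>/ccs``) with simulation provenance carried in the header
comment field so the read name itself stays vendor-conformant.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq

# 15 IUPAC nucleotide codes (DNA only; U rejected).
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_CODES)
CONCRETE_BASES = "ACGT"

PHRED_OFFSET = 33
MAX_PHRED = 93  # FASTQ '~'


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclasses.dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence (genome, ASV, template, ...)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record must have a non-empty id")
        if not self.seq:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - IUPAC_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class BarcodePair:
    """Dual barcodes identifying one sample in a multiplexed run."""

    sample_id: str
    fwd_barcode: str
    rev_barcode: str

    def __post_init__(self) -> None:
        if not self.fwd_barcode or not self.rev_barcode:
            raise ValueError(f"sample {self.sample_id!r}: barcodes must be non-empty")


@dataclasses.dataclass
class RunConfig:
    """Full parameterization of one simulation run.

    ``subread_accuracy`` is the per-alignment-column probability that a
    subread base matches the template (default 0.65); ``error_ratio``
    splits errors into substitution:insertion:deletion mass (default
    6:55:39, the PacBio RSII ratio).  ``np_min``/``np_max`` bound the
    number of CCS passes per molecule (default 2-59).
    """

    n_samples: int = 2
    reads_per_sample: int = 100
    abundance_dist: str = "uniform"
    abundance_params: dict = dataclasses.field(default_factory=dict)
    subread_accuracy: float = 0.65
    error_ratio: tuple[float, float, float] = (6.0, 55.0, 39.0)
    np_source: str = "lognormal"
    np_min: int = 2
    np_max: int = 59
    np_mu: float = 2.3
    np_sigma: float = 0.5
    np_table: str | None = None
    seed: int = 0
    primer_fwd: str = "AGRGTTYGATYMTGGCTCAG"  # 27F
    primer_rev: str = "RGYTACCTTGTTACGACTT"  # 1492R
    max_primer_mismatch: int = 2
    min_product_len: int | None = None
    max_product_len: int | None = None
    workers: int = 1

    def __post_init__(self) -> None:
        if self.np_min < 1:
            raise ValueError("np_min must be >= 1")
        if self.np_max < self.np_min:
            raise ValueError("np_max must be >= np_min")
        if not 0.0 < self.subread_accuracy <= 1.0:
            raise ValueError("subread_accuracy must be in (0, 1]")
        if sum(self.error_ratio) <= 0 or any(w < 0 for w in self.error_ratio):
            raise ValueError("error_ratio weights must be non-negative and sum > 0")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be > 0")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be > 0")
        if self.abundance_dist not in {"uniform", "lognormal", "powerlaw", "empirical"}:
            raise ValueError(f"unknown abundance_dist {self.abundance_dist!r}")
        if self.np_source not in {"empirical", "lognormal"}:
            raise ValueError(f"unknown np_source {self.np_source!r}")
        self.error_ratio = tuple(float(w) for w in self.error_ratio)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON (keys mirror the field names)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "error_ratio" in data:
            data["error_ratio"] = tuple(data["error_ratio"])
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["error_ratio"] = list(data["error_ratio"])
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


def _normalize_seq(raw: str, record_id: str) -> str:
    seq = raw.upper()
    if "U" in seq:
        raise FormatError(f"record {record_id!r} contains 'U' (RNA not supported)")
    return seq


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Sequences are upper-cased; duplicate ids and empty sequences are
    format errors naming the offending record.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = _normalize_seq(str(rec.seq), rec.id)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, seq=seq, description=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> int:
    """Write records as FASTA; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
            n += 1
    return n


def phred_to_ascii(quals: Sequence[int]) -> str:
    """Encode integer Phred scores as a Phred+33 quality string."""
    return "".join(chr(min(int(q), MAX_PHRED) + PHRED_OFFSET) for q in quals)


def write_fastq(reads: Iterable["SimulatedReadLike"], path: str | Path) -> int:
    """Write simulated CCS reads as 4-line FASTQ (Phred+33).

    Header: ``@<movie>/<zmw>/ccs sample=.. genome=.. asv=.. np=..``.
    Raises if any read's quality length differs from its sequence length.
    """
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            if len(read.seq) != len(read.qual):
                raise ValueError(
                    f"read {read.read_id!r}: seq length {len(read.seq)} != "
                    f"qual length {len(read.qual)}"
                )
            comment = (
                f"sample={read.sample_id} genome={read.genome_id} "
                f"asv={read.asv_id} np={read.np}"
            )
            fh.write(f"@{read.read_id} {comment}\n{read.seq}\n+\n")
            fh.write(phred_to_ascii(read.qual) + "\n")
            n += 1
    return n


def write_ground_truth(reads: Iterable["SimulatedReadLike"], path: str | Path) -> int:
    """Sidecar TSV with per-read provenance (robust to header stripping)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("read_id\tsample_id\tgenome_id\tasv_id\tnp\ttemplate_len\n")
        for read in reads:
            fh.write(
                f"{read.read_id}\t{read.sample_id}\t{read.genome_id}\t"
                f"{read.asv_id}\t{read.np}\t{read.template_len}\n"
            )
            n += 1
    return n


def read_barcode_table(path: str | Path) -> list[BarcodePair]:
    """Read a dual-barcode TSV: ``sample_id<TAB>fwd_barcode<TAB>rev_barcode``."""
    pairs: list[BarcodePair] = []
    seen_pairs: set[tuple[str, str]] = set()
    seen_samples: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample_id", "fwd_barcode", "rev_barcode"]:
            raise FormatError(f"{path}: expected header sample_id/fwd_barcode/rev_barcode")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            sample, fwd, rev = parts[0], parts[1].upper(), parts[2].upper()
            if sample in seen_samples:
                raise FormatError(f"{path}:{lineno}: duplicate sample_id {sample!r}")
            if (fwd, rev) in seen_pairs:
                raise FormatError(f"{path}:{lineno}: duplicate barcode pair for {sample!r}")
            seen_samples.add(sample)
            seen_pairs.add((fwd, rev))
            pairs.append(BarcodePair(sample, fwd, rev))
    return pairs


def write_barcode_table(pairs: Iterable[BarcodePair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tfwd_barcode\trev_barcode\n")
        for p in pairs:
            fh.write(f"{p.sample_id}\t{p.fwd_barcode}\t{p.rev_barcode}\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement with full IUPAC degeneracy complementation.

    R<->Y, M<->K, S<->S, W<->W, B<->V, D<->H, N<->N.  Raises on any
    character outside the IUPAC nucleotide alphabet.
    """
    bad = set(seq) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return str(Seq(seq).reverse_complement())


def is_concrete_dna(seq: str) -> bool:
    """True iff seq contains only A/C/G/T (no degeneracies)."""
    return not (set(seq) - set(CONCRETE_BASES))
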