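"""In-silico PCR: degenerate-primer site scanning and amplicon extraction.

Primer matching uses IUPAC degeneracy semantics: a genome base matches a
primer position iff it belongs to the primer code's degeneracy set.  An
``N`` in the genome matches nothing except a primer ``N`` (an ambiguous
genome base cannot be claimed as a primer hit).  Both strands are scanned;
minus-strand products are reported with plus-strand coordinates and a
strand flag, with the product sequence oriented 5'->3' from the forward
primer.

The stored product ``seq`` is primer-inclusive (both annealing footprints
retained); the primer-exclusive ``insert`` used for template building is
recorded separately.  Length filtering (on the primer-inclusive product)
is configurable and off by default.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np

from hifisim.io_formats import IUPAC_CODES, SeqRecord, reverse_complement

_BASE_ORD = {b: i for i, b in enumerate("ACGTRYSWKMBDHVN")}


@dataclasses.dataclass(frozen=True)
class Amplicon:
    """One primer-to-primer PCR product found in a genome."""

    genome_id: str
    seq: str  # primer-inclusive product, forward orientation
    insert: str  # primer-exclusive insert
    fwd_primer_site: str  # concrete genomic sequence under the forward primer
    rev_primer_site: str  # concrete genomic sequence under the reverse primer (read 5'->3' on the reverse primer's strand)
    start: int  # 0-based half-open on the + strand
    end: int
    strand: str  # '+' or '-'
    fwd_mismatches: int
    rev_mismatches: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end - self.start != len(self.seq):
            raise ValueError("coordinate span does not match product length")


@dataclasses.dataclass
class AmpliconSet:
    """All products extracted from one genome, with the amplitype.

    ``asv_of`` maps each amplicon index to its ASV id; identical product
    sequences collapse into a single ASV with summed multiplicity.
    """

    genome_id: str
    amplicons: list[Amplicon]
    asv_seqs: dict[str, str] = dataclasses.field(default_factory=dict)
    asv_inserts: dict[str, str] = dataclasses.field(default_factory=dict)
    multiplicity: dict[str, int] = dataclasses.field(default_factory=dict)
    asv_of: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.asv_seqs and self.amplicons:
            self._collapse()

    def _collapse(self) -> None:
        order: dict[str, str] = {}
        counts: Counter[str] = Counter()
        self.asv_of = []
        for amp in self.amplicons:
            if amp.seq not in order:
                order[amp.seq] = f"{self.genome_id}.asv{len(order) + 1}"
            asv_id = order[amp.seq]
            counts[asv_id] += 1
            self.asv_of.append(asv_id)
        self.asv_seqs = {asv_id: seq for seq, asv_id in order.items()}
        self.asv_inserts = {}
        for amp, asv_id in zip(self.amplicons, self.asv_of):
            self.asv_inserts.setdefault(asv_id, amp.insert)
        self.multiplicity = dict(counts)

    @property
    def n_amplicons(self) -> int:
        return len(self.amplicons)


def iupac_match(primer: str, window: str, max_mismatch: int = 0) -> tuple[bool, int]:
    """Compare a primer to an equal-length genome window under IUPAC semantics.

    Returns ``(matches, n_mismatch)`` where position *i* mismatches iff
    ``window[i]`` is not in the degeneracy set of ``primer[i]``.
    """
    if len(primer) != len(window):
        raise ValueError(
            f"primer length {len(primer)} != window length {len(window)}"
        )
    n_mismatch = 0
    for p, w in zip(primer, window):
        allowed = IUPAC_CODES.get(p)
        if allowed is None:
            raise ValueError(f"invalid primer character {p!r}")
        # genome N only matches primer N
        if w == "N":
            ok = p == "N"
        else:
            ok = w in allowed
        if not ok:
            n_mismatch += 1
    return n_mismatch <= max_mismatch, n_mismatch


def _primer_mismatch_profile(primer: str, genome: np.ndarray) -> np.ndarray:
    """Mismatch count of `primer` at every genome offset (vectorized scan).

    `genome` is an int8 array of indices into the IUPAC ordering; returns
    an int array of length ``len(genome) - len(primer) + 1``.
    """
    m = len(primer)
    n = genome.size
    if n < m:
        return np.zeros(0, dtype=np.int32)
    n_off = n - m + 1
    mismatches = np.zeros(n_off, dtype=np.int32)
    for i, p in enumerate(primer):
        allowed = IUPAC_CODES[p]
        # genome N (code 14) matches only primer N
        codes = [_BASE_ORD[b] for b in allowed if b in "ACGT"]
        if p == "N":
            codes.append(_BASE_ORD["N"])
        col = genome[i : i + n_off]
        ok = np.isin(col, codes)
        mismatches += ~ok
    return mismatches


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int8)
    for b, i in _BASE_ORD.items():
        lut[ord(b)] = i
    out = lut[arr]
    if (out < 0).any():
        raise ValueError("genome contains characters outside the IUPAC alphabet")
    return out


def _scan_plus_strand(
    seq: str,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch: int,
    min_len: int | None,
    max_len: int | None,
) -> list[tuple[int, int, int, int]]:
    """All (start, end, fwd_mm, rev_mm) products on the given strand."""
    genome = _encode(seq)
    rc_rev = reverse_complement(rev_primer)
    fwd_mm = _primer_mismatch_profile(fwd_primer, genome)
    rev_mm = _primer_mismatch_profile(rc_rev, genome)
    fwd_sites = np.flatnonzero(fwd_mm <= max_mismatch)
    rev_sites = np.flatnonzero(rev_mm <= max_mismatch)
    out: list[tuple[int, int, int, int]] = []
    lf, lr = len(fwd_primer), len(rc_rev)
    for i in fwd_sites:
        # reverse site must start at/after the end of the forward footprint
        for j in rev_sites[rev_sites >= i + lf]:
            end = int(j) + lr
            length = end - int(i)
            if max_len is not None and length > max_len:
                break  # rev_sites sorted ascending: all later are longer
            if min_len is not None and length < min_len:
                continue
            out.append((int(i), end, int(fwd_mm[i]), int(rev_mm[j])))
    return out


def extract_amplicons(
    genome: SeqRecord,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch: int = 2,
    min_len: int | None = None,
    max_len: int | None = None,
) -> AmpliconSet:
    """Extract all amplicons from both strands of a genome.

    Nested/overlapping candidate products are all reported.  Identical
    product sequences collapse into one ASV with multiplicity; ASV ids
    are ``<genome_id>.asv<k>`` in order of first occurrence.
    """
    if min_len is not None and max_len is not None and min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    lf, lr = len(fwd_primer), len(rev_primer)
    amplicons: list[Amplicon] = []

    for strand, seq in (("+", genome.seq), ("-", reverse_complement(genome.seq))):
        n = len(seq)
        for s, e, fmm, rmm in _scan_plus_strand(
            seq, fwd_primer, rev_primer, max_mismatch, min_len, max_len
        ):
            product = seq[s:e]
            if strand == "+":
                start, end = s, e
            else:  # map back to + strand coordinates
                start, end = n - e, n - s
            amplicons.append(
                Amplicon(
                    genome_id=genome.id,
                    seq=product,
                    insert=product[lf : len(product) - lr],
                    fwd_primer_site=product[:lf],
                    rev_primer_site=reverse_complement(product[len(product) - lr :]),
                    start=start,
                    end=end,
                    strand=strand,
                    fwd_mismatches=fmm,
                    rev_mismatches=rmm,
                )
            )
    amplicons.sort(key=lambda a: (a.start, a.end, a.strand))
    return AmpliconSet(genome_id=genome.id, amplicons=amplicons)


def amplitype(amplicon_set: AmpliconSet) -> str:
    """Canonical multiplicity signature, e.g. ``"3+2+1"`` (empty set -> "")."""
    mults = sorted(amplicon_set.multiplicity.values(), reverse=True)
    return "+".join(str(m) for m in mults)
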