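"""Dual-barcoded sequencing template construction.

Each template is the concrete DNA molecule loaded into a sequencing well:

    A + FwdBarcode + FwdPrimer + insert
      + revcomp(RevPrimer) + revcomp(RevBarcode) + A

The single flanking ``A`` bases are literal.  Degenerate primer positions
must already be resolved to concrete bases before template construction:
by default the pipeline uses "oligo mode", a random concrete
disambiguation of the degenerate primer per molecule batch (the amplicon
physically carries the primer oligo at its 5' ends); a flag switches to
the genomic realization found at the binding site.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from hifisim.abundance import CountTable
from hifisim.amplicons import AmpliconSet
from hifisim.fixtures import realize_primer
from hifisim.io_formats import BarcodePair, is_concrete_dna, reverse_complement

logger = logging.getLogger(__name__)

_SEGMENTS = (
    "lead_A",
    "fwd_barcode",
    "fwd_primer",
    "insert",
    "rc_rev_primer",
    "rc_rev_barcode",
    "trail_A",
)


@dataclasses.dataclass(frozen=True)
class Template:
    """One barcoded molecule with the coordinates of each segment."""

    template_id: str
    sample_id: str
    genome_id: str
    asv_id: str
    seq: str
    spans: dict[str, tuple[int, int]]  # segment -> (start, end), tiling seq

    def segment(self, name: str) -> str:
        s, e = self.spans[name]
        return self.seq[s:e]


def build_template(
    insert: str,
    barcodes: BarcodePair,
    fwd_primer: str,
    rev_primer: str,
    asv_id: str = "asv",
    genome_id: str = "",
    template_id: str | None = None,
) -> Template:
    """Assemble one template from concrete components.

    All components must be non-empty concrete DNA (no IUPAC degeneracies
    left): a template is a physical molecule.
    """
    parts = {
        "insert": insert,
        "fwd_primer": fwd_primer,
        "rev_primer": rev_primer,
        "fwd_barcode": barcodes.fwd_barcode,
        "rev_barcode": barcodes.rev_barcode,
    }
    for name, seq in parts.items():
        if not seq:
            raise ValueError(f"{name} must be non-empty")
        if not is_concrete_dna(seq):
            raise ValueError(
                f"{name} contains degenerate bases ({seq!r}); "
                "templates must be concrete DNA"
            )
    segments = [
        ("lead_A", "A"),
        ("fwd_barcode", barcodes.fwd_barcode),
        ("fwd_primer", fwd_primer),
        ("insert", insert),
        ("rc_rev_primer", reverse_complement(rev_primer)),
        ("rc_rev_barcode", reverse_complement(barcodes.rev_barcode)),
        ("trail_A", "A"),
    ]
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    chunks = []
    for name, seg in segments:
        spans[name] = (pos, pos + len(seg))
        chunks.append(seg)
        pos += len(seg)
    return Template(
        template_id=template_id or f"{barcodes.sample_id}:{asv_id}",
        sample_id=barcodes.sample_id,
        genome_id=genome_id,
        asv_id=asv_id,
        seq="".join(chunks),
        spans=spans,
    )


def assign_templates(
    count_table: CountTable,
    amplicon_sets: list[AmpliconSet],
    barcode_table: list[BarcodePair],
    fwd_primer: str,
    rev_primer: str,
    primer_mode: str = "oligo",
    rng: np.random.Generator | None = None,
) -> list[tuple[Template, int]]:
    """One (Template, copies) per sample x ASV with count > 0.

    Per-sample total multiplicity equals that sample's realized depth.
    ``primer_mode='oligo'`` (default) resolves degenerate primer positions
    to a random concrete base per template; ``'genomic'`` uses the
    sequence found at the ASV's source binding site.
    """
    if primer_mode not in {"oligo", "genomic"}:
        raise ValueError(f"unknown primer_mode {primer_mode!r}")
    barcodes = {bp.sample_id: bp for bp in barcode_table}
    missing = [s for s in count_table.sample_ids if s not in barcodes]
    if missing:
        raise ValueError(f"no barcode pair for sample(s): {missing}")
    if primer_mode == "oligo" and rng is None:
        rng = np.random.default_rng(0)

    insert_of: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    site_primers: dict[str, tuple[str, str]] = {}
    for aset in amplicon_sets:
        for i, amp in enumerate(aset.amplicons):
            asv_id = aset.asv_of[i]
            insert_of.setdefault(asv_id, amp.insert)
            genome_of.setdefault(asv_id, aset.genome_id)
            site_primers.setdefault(asv_id, (amp.fwd_primer_site, amp.rev_primer_site))

    out: list[tuple[Template, int]] = []
    for j, sample in enumerate(count_table.sample_ids):
        col = count_table.counts[:, j]
        if col.sum() == 0:
            logger.warning("sample %s has all-zero counts; no templates", sample)
            continue
        for i, asv_id in enumerate(count_table.asv_ids):
            c = int(col[i])
            if c == 0:
                continue
            if primer_mode == "oligo":
                p_fwd = realize_primer(fwd_primer, rng)
                p_rev = realize_primer(rev_primer, rng)
            else:
                p_fwd, p_rev = site_primers[asv_id]
            tpl = build_template(
                insert=insert_of[asv_id],
                barcodes=barcodes[sample],
                fwd_primer=p_fwd,
                rev_primer=p_rev,
                asv_id=asv_id,
                genome_id=genome_of[asv_id],
                template_id=f"{sample}:{asv_id}",
            )
            out.append((tpl, c))
    return out
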