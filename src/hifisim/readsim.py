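"""Subread simulation and CCS-style consensus calling.

Each molecule (ZMW) is read in ``np`` passes of alternating strand.  A
pass walks the template base by base: with probability ``accuracy`` the
base is emitted unchanged; otherwise an error type is chosen by the
sub:ins:del ratio — substitution emits a uniformly random different base,
insertion emits a uniformly random base and re-processes the same
template base (so insertion runs are geometric), deletion skips the base.
Every walk step emits exactly one alignment column, so the expected
fraction of match columns equals ``accuracy`` and the error-column
composition equals the normalized ratio; both realized statistics are
recorded on each subread.

Consensus is backbone-based plurality voting: subreads are oriented to
the forward strand, the medoid subread (minimum total edit distance to
the others) becomes the backbone, every subread is globally aligned to
it, and each backbone column — plus insertion columns observed in at
least half of the subreads — takes the plurality symbol.  Per-base
quality is the Phred-scaled column agreement, capped at 93.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Sequence

import edlib
import numpy as np

from hifisim.passnum import PassNumberDistribution, sample_np
from hifisim.templates import Template

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_GAP = 4
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

QUAL_CAP = 93
QUAL_EPS = 1e-10


@dataclasses.dataclass
class ErrorModel:
    """Per-pass error parameters.

    ``accuracy`` is the probability a walk step emits a correct base
    (default 0.65); ``ratio`` weights substitution:insertion:deletion
    given an error (default 6:55:39).  ``homopolymer_indel_multiplier``
    (>1) scales the ins+del mass inside homopolymer runs of length >= 3,
    renormalizing per position; default 1 (off).
    """

    accuracy: float = 0.65
    ratio: tuple[float, float, float] = (6.0, 55.0, 39.0)
    homopolymer_indel_multiplier: float = 1.0
    single_coverage_q: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.accuracy <= 1.0:
            raise ValueError("accuracy must be in (0, 1]")
        w = np.asarray(self.ratio, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("ratio weights must be non-negative with positive sum")
        if self.homopolymer_indel_multiplier < 1.0:
            raise ValueError("homopolymer_indel_multiplier must be >= 1")
        self.ratio = tuple(w / w.sum())

    @property
    def error_probs(self) -> tuple[float, float, float]:
        """(p_sub, p_ins, p_del) per walk step."""
        p_err = 1.0 - self.accuracy
        return tuple(p_err * w for w in self.ratio)


@dataclasses.dataclass
class Subread:
    """One pass over the template, in read orientation."""

    zmw_id: int
    pass_index: int  # 1-based; odd passes are '+', even are '-'
    strand: str
    seq: str
    n_match: int = 0
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0

    @property
    def n_columns(self) -> int:
        return self.n_match + self.n_sub + self.n_ins + self.n_del

    @property
    def aligned_identity(self) -> float:
        """Match columns over all alignment columns of the edit script."""
        return self.n_match / self.n_columns if self.n_columns else 1.0


@dataclasses.dataclass
class SimulatedRead:
    """A CCS consensus read with per-base quality and full provenance."""

    read_id: str
    sample_id: str
    genome_id: str
    asv_id: str
    np: int
    seq: str
    qual: Sequence[int]
    template_id: str = ""
    template_len: int = 0

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("seq and qual lengths differ")
        if self.np < 1:
            raise ValueError("np must be >= 1")


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence must be concrete DNA (A/C/G/T)")
    return codes


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _rc_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def _homopolymer_mask(codes: np.ndarray, min_run: int = 3) -> np.ndarray:
    """True at positions inside a run of >= min_run identical bases."""
    n = codes.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    change = np.flatnonzero(np.diff(codes) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))
    mask = np.zeros(n, dtype=bool)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            mask[s:e] = True
    return mask


def mutate_pass(
    template_seq: str,
    model: ErrorModel,
    strand: str = "+",
    seed: int | np.random.Generator = 0,
    zmw_id: int = 0,
    pass_index: int = 1,
) -> Subread:
    """Simulate one pass over the template.

    For strand '-', the walk operates on the reverse complement of the
    template so errors accrue in read orientation.
    """
    if strand not in "+-":
        raise ValueError(f"invalid strand {strand!r}")
    if not template_seq:
        raise ValueError("template must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tpl = _encode(template_seq)
    if strand == "-":
        tpl = _rc_codes(tpl)
    n = tpl.size

    p_sub, p_ins, p_del = model.error_probs
    acc = model.accuracy
    if model.homopolymer_indel_multiplier > 1.0:
        m = model.homopolymer_indel_multiplier
        hp = _homopolymer_mask(tpl)
        z = np.where(hp, acc + p_sub + m * (p_ins + p_del), 1.0)
        p_ins_pos = np.where(hp, m * p_ins, p_ins) / z
        p_sub_pos = np.full(n, p_sub) / z
        p_del_pos = np.where(hp, m * p_del, p_del) / z
        acc_pos = np.full(n, acc) / z
    else:
        p_ins_pos = np.full(n, p_ins)
        p_sub_pos = np.full(n, p_sub)
        p_del_pos = np.full(n, p_del)
        acc_pos = np.full(n, acc)

    # insertions before consuming each base: geometric in p_ins
    if p_ins == 0 and model.homopolymer_indel_multiplier == 1.0:
        n_ins = np.zeros(n, dtype=np.int64)
    else:
        n_ins = rng.geometric(1.0 - p_ins_pos) - 1
    # consumed outcome among {match, sub, del}, renormalized
    denom = 1.0 - p_ins_pos
    u = rng.random(n) * denom
    outcome = np.where(u < acc_pos, 0, np.where(u < acc_pos + p_sub_pos, 1, 2))

    keep = outcome != 2
    emit = n_ins + keep
    total = int(emit.sum())
    seq = rng.integers(0, 4, total, dtype=np.uint8)  # fills insertion slots
    ends = np.cumsum(emit)
    slots = ends[keep] - 1
    bases = tpl[keep].copy()
    sub_here = outcome[keep] == 1
    n_sub_total = int(sub_here.sum())
    if n_sub_total:
        shift = rng.integers(1, 4, n_sub_total, dtype=np.uint8)
        bases[sub_here] = (bases[sub_here] + shift) % 4
    seq[slots] = bases

    return Subread(
        zmw_id=zmw_id,
        pass_index=pass_index,
        strand=strand,
        seq=_decode(seq),
        n_match=int((outcome == 0).sum()),
        n_sub=n_sub_total,
        n_ins=int(n_ins.sum()),
        n_del=int((outcome == 2).sum()),
    )


def simulate_zmw(
    template_seq: str,
    np_passes: int,
    model: ErrorModel,
    seed: int | np.random.Generator = 0,
    zmw_id: int = 0,
) -> list[Subread]:
    """np independent passes with alternating strand (+, -, +, ...)."""
    if np_passes < 1:
        raise ValueError("np must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for k in range(1, np_passes + 1):
        strand = "+" if k % 2 == 1 else "-"
        out.append(
            mutate_pass(template_seq, model, strand, rng, zmw_id=zmw_id, pass_index=k)
        )
    return out


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _medoid_index(seqs: list[str]) -> int:
    """Index minimizing total edit distance to the others (ties: first)."""
    n = len(seqs)
    if n <= 2:
        return 0
    totals = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = _edit_distance(seqs[i], seqs[j])
            totals[i] += d
            totals[j] += d
    return int(np.argmin(totals))


def _phred(k: int, n: int) -> int:
    err = max(QUAL_EPS, 1.0 - k / n)
    return min(QUAL_CAP, round(-10.0 * np.log10(err)))


INSERTION_VOTE_FRACTION = 0.4  # min fraction of subreads backing an insertion column


def _vote_against(
    oriented: list[str], backbone: str, frac: float = INSERTION_VOTE_FRACTION
) -> tuple[str, np.ndarray]:
    """One round of column voting against a backbone.

    Every subread is globally aligned to the backbone; backbone columns
    take the plurality of {A,C,G,T,gap} (gap-winning columns are
    dropped), and insertion columns supported by at least ``frac`` of
    the subreads are emitted with the plurality inserted base.  Returns
    (sequence, per-column agreement quality).
    """
    n = len(oriented)
    L = len(backbone)
    base_mat = np.full((n, L), _GAP, dtype=np.uint8)
    insertions: dict[int, list[np.ndarray]] = {}

    for k, seq in enumerate(oriented):
        cigar = edlib.align(seq, backbone, mode="NW", task="path")["cigar"]
        codes = _encode(seq)
        qpos = tpos = 0
        for m in _CIGAR_RE.finditer(cigar):
            ln, op = int(m.group(1)), m.group(2)
            if op in "=XM":
                base_mat[k, tpos : tpos + ln] = codes[qpos : qpos + ln]
                qpos += ln
                tpos += ln
            elif op == "I":  # extra bases in the subread
                insertions.setdefault(tpos, []).append(codes[qpos : qpos + ln])
                qpos += ln
            else:  # 'D': backbone base absent from the subread
                tpos += ln

    votes = np.zeros((5, L), dtype=np.int32)
    for s in range(5):
        votes[s] = (base_mat == s).sum(axis=0)
    winners = votes.argmax(axis=0)  # ties: lowest code, bases before gap
    win_votes = votes[winners, np.arange(L)]

    out_codes: list[int] = []
    out_quals: list[int] = []

    def emit_insertions(site: int) -> None:
        ins_lists = insertions.get(site)
        if not ins_lists:
            return
        t = 0
        while True:
            col = [a[t] for a in ins_lists if a.size > t]
            if not col or len(col) < frac * n:
                break
            counts = np.bincount(np.array(col, dtype=np.int64), minlength=4)
            b = int(counts.argmax())
            out_codes.append(b)
            out_quals.append(_phred(int(counts[b]), n))
            t += 1

    for j in range(L):
        emit_insertions(j)
        w = int(winners[j])
        if w != _GAP:
            out_codes.append(w)
            out_quals.append(_phred(int(win_votes[j]), n))
    emit_insertions(L)
    seq = _decode(np.asarray(out_codes, dtype=np.uint8))
    return seq, np.asarray(out_quals, dtype=np.int64)


def _draft_backbone(oriented: list[str]) -> str:
    """Two voting rounds starting from the medoid subread."""
    bb = oriented[_medoid_index(oriented)]
    if len(oriented) == 1:
        return bb
    for _ in range(2):
        bb, _ = _vote_against(oriented, bb)
    return bb


def consensus(
    subreads: list[Subread],
    template_length_hint: int = 0,
    single_coverage_q: int = 20,
) -> tuple[str, np.ndarray]:
    """Hierarchical plurality-vote consensus of one ZMW's subreads.

    For deep ZMWs the subreads are first split round-robin into groups
    of ~3 whose group drafts vote among themselves; the resulting
    backbone is then refined and finally voted on by *all* subreads.
    The hierarchy weakens the correlation between backbone errors and
    the voters that produced them, which a single medoid backbone
    suffers from at low per-pass accuracy.  Returns (sequence, per-base
    integer quality); a single subread is returned as-is (oriented '+')
    at the fixed single-coverage quality.
    """
    if not subreads:
        raise ValueError("need at least one subread")
    from hifisim.io_formats import reverse_complement

    oriented = [
        sr.seq if sr.strand == "+" else reverse_complement(sr.seq) for sr in subreads
    ]
    n = len(oriented)
    if n <= 2:
        # no plurality exists below 3 passes; emit the first pass as-is
        quals = np.full(len(oriented[0]), single_coverage_q, dtype=np.int64)
        return oriented[0], quals

    if n < 6:
        bb = _draft_backbone(oriented)
    else:
        n_groups = max(1, n // 3)
        drafts = [_draft_backbone(oriented[g::n_groups]) for g in range(n_groups)]
        bb = drafts[_medoid_index(drafts)]
        if len(drafts) > 1:
            bb, _ = _vote_against(drafts, bb)
        bb, _ = _vote_against(oriented, bb)
    return _vote_against(oriented, bb)


def _simulate_one_zmw(args: tuple) -> SimulatedRead:
    """Worker: simulate one molecule end to end (picklable for pools)."""
    template_seq, tpl_meta, np_passes, model, child_seed, zmw_id, movie = args
    rng = np.random.default_rng(child_seed)
    subreads = simulate_zmw(template_seq, np_passes, model, rng, zmw_id=zmw_id)
    seq, qual = consensus(subreads, len(template_seq), model.single_coverage_q)
    sample_id, genome_id, asv_id, template_id = tpl_meta
    return SimulatedRead(
        read_id=f"{movie}/{zmw_id}/ccs",
        sample_id=sample_id,
        genome_id=genome_id,
        asv_id=asv_id,
        np=int(np_passes),
        seq=seq,
        qual=qual,
        template_id=template_id,
        template_len=len(template_seq),
    )


def simulate_dataset(
    templates_with_copies: list[tuple[Template, int]],
    np_dist: PassNumberDistribution,
    model: ErrorModel,
    seed: int = 0,
    workers: int = 1,
) -> list[SimulatedRead]:
    """One ZMW per template copy; np sampled per ZMW; full provenance.

    Results are independent of ``workers``: pass numbers are drawn up
    front from the run seed and each ZMW gets its own derived seed.
    """
    if not templates_with_copies:
        raise ValueError("no templates to simulate")
    movie = f"m{seed % 100000:05d}_000000_000000"
    molecules: list[Template] = []
    for tpl, copies in templates_with_copies:
        molecules.extend([tpl] * copies)
    n_zmw = len(molecules)
    np_rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 31)))
    np_values = sample_np(np_dist, n_zmw, np_rng)

    jobs = []
    for zmw_id, (tpl, np_val) in enumerate(zip(molecules, np_values), start=1):
        child_seed = np.random.SeedSequence(entropy=(seed, 37, zmw_id))
        meta = (tpl.sample_id, tpl.genome_id, tpl.asv_id, tpl.template_id)
        jobs.append((tpl.seq, meta, int(np_val), model, child_seed, zmw_id, movie))

    if workers <= 1:
        return [_simulate_one_zmw(j) for j in jobs]
    import multiprocessing

    with multiprocessing.Pool(workers) as pool:
        reads = pool.map(_simulate_one_zmw, jobs, chunksize=64)
    return reads
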