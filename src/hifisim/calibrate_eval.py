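"""Evaluation metrics and subread-accuracy calibration.

Metrics mirror how simulated amplicon datasets are judged against real
ones: (i) the distribution of minimum global edit distances from each
read to its nearest reference ASV, (ii) Pearson correlation between
expected and observed ASV abundances, and (iii) positional profiles of
substitution/insertion/deletion events along the amplicon.  The
calibration loop chooses the subread accuracy whose simulated
edit-distance histogram minimizes KL divergence to a target histogram.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import edlib
import numpy as np
from scipy import stats

from hifisim.readsim import SimulatedRead

KL_SMOOTH_EPS = 1e-9


@dataclasses.dataclass
class EditDistanceProfile:
    """Per-read nearest-reference distances plus their histogram."""

    read_ids: list[str]
    distances: np.ndarray
    nearest_asv: list[str]
    histogram: np.ndarray  # unit bins [0, d_max] plus one overflow bin
    d_max: int
    min_len: int | None = None
    max_len: int | None = None
    n_filtered: int = 0


@dataclasses.dataclass
class PositionalErrorProfile:
    """Event proportions per template position.

    ``proportions[:, j]`` holds (match, sub, ins, del) fractions of all
    events observed at template column j; each column sums to 1.
    Insertions are counted at the template position they precede.
    """

    counts: np.ndarray  # 4 x L
    proportions: np.ndarray

    EVENTS = ("match", "substitution", "insertion", "deletion")


def global_edit_distance(a: str, b: str) -> int:
    """End-to-end unit-cost Levenshtein distance."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def nearest_reference(
    read_seq: str, references: dict[str, str]
) -> tuple[int, str]:
    """Minimum global edit distance over references; ties break to the
    lexicographically smallest ASV id."""
    if not references:
        raise ValueError("reference set is empty")
    best_d, best_id = None, None
    for asv_id in sorted(references):
        d = global_edit_distance(read_seq, references[asv_id])
        if best_d is None or d < best_d:
            best_d, best_id = d, asv_id
    return best_d, best_id


def edit_distance_profile(
    reads: Sequence[SimulatedRead],
    references: dict[str, str],
    d_max: int = 100,
    min_len: int | None = None,
    max_len: int | None = None,
) -> EditDistanceProfile:
    """Nearest-reference profile with optional read-length filtering.

    Reads outside [min_len, max_len] are excluded before any metric is
    computed, mirroring the length windows used when benchmarking
    amplicon datasets.
    """
    kept = []
    n_filtered = 0
    for r in reads:
        L = len(r.seq)
        if (min_len is not None and L < min_len) or (
            max_len is not None and L > max_len
        ):
            n_filtered += 1
            continue
        kept.append(r)
    distances = np.zeros(len(kept), dtype=np.int64)
    nearest = []
    for i, r in enumerate(kept):
        d, asv = nearest_reference(r.seq, references)
        distances[i] = d
        nearest.append(asv)
    hist = np.bincount(np.minimum(distances, d_max + 1), minlength=d_max + 2)
    return EditDistanceProfile(
        read_ids=[r.read_id for r in kept],
        distances=distances,
        nearest_asv=nearest,
        histogram=hist,
        d_max=d_max,
        min_len=min_len,
        max_len=max_len,
        n_filtered=n_filtered,
    )


def misassignment_rate(
    reads: Sequence[SimulatedRead], references: dict[str, str]
) -> float:
    """Fraction of reads whose nearest reference is not their true ASV.

    When several references tie at the minimum distance, the read counts
    as correctly assigned if its true ASV is among the tied set.
    """
    if not reads:
        raise ValueError("no reads")
    n_wrong = 0
    for r in reads:
        best_d, _ = nearest_reference(r.seq, references)
        true_d = global_edit_distance(r.seq, references[r.asv_id])
        if true_d > best_d:
            n_wrong += 1
    return n_wrong / len(reads)


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in nats over a shared binning.

    ``q`` must already be smoothed: a zero q-bin where p > 0 is an error
    (forces an explicit smoothing choice upstream).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"histogram shapes differ: {p.shape} vs {q.shape}")
    p = p / p.sum()
    q = q / q.sum()
    mask = p > 0
    if (q[mask] == 0).any():
        raise ValueError("q has zero mass where p > 0; smooth q first")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def smooth_histogram(hist: np.ndarray, eps: float = KL_SMOOTH_EPS) -> np.ndarray:
    """Add-mass smoothing then renormalization (never returns zeros)."""
    h = np.asarray(hist, dtype=float)
    h = h / h.sum() + eps
    return h / h.sum()


def calibrate_accuracy(
    target_hist: np.ndarray,
    sim_factory: Callable[[float], np.ndarray],
    accuracy_grid: Sequence[float],
    seed: int = 0,
) -> tuple[float, dict[float, float]]:
    """Grid-search the subread accuracy minimizing KL(target || simulated).

    ``sim_factory(accuracy)`` must return an edit-distance histogram on
    the same binning as ``target_hist`` (it receives the accuracy only;
    any seeding is the factory's business).  Ties break to the lower
    accuracy.  Returns (best_accuracy, {accuracy: KL}).
    """
    grid = sorted(accuracy_grid)
    if not grid:
        raise ValueError("accuracy grid is empty")
    if any(not 0 < a <= 1 for a in grid):
        raise ValueError("grid accuracies must be in (0, 1]")
    scores: dict[float, float] = {}
    for acc in grid:
        sim_hist = np.asarray(sim_factory(acc), dtype=float)
        scores[acc] = kl_divergence(target_hist, smooth_histogram(sim_hist))
    best = min(grid, key=lambda a: (scores[a], a))
    return best, scores


def abundance_r2(expected: np.ndarray, observed: np.ndarray, log10: bool = False) -> float:
    """Squared Pearson correlation between expected and observed abundances."""
    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if log10:
        x = np.log10(x)
        y = np.log10(y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in expected or observed vector")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def positional_error_profile(
    reads: Sequence[SimulatedRead],
    true_templates: dict[str, str],
) -> PositionalErrorProfile:
    """Per-template-position event proportions pooled over reads.

    Each read is globally aligned to its true source template
    (``true_templates[read.template_id]``); alignment columns are
    classified as match/substitution/insertion/deletion and pooled by
    template coordinate.  Columns are padded to the longest template.
    """
    if not reads:
        raise ValueError("no reads")
    L = max(len(t) for t in true_templates.values())
    counts = np.zeros((4, L + 1), dtype=np.int64)  # +1: trailing insertions
    import re

    cigar_re = re.compile(r"(\d+)([=XIDM])")
    for r in reads:
        tpl = true_templates[r.template_id]
        res = edlib.align(r.seq, tpl, mode="NW", task="path")
        tpos = 0
        for m in cigar_re.finditer(res["cigar"]):
            ln, op = int(m.group(1)), m.group(2)
            if op == "=":
                counts[0, tpos : tpos + ln] += 1
                tpos += ln
            elif op in "XM":
                counts[1, tpos : tpos + ln] += 1
                tpos += ln
            elif op == "I":
                counts[2, tpos] += ln
            else:  # 'D'
                counts[3, tpos : tpos + ln] += 1
                tpos += ln
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    return PositionalErrorProfile(counts=counts, proportions=props)


def aligned_identity(read_seq: str, template_seq: str) -> float:
    """Match columns over all alignment columns of an optimal global
    alignment (edlib)."""
    res = edlib.align(read_seq, template_seq, mode="NW", task="path")
    import re

    n_match = n_cols = 0
    for m in re.finditer(r"(\d+)([=XIDM])", res["cigar"]):
        ln = int(m.group(1))
        n_cols += ln
        if m.group(2) == "=":
            n_match += ln
    return n_match / n_cols if n_cols else 1.0
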