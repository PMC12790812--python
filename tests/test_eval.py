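import numpy as np
import pytest

from hifisim.calibrate_eval import (
    abundance_r2,
    aligned_identity,
    calibrate_accuracy,
    edit_distance_profile,
    kl_divergence,
    misassignment_rate,
    nearest_reference,
    positional_error_profile,
    smooth_histogram,
)
from hifisim.readsim import SimulatedRead


def brute_force_levenshtein(a: str, b: str) -> int:
    """Independent quadratic DP oracle for unit-cost global edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def _read(seq, rid="r1", asv="a1", tid="t1"):
    return SimulatedRead(
        read_id=rid, sample_id="S1", genome_id="g1", asv_id=asv,
        np=5, seq=seq, qual=[30] * len(seq), template_id=tid,
        template_len=len(seq),
    )


def _random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestNearestReference:
    def test_exact_match(self):
        refs = {"a1": "ACGTACGT", "a2": "TTTTTTTT"}
        assert nearest_reference("ACGTACGT", refs) == (0, "a1")

    def test_single_deletion(self):
        refs = {"a1": "ACGTACGT", "a2": "TTTTTTTT"}
        assert nearest_reference("ACGACGT", refs) == (1, "a1")

    def test_tie_breaks_lexicographically(self):
        refs = {"b": "AAAA", "a": "AAAA"}
        assert nearest_reference("AAAT", refs) == (1, "a")

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            nearest_reference("ACGT", {})

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        refs = {f"a{k}": _random_dna(rng, 180 + 10 * k) for k in range(5)}
        for _ in range(100):
            read = _random_dna(rng, int(rng.integers(150, 230)))
            d, asv = nearest_reference(read, refs)
            oracle = {k: brute_force_levenshtein(read, v) for k, v in refs.items()}
            assert d == min(oracle.values())
            assert oracle[asv] == d


class TestMisassignment:
    def test_error_free_reads(self):
        refs = {"a1": "ACGTACGTAC", "a2": "GGGGGCCCCC"}
        reads = [_read("ACGTACGTAC", asv="a1"), _read("GGGGGCCCCC", rid="r2", asv="a2")]
        assert misassignment_rate(reads, refs) == 0.0

    def test_tie_including_truth_counts_correct(self):
        refs = {"a1": "AAAA", "a2": "AAAA"}
        reads = [_read("AAAT", asv="a2")]
        assert misassignment_rate(reads, refs) == 0.0

    def test_wrong_assignment_detected(self):
        refs = {"a1": "AAAAAAAA", "a2": "TTTTTTTT"}
        reads = [_read("TTTTTTTA", asv="a1")]
        assert misassignment_rate(reads, refs) == 1.0


class TestKlDivergence:
    def test_identical_histograms(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == 0.0

    def test_closed_form_two_bins(self):
        # 0.5 ln 2 + 0.5 ln(2/3) = 0.1438 nats
        val = kl_divergence(np.array([0.5, 0.5]), np.array([0.25, 0.75]))
        assert val == pytest.approx(0.5 * np.log(2) + 0.5 * np.log(2 / 3))
        assert val == pytest.approx(0.1438, abs=1e-4)

    def test_unsmoothed_zero_rejected(self):
        with pytest.raises(ValueError, match="smooth"):
            kl_divergence(np.array([0.5, 0.5]), np.array([1.0, 0.0]))

    def test_bin_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.ones(3) / 3, np.ones(4) / 4)

    def test_non_negative_random_histograms(self):
        rng = np.random.default_rng(33)
        for _ in range(50):
            p = smooth_histogram(rng.random(8))
            q = smooth_histogram(rng.random(8))
            assert kl_divergence(p, q) >= 0.0


class TestCalibrateAccuracy:
    def test_single_point_grid(self):
        target = np.array([1.0, 2.0, 3.0])
        best, scores = calibrate_accuracy(target, lambda a: target, [0.65])
        assert best == 0.65

    def test_degenerate_target_prefers_max_accuracy(self):
        # all-zero-distance target: the least-error simulation wins
        target = np.zeros(11)
        target[0] = 1.0

        def factory(acc):
            h = np.zeros(11)
            h[0] = acc  # more mass at distance 0 for higher accuracy
            h[5] = 1 - acc
            return h

        best, _ = calibrate_accuracy(target, factory, [0.55, 0.65, 0.75])
        assert best == 0.75

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            calibrate_accuracy(np.ones(3), lambda a: np.ones(3), [])


class TestAbundanceR2:
    def test_perfect_and_affine(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert abundance_r2(x, x) == pytest.approx(1.0)
        assert abundance_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        # r^2 of (1,2,3) vs (1,2,4) = 27/28
        assert abundance_r2(np.array([1, 2, 3]), np.array([1, 2, 4])) == pytest.approx(
            27 / 28
        )
        assert abundance_r2(np.array([1, 2, 3]), np.array([1, 2, 4])) == pytest.approx(
            0.9643, abs=1e-4
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            abundance_r2(np.array([1, 1, 1]), np.array([1, 2, 3]))


class TestEditDistanceProfile:
    def test_length_filter_applied_before_metrics(self):
        refs = {"a1": "ACGTACGTAC"}
        reads = [
            _read("ACGTACGTAC", rid="keep"),
            _read("ACGT", rid="short"),
            _read("ACGTACGTACGTACGTACGT", rid="long"),
        ]
        prof = edit_distance_profile(reads, refs, min_len=8, max_len=12)
        assert prof.read_ids == ["keep"]
        assert prof.n_filtered == 2

    def test_histogram_overflow_bin(self):
        refs = {"a1": "A" * 50}
        reads = [_read("T" * 50)]
        prof = edit_distance_profile(reads, refs, d_max=10)
        assert prof.histogram[-1] == 1  # distance 50 lands in overflow


class TestPositionalErrorProfile:
    def test_error_free_reads_all_match(self):
        tpl = "ACGTACGTACGT"
        reads = [_read(tpl, tid="t1")]
        prof = positional_error_profile(reads, {"t1": tpl})
        assert (prof.proportions[0, : len(tpl)] == 1.0).all()

    def test_single_deletion_localized(self):
        tpl = "ACGTACGTACGTACGTACGTA"  # length 21
        read_seq = tpl[:10] + tpl[11:]  # delete position 10
        prof = positional_error_profile([_read(read_seq, tid="t1")], {"t1": tpl})
        del_cols = np.flatnonzero(prof.counts[3, :])
        assert len(del_cols) == 1
        assert prof.proportions[3, del_cols[0]] == 1.0

    def test_uniform_error_model_has_flat_profile(self):
        # the mutation walk has no positional dependence: regressing the
        # per-column error proportion on position gives slope ~ 0
        from hifisim.readsim import ErrorModel, mutate_pass

        rng = np.random.default_rng(35)
        tpl = _random_dna(rng, 300)
        reads = []
        for i in range(200):
            sr = mutate_pass(tpl, ErrorModel(accuracy=0.9), seed=1000 + i)
            reads.append(_read(sr.seq, rid=f"r{i}", tid="t1"))
        prof = positional_error_profile(reads, {"t1": tpl})
        err = 1.0 - prof.proportions[0, :300]
        pos = np.arange(300)
        slope = np.polyfit(pos, err, 1)[0]
        # slope in error-fraction per bp; flat within noise
        assert abs(slope) < 5e-5


class TestAlignedIdentity:
    def test_identical(self):
        assert aligned_identity("ACGT", "ACGT") == 1.0

    def test_single_mismatch(self):
        assert aligned_identity("ACGA", "ACGT") == pytest.approx(0.75)
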