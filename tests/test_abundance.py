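import numpy as np
import pytest
from scipy import stats

from hifisim import abundance as ab
from hifisim.amplicons import extract_amplicons


class TestGenomeMolarity:
    def test_uniform_even_community(self):
        # an 8-genome evenly mixed mock community
        v = ab.sample_genome_molarity("uniform", None, 8)
        assert np.allclose(v, 0.125)

    def test_empirical_normalization(self):
        v = ab.sample_genome_molarity("empirical", {"profile": [2, 1, 1]}, 3)
        assert np.allclose(v, [0.5, 0.25, 0.25])

    def test_powerlaw_harmonic(self):
        # rank^-1 / H_3
        v = ab.sample_genome_molarity("powerlaw", {"alpha": 1.0}, 3)
        h3 = 1 + 0.5 + 1 / 3
        assert np.allclose(v, [1 / h3, 0.5 / h3, (1 / 3) / h3])
        assert np.allclose(v, [0.5455, 0.2727, 0.1818], atol=1e-4)

    def test_lognormal_sums_to_one(self):
        v = ab.sample_genome_molarity("lognormal", {"mu": 0, "sigma": 1}, 50, seed=1)
        assert v.min() > 0 and np.isclose(v.sum(), 1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            ab.sample_genome_molarity("zipf", None, 3)
        with pytest.raises(ValueError):
            ab.sample_genome_molarity("empirical", {"profile": [1, 2]}, 3)


class TestVariabilityModel:
    def test_negative_prediction_maps_to_zero(self):
        # NA emulation: a mean curve forced negative yields exactly 0,
        # i.e. no biological variability between replicates
        model = ab.VariabilityModel(dispersion_slope=0.0, dispersion_intercept=-5.0)
        assert ab.predict_variability(0.01, model, seed=0) == 0.0

    def test_infinite_size_is_variance_free(self):
        model = ab.VariabilityModel(nb_size=np.inf)
        x = 0.001
        assert ab.predict_variability(x, model, seed=1) == pytest.approx(
            float(model.mean_cv2(x))
        )

    def test_monte_carlo_mean_matches_curve(self):
        model = ab.VariabilityModel()
        x = 0.001  # mean CV2 = -0.25 - 0.18*ln(0.001) ~ 0.993
        rng = np.random.default_rng(2)
        draws = model.sample_cv2(np.full(10_000, x), rng)
        m = float(model.mean_cv2(x))
        sd = m / np.sqrt(model.nb_size)  # gamma CV = 1/sqrt(shape)
        assert abs(draws.mean() - m) <= 4 * sd / np.sqrt(10_000)

    def test_non_positive_intensity_rejected(self):
        with pytest.raises(ValueError):
            ab.predict_variability(0.0, ab.VariabilityModel())

    def test_fit_recovers_log_linear_curve(self):
        x = np.logspace(-4, -1, 30)
        y = -0.3 - 0.15 * np.log(x)
        fitted = ab.VariabilityModel.fit(x, y)
        assert fitted.dispersion_slope == pytest.approx(-0.15, abs=1e-9)
        assert fitted.dispersion_intercept == pytest.approx(-0.3, abs=1e-9)


class TestSampleCounts:
    def test_counts_conserve_depth(self):
        rng = np.random.default_rng(3)
        intens = ab.sample_genome_molarity("lognormal", {}, 30, rng)
        var = np.full(30, 0.4)
        for depth in (7, 100, 5000):
            counts = ab.simulate_sample_counts(intens, var, depth, rng)
            assert counts.sum() == depth

    def test_zero_variability_large_depth_recovers_intensities(self):
        intens = np.array([0.5, 0.3, 0.2])
        counts = ab.simulate_sample_counts(intens, np.zeros(3), 200_000, seed=4)
        assert np.abs(counts / 200_000 - intens).max() < 0.01

    def test_binomial_pmf_chi_square(self):
        # two even features, zero variability, depth 10: counts of feature 1
        # must follow Binomial(10, 0.5); chi-square over 10^4 replicates
        rng = np.random.default_rng(5)
        n_rep, depth = 10_000, 10
        obs = np.zeros(depth + 1)
        intens = np.array([0.5, 0.5])
        zero = np.zeros(2)
        for _ in range(n_rep):
            c = ab.simulate_sample_counts(intens, zero, depth, rng)
            obs[c[0]] += 1
        expected = stats.binom.pmf(np.arange(depth + 1), depth, 0.5) * n_rep
        chi2 = ((obs - expected) ** 2 / expected).sum()
        # df = 10; reject only at alpha = 1e-3
        assert chi2 < stats.chi2.ppf(0.999, depth)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ab.simulate_sample_counts(np.ones(3) / 3, np.zeros(2), 10)


class TestExpandToAsv:
    def test_identical_copies_aggregate(self, small_community, primers):
        _, genomes, _ = small_community
        aset = extract_amplicons(genomes[0], *primers, max_mismatch=0, max_len=400)
        # force identical: use the zero-divergence genome3 (single copy)
        ids, w = ab.expand_to_asv({genomes[0].id: 1.0}, [aset])
        assert np.isclose(w.sum(), 1.0)
        assert len(ids) == len(aset.multiplicity)

    def test_copy_number_weighting(self):
        from hifisim.amplicons import Amplicon, AmpliconSet

        def mk(gid, seqs):
            amps = [
                Amplicon(
                    genome_id=gid, seq=s, insert=s[2:-2], fwd_primer_site=s[:2],
                    rev_primer_site=s[-2:], start=10 * i, end=10 * i + len(s),
                    strand="+", fwd_mismatches=0, rev_mismatches=0,
                )
                for i, s in enumerate(seqs)
            ]
            return AmpliconSet(genome_id=gid, amplicons=amps)

        # genome1: 4 distinct copies; genome2: 2 distinct copies; even molarity
        g1 = mk("g1", ["AACCGGTA", "AACCGGTC", "AACCGGTG", "AACCGGTT"])
        g2 = mk("g2", ["TTGGCCAA", "TTGGCCAC"])
        ids, w = ab.expand_to_asv({"g1": 0.5, "g2": 0.5}, [g1, g2])
        mass1 = w[[i for i, x in enumerate(ids) if x.startswith("g1")]].sum()
        mass2 = w[[i for i, x in enumerate(ids) if x.startswith("g2")]].sum()
        assert mass1 / mass2 == pytest.approx(2.0)

    def test_empty_genome_warns_and_contributes_nothing(self):
        from hifisim.amplicons import AmpliconSet

        empty = AmpliconSet(genome_id="g0", amplicons=[])
        with pytest.warns(UserWarning, match="g0"):
            ids, w = ab.expand_to_asv({"g0": 1.0}, [empty])
        assert ids == [] and w.size == 0


class TestAbundanceRecovery:
    def test_staggered_community_r2(self):
        # 20-genome staggered community at 13k reads/sample: expected vs
        # mean observed frequency correlates strongly despite biological noise
        from hifisim.calibrate_eval import abundance_r2

        rng = np.random.default_rng(3)
        mol = ab.sample_genome_molarity("powerlaw", {"alpha": 1.0}, 20, rng)
        model = ab.VariabilityModel()
        ct = ab.simulate_count_table(
            [f"a{i}" for i in range(20)], mol,
            [f"S{j}" for j in range(10)], 13_000, model, rng,
        )
        obs = ct.counts.mean(axis=1) / 13_000
        assert abundance_r2(mol, obs) > 0.95
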