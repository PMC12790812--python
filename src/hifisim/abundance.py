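"""Genome-level abundance simulation and copy-number-aware ASV expansion.

The model follows the intensity + variability contract of sparse-count
microbiome simulators: each feature has an expected relative abundance
(intensity) and a squared coefficient of variation (CV^2) describing
biological between-replicate variability.  Counts for a sample arise in
two stages:

1. biological: a per-feature intensity is drawn from a Gamma with mean
   equal to the expected intensity and CV^2 equal to the feature's
   variability (variability 0 => the intensity is used as-is, i.e. no
   biological variability);
2. technical: the configured sequencing depth is multinomially allocated
   over the renormalized stage-1 intensities.

Mean CV^2 is modeled as a log-linear function of intensity (the canonical
overdispersion shape: variability decreasing with abundance), with a
negative-binomial-style dispersion around that mean.  A predicted mean
CV^2 <= 0 is mapped to exactly 0 — replicates then receive identical
abundance values before the technical sampling step, emulating how NA
variability estimates are handled in intensity/variability simulators.
All three curve parameters are user-settable and a fitting helper
estimates them from any (intensity, CV^2) table.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from hifisim.amplicons import AmpliconSet

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AbundanceMatrix:
    """Expected relative abundance and CV^2 per feature x sample."""

    genome_ids: list[str]
    sample_ids: list[str]
    intensity: np.ndarray  # genome x sample, columns sum to 1
    variability: np.ndarray  # genome x sample, CV^2 >= 0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.variability = np.asarray(self.variability, dtype=float)
        shape = (len(self.genome_ids), len(self.sample_ids))
        if self.intensity.shape != shape or self.variability.shape != shape:
            raise ValueError("matrix dimensions inconsistent with id lists")
        if (self.intensity < 0).any() or (self.variability < 0).any():
            raise ValueError("intensity and variability must be non-negative")
        sums = self.intensity.sum(axis=0)
        if not np.allclose(sums, 1.0):
            self.intensity = self.intensity / sums


@dataclasses.dataclass
class CountTable:
    """Realized integer counts per feature x sample."""

    asv_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.asv_ids), len(self.sample_ids)):
            raise ValueError("count matrix dimensions inconsistent with id lists")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclasses.dataclass
class VariabilityModel:
    """Intensity -> CV^2 model with negative-binomial-style dispersion.

    mean CV^2(x) = dispersion_intercept + dispersion_slope * ln(x); draws
    around a positive mean come from a Gamma with shape ``nb_size`` (so
    the draw's own CV^2 is 1/nb_size, and nb_size -> inf degenerates to
    the mean curve).  A non-positive mean yields exactly 0.

    Defaults give moderate variability typical of microbiome data:
    CV^2 ~ 1.0 at 0.1% relative abundance, declining to ~0.17 at 10%.
    """

    dispersion_slope: float = -0.18
    dispersion_intercept: float = -0.25
    nb_size: float = 4.0
    floor_behavior: str = "zero"

    def __post_init__(self) -> None:
        if self.nb_size <= 0:
            raise ValueError("nb_size must be > 0")
        if self.floor_behavior != "zero":
            raise ValueError("only floor_behavior='zero' is supported")

    def mean_cv2(self, intensity: float | np.ndarray) -> np.ndarray:
        x = np.asarray(intensity, dtype=float)
        if (x <= 0).any():
            raise ValueError("intensity must be positive")
        return self.dispersion_intercept + self.dispersion_slope * np.log(x)

    def sample_cv2(
        self, intensity: float | np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw CV^2 values; non-positive predicted means map to 0."""
        mean = np.atleast_1d(self.mean_cv2(intensity))
        out = np.zeros_like(mean)
        pos = mean > 0
        if pos.any():
            if np.isinf(self.nb_size):
                out[pos] = mean[pos]
            else:
                out[pos] = rng.gamma(
                    shape=self.nb_size, scale=mean[pos] / self.nb_size
                )
        return out

    @classmethod
    def fit(cls, intensities: np.ndarray, cv2s: np.ndarray, nb_size: float = 4.0) -> "VariabilityModel":
        """Least-squares fit of the log-linear mean curve to a user table."""
        x = np.log(np.asarray(intensities, dtype=float))
        y = np.asarray(cv2s, dtype=float)
        if x.size < 2:
            raise ValueError("need at least 2 points to fit")
        slope, intercept = np.polyfit(x, y, 1)
        return cls(dispersion_slope=float(slope), dispersion_intercept=float(intercept), nb_size=nb_size)


def predict_variability(
    intensity: float, model: VariabilityModel, seed: int | np.random.Generator = 0
) -> float:
    """Single CV^2 draw for one feature (see VariabilityModel.sample_cv2)."""
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return float(model.sample_cv2(intensity, rng)[0])


def sample_genome_molarity(
    dist: str,
    params: dict | None,
    n_genomes: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Relative genome molarities under a named abundance distribution.

    uniform: all 1/n.  lognormal: normalized exp(Normal(mu, sigma)) draws
    (params ``mu`` default 0, ``sigma`` default 1).  powerlaw: normalized
    rank^(-alpha) (param ``alpha`` default 1).  empirical: normalized copy
    of params["profile"] (length must equal n_genomes).
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    params = params or {}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dist == "uniform":
        v = np.full(n_genomes, 1.0 / n_genomes)
    elif dist == "lognormal":
        mu = float(params.get("mu", 0.0))
        sigma = float(params.get("sigma", 1.0))
        v = np.exp(rng.normal(mu, sigma, n_genomes))
    elif dist == "powerlaw":
        alpha = float(params.get("alpha", 1.0))
        v = np.arange(1, n_genomes + 1, dtype=float) ** (-alpha)
    elif dist == "empirical":
        profile = np.asarray(params.get("profile", []), dtype=float)
        if profile.size != n_genomes:
            raise ValueError(
                f"empirical profile has length {profile.size}, expected {n_genomes}"
            )
        if (profile < 0).any() or profile.sum() <= 0:
            raise ValueError("empirical profile must be non-negative with positive sum")
        v = profile.copy()
    else:
        raise ValueError(f"unknown abundance distribution {dist!r}")
    return v / v.sum()


def build_abundance_matrix(
    genome_ids: list[str],
    sample_ids: list[str],
    molarity: np.ndarray,
    model: VariabilityModel,
    rng: np.random.Generator,
    variability_per: str = "feature_sample",
) -> AbundanceMatrix:
    """Shared intensity across samples; CV^2 drawn per feature x sample
    (default) or once per feature (``variability_per='feature'``)."""
    n_g, n_s = len(genome_ids), len(sample_ids)
    intensity = np.tile(molarity[:, None], (1, n_s))
    if variability_per == "feature":
        col = model.sample_cv2(molarity, rng)
        variability = np.tile(col[:, None], (1, n_s))
    elif variability_per == "feature_sample":
        variability = np.column_stack(
            [model.sample_cv2(molarity, rng) for _ in range(n_s)]
        )
    else:
        raise ValueError(f"unknown variability_per {variability_per!r}")
    return AbundanceMatrix(genome_ids, sample_ids, intensity, variability)


def simulate_sample_counts(
    intensity_col: np.ndarray,
    variability_col: np.ndarray,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Two-stage (biological Gamma, technical multinomial) count draw.

    Gamma parameterization: mean = intensity, CV^2 = variability, i.e.
    shape = 1/CV^2, scale = intensity * CV^2.  Counts always sum to depth.
    """
    intensity_col = np.asarray(intensity_col, dtype=float)
    variability_col = np.asarray(variability_col, dtype=float)
    if intensity_col.shape != variability_col.shape:
        raise ValueError("intensity and variability columns differ in length")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    realized = intensity_col.copy()
    var_pos = variability_col > 0
    if var_pos.any():
        shape = 1.0 / variability_col[var_pos]
        scale = intensity_col[var_pos] * variability_col[var_pos]
        realized[var_pos] = rng.gamma(shape=shape, scale=scale)
    total = realized.sum()
    if total <= 0:
        raise ValueError("all realized intensities are zero")
    return rng.multinomial(depth, realized / total)


def expand_to_asv(
    genome_intensity: dict[str, float] | np.ndarray,
    amplicon_sets: list[AmpliconSet],
    genome_ids: list[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Genome molarity -> expected ASV-level intensity.

    Each ASV's weight is its genome's molarity times its copy multiplicity
    within the genome; the result is renormalized over all ASVs.  Genomes
    with no extractable amplicon contribute nothing (logged as a warning).
    """
    if isinstance(genome_intensity, dict):
        molarity = genome_intensity
    else:
        if genome_ids is None:
            raise ValueError("genome_ids required when molarity is an array")
        molarity = dict(zip(genome_ids, np.asarray(genome_intensity, dtype=float)))

    asv_ids: list[str] = []
    weights: list[float] = []
    for aset in amplicon_sets:
        if aset.n_amplicons == 0:
            logger.warning("genome %s has no extractable amplicons", aset.genome_id)
            warnings.warn(
                f"genome {aset.genome_id} has no extractable amplicons; "
                "it contributes no reads",
                stacklevel=2,
            )
            continue
        m = molarity[aset.genome_id]
        for asv_id, mult in aset.multiplicity.items():
            asv_ids.append(asv_id)
            weights.append(m * mult)
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or w.sum() <= 0:
        return asv_ids, w
    return asv_ids, w / w.sum()


def simulate_count_table(
    asv_ids: list[str],
    asv_intensity: np.ndarray,
    sample_ids: list[str],
    depth: int,
    model: VariabilityModel,
    rng: np.random.Generator,
    variability_per: str = "feature_sample",
) -> CountTable:
    """Per-sample two-stage sampling at the ASV level."""
    n_asv = len(asv_ids)
    counts = np.zeros((n_asv, len(sample_ids)), dtype=np.int64)
    shared_cv2 = model.sample_cv2(asv_intensity, rng) if variability_per == "feature" else None
    for j in range(len(sample_ids)):
        cv2_col = shared_cv2 if shared_cv2 is not None else model.sample_cv2(asv_intensity, rng)
        counts[:, j] = simulate_sample_counts(asv_intensity, cv2_col, depth, rng)
    return CountTable(asv_ids, sample_ids, counts)
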