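"""Pass-number (np) distributions for CCS molecules.

The number of polymerase passes per molecule drives consensus accuracy.
Supported sources: an empirical histogram (TSV ``np<TAB>count``) or a
lognormal on the log scale, both truncated to [np_min, np_max]
(default 2-59).  Lognormal draws are rounded to the nearest integer and
rejection-sampled back into range, which is unbiased within the support.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd


@dataclasses.dataclass
class PassNumberDistribution:
    """Distribution of integer pass numbers on [np_min, np_max]."""

    kind: str  # 'empirical' or 'lognormal'
    np_min: int = 2
    np_max: int = 59
    support: np.ndarray | None = None  # empirical only
    probabilities: np.ndarray | None = None  # empirical only
    mu: float | None = None  # lognormal only (log scale)
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.np_min < 1:
            raise ValueError("np_min must be >= 1")
        if self.np_max < self.np_min:
            raise ValueError("np_max must be >= np_min")
        if self.kind == "empirical":
            self.support = np.asarray(self.support, dtype=np.int64)
            self.probabilities = np.asarray(self.probabilities, dtype=float)
            if self.support.size == 0:
                raise ValueError("empirical distribution has empty support")
            if not np.isclose(self.probabilities.sum(), 1.0):
                raise ValueError("probabilities must sum to 1")
            out = (self.support < self.np_min) | (self.support > self.np_max)
            if out.any():
                raise ValueError("empirical support extends outside [np_min, np_max]")
        elif self.kind == "lognormal":
            if self.mu is None or self.sigma is None or self.sigma < 0:
                raise ValueError("lognormal requires mu and sigma >= 0")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")

    def mean(self) -> float:
        if self.kind == "empirical":
            return float((self.support * self.probabilities).sum())
        # numeric truncated-discretized mean over the integer support
        k = np.arange(self.np_min, self.np_max + 1)
        p = _lognormal_bin_mass(k, self.mu, self.sigma)
        return float((k * p).sum() / p.sum())


def _lognormal_bin_mass(k: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """P(round(X) == k) for lognormal X; handles the sigma=0 point mass."""
    from scipy.stats import lognorm

    if sigma == 0:
        return (np.abs(k - np.exp(mu)) <= 0.5).astype(float)
    dist = lognorm(s=sigma, scale=np.exp(mu))
    return dist.cdf(k + 0.5) - dist.cdf(np.maximum(k - 0.5, 0.0))


def load_empirical(
    np_table: str | Path | list[tuple[int, int]],
    np_min: int = 2,
    np_max: int = 59,
) -> PassNumberDistribution:
    """Build an empirical distribution from a histogram TSV or row list.

    Out-of-range rows are dropped; remaining counts normalize to
    probabilities.  All rows out of range is an error.
    """
    if isinstance(np_table, (str, Path)):
        df = pd.read_csv(np_table, sep="\t")
        if not {"np", "count"}.issubset(df.columns):
            raise ValueError(f"{np_table}: expected columns 'np' and 'count'")
        rows = list(zip(df["np"].astype(int), df["count"].astype(float)))
    else:
        rows = [(int(a), float(b)) for a, b in np_table]
    if any(c < 0 for _, c in rows):
        raise ValueError("negative counts in pass-number table")
    kept = [(v, c) for v, c in rows if np_min <= v <= np_max and c > 0]
    if not kept:
        raise ValueError(
            f"no pass-number rows within [{np_min}, {np_max}]"
        )
    support = np.array([v for v, _ in kept], dtype=np.int64)
    counts = np.array([c for _, c in kept], dtype=float)
    return PassNumberDistribution(
        kind="empirical",
        np_min=np_min,
        np_max=np_max,
        support=support,
        probabilities=counts / counts.sum(),
    )


def fit_lognormal(np_samples) -> tuple[float, float]:
    """MLE of (mu, sigma) for an un-truncated lognormal from observed np.

    Returns the mean and population (ddof=0) standard deviation of
    log(np) — the maximum-likelihood convention, so {e, e^3} -> (2, 1).
    """
    x = np.asarray(np_samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if (x <= 0).any():
        raise ValueError("pass numbers must be positive")
    logs = np.log(x)
    return float(logs.mean()), float(logs.std(ddof=0))


def sample_np(
    dist: PassNumberDistribution,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw n integer pass numbers, all within [np_min, np_max]."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if dist.kind == "empirical":
        idx = rng.choice(dist.support.size, size=n, p=dist.probabilities)
        return dist.support[idx]
    # lognormal: round to nearest int, reject out-of-range draws
    out = np.zeros(n, dtype=np.int64)
    pending = np.arange(n)
    while pending.size:
        draw = np.rint(rng.lognormal(dist.mu, dist.sigma, pending.size)).astype(np.int64)
        ok = (draw >= dist.np_min) & (draw <= dist.np_max)
        if not ok.any() and dist.sigma == 0:
            raise ValueError(
                "degenerate lognormal point mass lies outside [np_min, np_max]"
            )
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
    return out


def from_config(
    np_source: str,
    np_min: int,
    np_max: int,
    mu: float = 2.3,
    sigma: float = 0.5,
    np_table: str | Path | None = None,
) -> PassNumberDistribution:
    """Construct the distribution a RunConfig describes."""
    if np_source == "empirical":
        if np_table is None:
            raise ValueError("np_source='empirical' requires np_table")
        return load_empirical(np_table, np_min, np_max)
    return PassNumberDistribution(
        kind="lognormal", np_min=np_min, np_max=np_max, mu=mu, sigma=sigma
    )
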