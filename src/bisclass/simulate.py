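"""Synthetic methylome generator.

Emulates the statistical structure of invertebrate whole-genome bisulfite
data: heavily overdispersed per-site read depth, a sparsely methylated
genome, and (optionally) spatial clustering of methylated cytosines.

* Coverage is drawn from a shifted negative binomial: ``N = 1 + NB`` where
  the NB component is moment-matched so the shifted draw has the configured
  mean and ``var_factor`` times the mean as variance.  At honey-bee-like
  settings (mean ~4, variance ~3x mean) roughly half of all sites carry
  fewer than 4 reads.
* Truth is Bernoulli per site.  In clustered mode, methylation concentrates
  in ``cluster_fraction`` of the genome at ``cluster_intensity`` times the
  global level; by default the out-of-cluster rate is set by conservation so
  the genome-wide expectation equals ``pi`` in both modes (zero out-of-
  cluster at the default 1/10 fraction, 10x intensity).
* Reads are error-injected: a methylated site yields C reads with
  probability ``p1_eff``, a non-methylated one with ``p0_eff``.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import COUNT_COLUMNS, effective_error_rates

__all__ = [
    "SimConfig",
    "SimTruth",
    "ShiftedNegBinFit",
    "sample_coverage",
    "fit_shifted_negbin",
    "simulate_truth",
    "simulate_reads",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """All simulator knobs.

    Defaults reproduce a honey-bee-like regime: 100,000 CpGs at 15 bp
    spacing (so 200 nearest neighbors span ~3 kb), mean coverage 4 with
    variance three times the mean, global methylation level 0.005,
    non-conversion 0.002 and retention 0.7.
    """

    n_sites: int = 100_000
    mean_cov: float = 4.0
    var_factor: float = 3.0
    pi: float = 0.005
    clustered: bool = False
    cluster_fraction: float = 0.1
    cluster_intensity: float = 10.0
    cluster_count: int = 10
    preserve_global_mean: bool = True
    p0: float = 0.002
    p1: float = 0.7
    eps: float = 0.0
    spacing: int = 15
    chrom: str = "sim1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 < self.pi < 1.0:
            raise ValueError(f"pi must lie in (0, 1), got {self.pi}")
        if self.mean_cov <= 1.0:
            raise ValueError(f"mean_cov must exceed 1 (shift constant), got {self.mean_cov}")
        if self.var_factor * self.mean_cov <= self.mean_cov - 1.0:
            raise ValueError("infeasible moments: need var_factor * mean_cov > mean_cov - 1")
        if not 0.0 < self.cluster_fraction < 1.0:
            raise ValueError("cluster_fraction must lie in (0, 1)")
        if self.cluster_count < 1:
            raise ValueError("cluster_count must be >= 1")
        if self.clustered:
            if self.cluster_fraction * self.cluster_intensity * self.pi > 1.0:
                raise ValueError("cluster_fraction * cluster_intensity * pi must be <= 1")
            if self.cluster_intensity * self.pi > 1.0:
                raise ValueError("in-cluster methylation probability exceeds 1")
        effective_error_rates(self.p0, self.p1, self.eps)  # validates
        if self.spacing < 1:
            raise ValueError("spacing must be >= 1")

    @property
    def in_cluster_rate(self) -> float:
        return self.cluster_intensity * self.pi

    @property
    def out_cluster_rate(self) -> float:
        if not self.preserve_global_mean:
            return self.pi
        rate = self.pi * (1.0 - self.cluster_fraction * self.cluster_intensity) / (
            1.0 - self.cluster_fraction
        )
        return max(rate, 0.0)


@dataclass
class SimTruth:
    """Simulated sites plus the latent truth used to generate them."""

    sites: pd.DataFrame
    status: np.ndarray
    cluster_mask: np.ndarray
    config: SimConfig


@dataclass(frozen=True)
class ShiftedNegBinFit:
    """Method-of-moments fit of the shifted negative binomial coverage model."""

    mean: float
    variance: float
    r: float
    q: float
    feasible: bool

    def theoretical_quantiles(self, probs) -> np.ndarray:
        """Quantiles of the fitted shifted NB, for Q-Q plots against data."""
        if not self.feasible:
            raise ValueError("no feasible negative binomial fit for these moments")
        return stats.nbinom.ppf(np.asarray(probs, dtype=float), self.r, self.q) + 1.0


def _negbin_params(mean_cov: float, var_factor: float) -> tuple[float, float]:
    """Moment-match the NB component of the shifted distribution.

    The shift constant is 1, so the NB component has mean ``mean_cov - 1``
    while the variance is unchanged at ``var_factor * mean_cov``.
    """
    mu = mean_cov - 1.0
    var = var_factor * mean_cov
    if mu <= 0 or var <= mu:
        raise ValueError(
            f"infeasible shifted-NB moments: component mean {mu}, variance {var}"
        )
    q = mu / var  # scipy's success probability
    r = mu * mu / (var - mu)
    return r, q


def sample_coverage(n: int, mean_cov: float, var_factor: float = 3.0, seed=None) -> np.ndarray:
    """Draw per-site read depths from the shifted negative binomial.

    Every draw is at least 1; the sample mean converges to ``mean_cov`` and
    the sample variance to ``var_factor * mean_cov``.
    """
    r, q = _negbin_params(mean_cov, var_factor)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return 1 + rng.negative_binomial(r, q, size=n)


def fit_shifted_negbin(coverages) -> ShiftedNegBinFit:
    """Method-of-moments fit of the shifted NB to observed read depths."""
    cov = np.asarray(coverages, dtype=float)
    if cov.size < 2:
        raise ValueError("need at least 2 coverage values")
    if np.any(cov < 1):
        raise ValueError("coverages must be >= 1 for the shifted model")
    mean = float(cov.mean())
    var = float(cov.var(ddof=1))
    mu = mean - 1.0
    feasible = mu > 0 and var > mu
    if feasible:
        q = mu / var
        r = mu * mu / (var - mu)
    else:
        q = float("nan")
        r = float("nan")
    return ShiftedNegBinFit(mean=mean, variance=var, r=r, q=q, feasible=feasible)


def _place_clusters(n_sites: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Contiguous, non-overlapping cluster blocks covering ~cluster_fraction of sites."""
    n_cluster_sites = int(round(n_sites * config.cluster_fraction))
    count = min(config.cluster_count, max(n_cluster_sites, 1))
    block = max(n_cluster_sites // count, 1)
    free = n_sites - block * count
    if free < 0:
        raise ValueError("cluster blocks exceed genome size")
    # Uniform composition of the free space into count+1 gaps.
    gaps = rng.multinomial(free, np.full(count + 1, 1.0 / (count + 1)))
    mask = np.zeros(n_sites, dtype=bool)
    start = 0
    for i in range(count):
        start += gaps[i]
        mask[start : start + block] = True
        start += block
    return mask


def simulate_truth(config: SimConfig, rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw the latent methylation status per site (and the cluster mask).

    Homogeneous mode methylates each site independently with probability
    ``pi``.  Clustered mode raises the in-cluster rate to
    ``cluster_intensity * pi`` and lowers the out-of-cluster rate so the
    genome-wide expectation is unchanged (or keeps it at ``pi`` when
    ``preserve_global_mean`` is off).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = config.n_sites
    if not config.clustered:
        status = rng.random(n) < config.pi
        return status, np.zeros(n, dtype=bool)
    mask = _place_clusters(n, config, rng)
    prob = np.where(mask, config.in_cluster_rate, config.out_cluster_rate)
    status = rng.random(n) < prob
    return status, mask


def simulate_reads(status, coverage, p0: float, p1: float, eps: float = 0.0, seed=None) -> np.ndarray:
    """Error-injected C-read counts: Binomial(N, p1_eff or p0_eff) per site."""
    p0_eff, p1_eff = effective_error_rates(p0, p1, eps)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    status = np.asarray(status, dtype=bool)
    coverage = np.asarray(coverage)
    rate = np.where(status, p1_eff, p0_eff)
    return rng.binomial(coverage, rate)


def simulate_dataset(config: SimConfig) -> SimTruth:
    """Compose coverage, truth and reads into a full synthetic count table.

    Sites sit at uniform spacing on one synthetic chromosome, so with the
    default 15 bp spacing a 200-nearest-neighbor window spans about 3 kb.
    The returned :class:`SimTruth` carries the count table in the canonical
    column layout accepted by every caller in this package.
    """
    rng = np.random.default_rng(config.seed)
    coverage = sample_coverage(config.n_sites, config.mean_cov, config.var_factor, seed=rng)
    status, cluster_mask = simulate_truth(config, rng=rng)
    n_meth = simulate_reads(status, coverage, config.p0, config.p1, config.eps, seed=rng)
    pos = 1 + np.arange(config.n_sites, dtype=np.int64) * config.spacing
    sites = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos,
            "strand": "+",
            "context": "CpG",
            "n_meth": n_meth,
            "n_total": coverage,
        },
        columns=COUNT_COLUMNS,
    )
    return SimTruth(sites=sites, status=status, cluster_mask=cluster_mask, config=config)
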